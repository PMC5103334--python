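"""Paralog and ortholog grouping of mature miRNA with expression aggregation.

Within one miRNome, near-identical mature sequences (gene-duplication copies)
are gathered into paralog groups by greedy representative clustering at 90 %
identity and 90 % coverage of the longer sequence, then refined so every
retained member aligns to the group representative with at most 2
substitutions/indels and at most 1 nt overhang per end.

Across libraries, the same predicate plus *exact seed identity* builds
ortholog groups; a group is conserved only when every required library
contributes at least one member.  A group's expression in a library is the
geometric mean of its members' tag counts there, x̄_g = (Π x_n)^(1/k).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

from .homology import align_short
from .records import (
    AlignmentResult,
    GroupKind,
    MatureRecord,
    SequenceGroup,
)

logger = logging.getLogger(__name__)


def _sorted_for_clustering(records: Sequence[MatureRecord]) -> list[MatureRecord]:
    """Length-descending, ties lexicographic by sequence then id."""
    return sorted(records, key=lambda r: (-len(r.sequence), r.sequence, r.id))


def _cdhit_predicate(
    aln: AlignmentResult, identity: float, coverage: float
) -> bool:
    """CD-HIT-style joining rule: identity over the aligned region and
    coverage of the longer sequence both above threshold."""
    return aln.identity >= identity and aln.longer_coverage >= coverage


def paralog_compatible(aln: AlignmentResult) -> bool:
    """Refinement rule: <= 2 substitutions/indels, <= 1 nt overhang per end."""
    return aln.mismatches <= 2 and aln.overhang_5 <= 1 and aln.overhang_3 <= 1


def cluster_sequences(
    records: Sequence[MatureRecord],
    identity: float = 0.9,
    coverage: float = 0.9,
    extra_predicate=None,
) -> list[list[MatureRecord]]:
    """Greedy representative clustering of mature sequences.

    Records are visited longest-first; each joins the first existing cluster
    whose representative (founder) satisfies the identity/coverage rule and,
    if given, ``extra_predicate(record, representative, alignment)``;
    otherwise it founds a new cluster.
    """
    if not records:
        raise ValueError("no records to cluster")
    clusters: list[list[MatureRecord]] = []
    for rec in _sorted_for_clustering(records):
        placed = False
        for cluster in clusters:
            rep = cluster[0]
            aln = align_short(rec.sequence, rep.sequence, rec.id, rep.id)
            if not _cdhit_predicate(aln, identity, coverage):
                continue
            if extra_predicate is not None and not extra_predicate(rec, rep, aln):
                continue
            cluster.append(rec)
            placed = True
            break
        if not placed:
            clusters.append([rec])
    return clusters


def refine_paralog_groups(
    clusters: Iterable[Sequence[MatureRecord]],
) -> list[SequenceGroup]:
    """Final paralog groups: drop cluster members incompatible with the
    representative; each dropped member becomes a singleton group (single-copy
    miRNA count as groups of one)."""
    groups: list[SequenceGroup] = []
    singletons: list[MatureRecord] = []
    for cluster in clusters:
        rep = cluster[0]
        kept = [rep]
        for member in cluster[1:]:
            aln = align_short(member.sequence, rep.sequence, member.id, rep.id)
            if paralog_compatible(aln):
                kept.append(member)
            else:
                singletons.append(member)
        groups.append(
            SequenceGroup(
                group_id=f"PG{len(groups) + 1:04d}",
                members=kept,
                kind=GroupKind.PARALOG,
            )
        )
    for member in singletons:
        groups.append(
            SequenceGroup(
                group_id=f"PG{len(groups) + 1:04d}",
                members=[member],
                kind=GroupKind.PARALOG,
            )
        )
    return groups


def build_ortholog_groups(
    per_library_records: Mapping[str, Sequence[MatureRecord]],
    required_libraries: Iterable[str] | None = None,
    identity: float = 0.9,
    coverage: float = 0.9,
) -> list[SequenceGroup]:
    """Conserved (ortholog) groups across libraries.

    All libraries' records are merged and clustered with the paralog
    predicate plus exact seed identity (no mismatch tolerated in the seed
    region); only groups detected in every required library survive.
    Expression per library is the geometric mean of member tag counts.
    """
    if len(per_library_records) < 2:
        raise ValueError("ortholog grouping needs at least two libraries")
    required = (
        set(required_libraries)
        if required_libraries is not None
        else set(per_library_records)
    )
    missing = required - set(per_library_records)
    if missing:
        raise ValueError(f"required libraries absent from input: {sorted(missing)}")

    merged: list[MatureRecord] = []
    for library in sorted(per_library_records):
        for rec in per_library_records[library]:
            if rec.library != library:
                rec = MatureRecord(
                    id=rec.id, sequence=rec.sequence, library=library, count=rec.count
                )
            merged.append(rec)

    def ortholog_rule(rec, rep, aln):
        return paralog_compatible(aln) and rec.seed == rep.seed

    clusters = cluster_sequences(
        merged, identity=identity, coverage=coverage, extra_predicate=ortholog_rule
    )

    groups: list[SequenceGroup] = []
    for cluster in clusters:
        libraries = {m.library for m in cluster}
        if not required <= libraries:
            continue
        group = SequenceGroup(
            group_id=f"OG{len(groups) + 1:04d}",
            members=list(cluster),
            kind=GroupKind.ORTHOLOG,
            shared_seed=cluster[0].seed,
        )
        group.expression = {
            lib: aggregate_expression(group, lib) for lib in sorted(libraries)
        }
        groups.append(group)
    return groups


def geometric_mean(values: Sequence[float]) -> float:
    """x̄_g = (Π x_n)^(1/k); any zero member propagates to zero.

    The result is clamped into [min, max] of the members to keep the
    mathematical bound exact under floating-point rounding.
    """
    if not values:
        raise ValueError("geometric mean of no values")
    if any(v < 0 for v in values):
        raise ValueError("geometric mean needs non-negative values")
    if any(v == 0 for v in values):
        return 0.0
    g = math.exp(sum(math.log(v) for v in values) / len(values))
    return min(max(g, min(values)), max(values))


def aggregate_expression(group: SequenceGroup, library: str) -> float:
    """Geometric-mean tag count of a group's members in one library."""
    counts = [m.count for m in group.members_in(library)]
    if not counts:
        raise ValueError(
            f"group {group.group_id} has no member in library {library!r}"
        )
    return geometric_mean(counts)


__all__ = [
    "aggregate_expression",
    "build_ortholog_groups",
    "cluster_sequences",
    "geometric_mean",
    "paralog_compatible",
    "refine_paralog_groups",
]
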