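"""Pairwise short-sequence alignment and three-way homology classification.

Mature miRNA are compared against a reference catalogue and each best hit is
sorted into one of three groups:

* ``entire_match`` — a gapless, substitution-free alignment with at most 2 nt
  overhanging at each end;
* ``mismatch``     — at most 1 substitution or indel, and at most 1 nt
  overhanging at each end;
* ``no_hit``       — everything else.

The aligner is an exact end-free (overlap) dynamic program: terminal gaps are
unpenalized, internal columns score match +1 / mismatch -1 / gap -2.  Among
score-optimal alignments it prefers the one with the fewest substitutions and
indels, then the smallest 5' overhang, which makes the reported categories
deterministic and symmetric in the two sequences.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .records import (
    AlignmentResult,
    MatchCategory,
    extract_seed,
    normalize_dna,
)

_MATCH = 1
_MISMATCH = -1
_GAP = -2

# composite DP key: score (major), fewer errors (minor), smaller 5' overhang
_K_SCORE = 1 << 16
_K_ERR = 1 << 8

_VALID = set("ACGT")


def _check_sequence(seq: str, name: str) -> str:
    s = normalize_dna(seq)
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"{name} contains non-ACGTU characters: {sorted(bad)}")
    return s


def _dp_kernel(qa: np.ndarray, sa: np.ndarray) -> tuple[int, int, int, int, int, int, int]:
    """End-free DP over encoded sequences.

    Each cell carries a composite key (score major, fewer errors minor,
    smaller 5' overhang last) plus auxiliary totals, so the preferred optimal
    alignment is recovered without a traceback.  Returns
    (mismatches, q5, s5, q3, s3, aligned_len, matches).
    """
    n = qa.shape[0]
    m = sa.shape[0]
    key = np.empty((n + 1, m + 1), dtype=np.int64)
    err = np.zeros((n + 1, m + 1), dtype=np.int32)
    u5q = np.zeros((n + 1, m + 1), dtype=np.int32)
    u5s = np.zeros((n + 1, m + 1), dtype=np.int32)
    mat = np.zeros((n + 1, m + 1), dtype=np.int32)
    col = np.zeros((n + 1, m + 1), dtype=np.int32)
    for j in range(m + 1):
        key[0, j] = -j  # free start, subject 5' unaligned
        u5s[0, j] = j
    for i in range(1, n + 1):
        key[i, 0] = -i  # free start, query 5' unaligned
        u5q[i, 0] = i
        qc = qa[i - 1]
        for j in range(1, m + 1):
            if qc == sa[j - 1]:
                step = _MATCH
                derr = 0
                dmat = 1
            else:
                step = _MISMATCH
                derr = 1
                dmat = 0
            # diagonal
            bk = key[i - 1, j - 1] + step * _K_SCORE - derr * _K_ERR
            be = err[i - 1, j - 1] + derr
            ba = u5q[i - 1, j - 1]
            bb = u5s[i - 1, j - 1]
            bm = mat[i - 1, j - 1] + dmat
            bc = col[i - 1, j - 1] + 1
            # up: gap in subject
            k = key[i - 1, j] + _GAP * _K_SCORE - _K_ERR
            if k > bk:
                bk = k
                be = err[i - 1, j] + 1
                ba = u5q[i - 1, j]
                bb = u5s[i - 1, j]
                bm = mat[i - 1, j]
                bc = col[i - 1, j] + 1
            # left: gap in query
            k = key[i, j - 1] + _GAP * _K_SCORE - _K_ERR
            if k > bk:
                bk = k
                be = err[i, j - 1] + 1
                ba = u5q[i, j - 1]
                bb = u5s[i, j - 1]
                bm = mat[i, j - 1]
                bc = col[i, j - 1] + 1
            key[i, j] = bk
            err[i, j] = be
            u5q[i, j] = ba
            u5s[i, j] = bb
            mat[i, j] = bm
            col[i, j] = bc
    # free end: best cell on last row or last column; prefer high key then
    # small 3' overhang for determinism/symmetry
    best_k = np.int64(-(1 << 60))
    best_oh3 = 0
    bi = 0
    bj = 0
    for i in range(n + 1):  # last column
        oh3 = n - i if n - i > 0 else 0
        k = key[i, m]
        if k > best_k or (k == best_k and oh3 < best_oh3):
            best_k = k
            best_oh3 = oh3
            bi = i
            bj = m
    for j in range(m + 1):  # last row
        oh3 = m - j if m - j > 0 else 0
        k = key[n, j]
        if k > best_k or (k == best_k and oh3 < best_oh3):
            best_k = k
            best_oh3 = oh3
            bi = n
            bj = j
    return (
        int(err[bi, bj]),
        int(u5q[bi, bj]),
        int(u5s[bi, bj]),
        n - bi,
        m - bj,
        int(col[bi, bj]),
        int(mat[bi, bj]),
    )


try:  # pragma: no cover - plain-python fallback exercised when numba absent
    from numba import njit

    _dp_kernel = njit(cache=False)(_dp_kernel)
except Exception:  # pragma: no cover
    pass


@lru_cache(maxsize=200_000)
def _align_core(q: str, s: str) -> tuple[int, int, int, int, int, int, int]:
    qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
    sa = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return _dp_kernel(qa, sa)


def align_short(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal end-free alignment of two short nucleotide sequences.

    Overhangs are unpenalized; the reported overhang per side is the larger of
    the two sequences' unaligned lengths on that side.  ``mismatches`` is the
    total of substitutions and indels in the aligned core.
    """
    q = _check_sequence(query, "query")
    s = _check_sequence(subject, "subject")
    err, q5, s5, q3, s3, cols, mat = _align_core(q, s)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        mismatches=err,
        overhang_5=max(q5, s5),
        overhang_3=max(q3, s3),
        aligned_len=cols,
        matches=mat,
        query_unaligned_5=q5,
        query_unaligned_3=q3,
        subject_unaligned_5=s5,
        subject_unaligned_3=s3,
        query_len=len(q),
        subject_len=len(s),
    )


def classify_match(aln: AlignmentResult) -> MatchCategory:
    """Sort an alignment into entire-match / mismatch / no-hit.

    Entire match: no substitutions or indels, at most 2 nt overhang per end.
    Mismatch: at most 1 substitution or indel, at most 1 nt overhang per end.
    """
    if aln.mismatches == 0 and aln.overhang_5 <= 2 and aln.overhang_3 <= 2:
        return MatchCategory.ENTIRE_MATCH
    if aln.mismatches <= 1 and aln.overhang_5 <= 1 and aln.overhang_3 <= 1:
        return MatchCategory.MISMATCH
    return MatchCategory.NO_HIT


def classify_against_reference(
    query: str, references: Sequence[tuple[str, str]]
) -> tuple[MatchCategory, AlignmentResult | None]:
    """Classify a mature sequence by its best hit in a reference catalogue.

    The best hit is the reference giving the most favourable category
    (entire_match > mismatch > no_hit); returns (category, best alignment),
    or (no_hit, None) for an empty catalogue.
    """
    order = {
        MatchCategory.ENTIRE_MATCH: 0,
        MatchCategory.MISMATCH: 1,
        MatchCategory.NO_HIT: 2,
    }
    best: tuple[int, AlignmentResult] | None = None
    for ref_id, ref_seq in references:
        aln = align_short(query, ref_seq, subject_id=ref_id)
        rank = order[classify_match(aln)]
        if best is None or rank < best[0]:
            best = (rank, aln)
            if rank == 0:
                break
    if best is None:
        return MatchCategory.NO_HIT, None
    return classify_match(best[1]), best[1]


def find_novel_seeds(
    seeds: Iterable[str], reference_seeds: Iterable[str]
) -> tuple[int, set[str], set[str]]:
    """Summarize a seed catalogue against a reference seed set.

    Returns (number of distinct seeds, seeds occurring more than once,
    distinct seeds absent from the reference).  Seeds are compared in a
    normalized DNA representation so RNA/DNA case conventions cannot split
    identical seeds.
    """
    original: dict[str, str] = {}
    counts: dict[str, int] = {}
    for s in seeds:
        key = normalize_dna(s)
        original.setdefault(key, s)
        counts[key] = counts.get(key, 0) + 1
    ref = {normalize_dna(s) for s in reference_seeds}
    repeated = {original[k] for k, c in counts.items() if c > 1}
    novel = {original[k] for k in counts.keys() - ref}
    return len(counts), repeated, novel


__all__ = [
    "align_short",
    "classify_against_reference",
    "classify_match",
    "extract_seed",
    "find_novel_seeds",
]
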