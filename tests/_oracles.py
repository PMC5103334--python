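"""Independent brute-force oracles used to validate the implementations.

Each oracle re-derives its quantity from first principles (plain loops,
explicit enumeration, closed forms) without touching the code paths it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations


# ---------------------------------------------------------------------------
# end-free alignment: tuple-valued dynamic program, plain Python
# ---------------------------------------------------------------------------

def oracle_align(q: str, s: str) -> tuple[int, int, int]:
    """(mismatches, overhang_5, overhang_3) of the optimal end-free
    alignment under match +1 / mismatch -1 / gap -2, preferring fewer
    errors then smaller 5' overhang among score-optimal alignments."""
    n, m = len(q), len(s)
    # value per cell: (score, -errors, -max(q5, s5)) with start info carried
    cells: dict[tuple[int, int], tuple[tuple[int, int, int], int, int]] = {}
    for j in range(m + 1):
        cells[(0, j)] = ((0, 0, -j), 0, j)  # (key, q5, s5)
    for i in range(1, n + 1):
        cells[(i, 0)] = ((0, 0, -i), i, 0)
        for j in range(1, m + 1):
            options = []
            key, q5, s5 = cells[(i - 1, j - 1)]
            sub = 0 if q[i - 1] == s[j - 1] else 1
            options.append(
                ((key[0] + (1 if sub == 0 else -1), key[1] - sub, key[2]), q5, s5)
            )
            key, q5, s5 = cells[(i - 1, j)]
            options.append(((key[0] - 2, key[1] - 1, key[2]), q5, s5))
            key, q5, s5 = cells[(i, j - 1)]
            options.append(((key[0] - 2, key[1] - 1, key[2]), q5, s5))
            cells[(i, j)] = max(options, key=lambda o: o[0])
    ends = [(i, m) for i in range(n + 1)] + [(n, j) for j in range(m)]
    best = max(
        ends,
        key=lambda ij: (
            cells[ij][0],
            -max(n - ij[0], m - ij[1]),
        ),
    )
    key, q5, s5 = cells[best]
    errors = -key[1]
    oh5 = max(q5, s5)
    oh3 = max(n - best[0], m - best[1])
    return errors, oh5, oh3


# ---------------------------------------------------------------------------
# single-linkage all-pairs clustering under an arbitrary pairwise predicate
# ---------------------------------------------------------------------------

def oracle_single_linkage(items: list, predicate) -> list[set]:
    """Connected components of the predicate graph (union-find)."""
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(items)), 2):
        if predicate(items[i], items[j]):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, set] = {}
    for i in range(len(items)):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


# ---------------------------------------------------------------------------
# hypergeometric upper tail (one-sided Fisher p-value)
# ---------------------------------------------------------------------------

def oracle_hypergeom_tail(k: int, n_draws: int, n_success: int, n_total: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=n_total, K=n_success, n=n_draws)."""
    denom = math.comb(n_total, n_draws)
    upper = min(n_draws, n_success)
    total = 0
    for x in range(k, upper + 1):
        total += math.comb(n_success, x) * math.comb(n_total - n_success, n_draws - x)
    return total / denom


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, literal definition
# ---------------------------------------------------------------------------

def oracle_bh(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# ungapped genome scan, plain slicing
# ---------------------------------------------------------------------------

def oracle_hamming_scan(query: str, genome: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (start, mismatches) of forward-strand placements."""
    out = []
    k = len(query)
    for start in range(len(genome) - k + 1):
        d = sum(a != b for a, b in zip(query, genome[start : start + k]))
        if d <= max_mismatches:
            out.append((start, d))
    return out


# ---------------------------------------------------------------------------
# TMM factor, literal published formula with plain loops
# ---------------------------------------------------------------------------

def oracle_tmm_log2(obs: list[float], ref: list[float]) -> float:
    n_obs = sum(obs)
    n_ref = sum(ref)
    rows = [
        (o, r) for o, r in zip(obs, ref) if o > 0 and r > 0
    ]
    ms, as_, ws = [], [], []
    for o, r in rows:
        ms.append(math.log2((o / n_obs) / (r / n_ref)))
        as_.append(0.5 * math.log2((o / n_obs) * (r / n_ref)))
        ws.append(1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)))
    n = len(ms)
    def keep_ranks(values, trim):
        order = sorted(range(n), key=lambda i: (values[i], i))
        rank = {idx: pos + 1 for pos, idx in enumerate(order)}
        lo = math.floor(n * trim) + 1
        hi = n + 1 - math.floor(n * trim)
        return {i for i in range(n) if lo <= rank[i] <= hi}
    kept = keep_ranks(ms, 0.30) & keep_ranks(as_, 0.05)
    num = sum(ws[i] * ms[i] for i in kept)
    den = sum(ws[i] for i in kept)
    return num / den


# ---------------------------------------------------------------------------
# agglomerative complete-linkage merge order
# ---------------------------------------------------------------------------

def oracle_complete_linkage_merges(dist: "list[list[float]]") -> list[frozenset]:
    """Sequence of merged member sets under complete linkage."""
    clusters: list[set[int]] = [{i} for i in range(len(dist))]
    merges: list[frozenset] = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = max(dist[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges
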