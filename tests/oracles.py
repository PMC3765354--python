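"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the affine-gap
alignment oracle is a direct recursion over all alignment paths (memoized
on (i, j, gap-state), which preserves the exhaustive-maximum semantics),
the scan oracle scores windows one by one, and the cluster oracle
enumerates qualifying runs.
"""

from __future__ import annotations

import functools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_global_score(a: str, b: str, gap_open: float = 11.0,
                             gap_extend: float = 1.0) -> float:
    """Maximum affine-gap global alignment score over all alignments.

    Gap convention matches the package: a gap of length k costs
    open + (k-1) * extend. States: 0 = last column was a match/mismatch,
    1 = gap in b (a consumed), 2 = gap in a (b consumed)."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, _BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    score = rec(0, 0, 0)
    rec.cache_clear()
    return score


def enumerate_global_score(a: str, b: str, gap_open: float = 11.0,
                           gap_extend: float = 1.0) -> float:
    """Literal exhaustive enumeration (no memo); for tiny sequences only,
    to validate the memoized recursion above."""

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            yield 0.0
            return
        if i < len(a) and j < len(b):
            for s in rec(i + 1, j + 1, 0):
                yield _BLOSUM62[a[i], b[j]] + s
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            for s in rec(i + 1, j, 1):
                yield -cost + s
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            for s in rec(i, j + 1, 2):
                yield -cost + s

    return max(rec(0, 0, 0))


def best_nonoverlapping_windows(candidates: list[tuple[int, float]],
                                length: int) -> float:
    """Maximum total score over all non-overlapping window subsets
    (exhaustive bitmask search; use with <= 15 candidates)."""
    n = len(candidates)
    best = 0.0
    for mask in range(1, 1 << n):
        chosen = [candidates[k] for k in range(n) if mask >> k & 1]
        ok = all(abs(chosen[x][0] - chosen[y][0]) >= length
                 for x in range(len(chosen)) for y in range(x + 1, len(chosen)))
        if ok:
            best = max(best, sum(s for _, s in chosen))
    return best


def enumerate_tandem_runs(genes: list[tuple[str, int, str]],
                          max_intervening: int,
                          max_span_bp: int) -> set[frozenset]:
    """All maximal qualifying same-group runs on one chromosome.

    `genes`: (gene_id, start, group) sorted by start. A run extends from
    gene at sorted index `last` to any later index j with the same group,
    j - last - 1 <= max_intervening, and start_j - start_last <= max_span_bp.
    Returns maximal runs (no run a strict subset of another) of size >= 2."""
    n = len(genes)

    def extensions(last: int, grp: str):
        for j in range(last + 1, min(n, last + 2 + max_intervening)):
            if genes[j][2] == grp and genes[j][1] - genes[last][1] <= max_span_bp:
                yield j

    runs: set[frozenset] = set()

    def grow(chain: list[int]):
        grp = genes[chain[0]][2]
        exts = list(extensions(chain[-1], grp))
        if not exts:
            if len(chain) >= 2:
                runs.add(frozenset(genes[k][0] for k in chain))
            return
        for j in exts:
            grow(chain + [j])

    for i in range(n):
        grow([i])
    maximal = {r for r in runs
               if not any(r < other for other in runs if other != r)}
    return maximal
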