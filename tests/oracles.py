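"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's own fast paths: substring overlap is
checked with naive string scans or full dynamic programming, components
with BFS over an explicit pairwise matrix, and counting rules by direct
enumeration.
"""

from __future__ import annotations

from itertools import combinations


def lcs_dp(a: str, b: str) -> int:
    """Longest common contiguous substring by full O(n*m) DP."""
    best = 0
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
                best = max(best, table[i][j])
    return best


def overlaps_at_least(a: str, b: str, k: int) -> bool:
    """Naive scan: does any k-window of ``a`` occur verbatim in ``b``?"""
    return any(a[i : i + k] in b for i in range(len(a) - k + 1))


def connected_components_bfs(seqs: list[str], k: int) -> list[frozenset[int]]:
    """Components of the pairwise >=k-overlap graph by explicit BFS."""
    n = len(seqs)
    adj = {i: set() for i in range(n)}
    for i, j in combinations(range(n), 2):
        if overlaps_at_least(seqs[i], seqs[j], k):
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def common_substrings(seqs: list[str]) -> set[str]:
    """All substrings common to every sequence (exhaustive)."""
    subs = None
    for s in seqs:
        cur = {s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1)}
        subs = cur if subs is None else subs & cur
    return subs or set()


def tier_by_rule(
    ranks: dict[str, float], tau_class: float, tau_ext: float
) -> tuple[str, set[str]]:
    """Direct application of the tiered cutoff rule."""
    primary = {a for a, r in ranks.items() if r <= tau_class}
    if primary:
        return "primary", primary
    extended = {a for a, r in ranks.items() if r <= tau_ext}
    if extended:
        return "extended", extended
    return "unassigned", set()


def hypergeom_tail(k: int, n_a: int, n_b: int, universe: int) -> float:
    """P(overlap >= k) by exhaustive hypergeometric sum with exact rationals."""
    from fractions import Fraction
    from math import comb

    total = comb(universe, n_b)
    acc = Fraction(0)
    for x in range(k, min(n_a, n_b) + 1):
        acc += Fraction(comb(n_a, x) * comb(universe - n_a, n_b - x), total)
    return float(acc)
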