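"""Substring primitives shared by the background filter and nested-set
clustering.

Two peptides "overlap by >= k residues" when they share a contiguous
identical substring of length >= k, which is equivalent to sharing at least
one k-mer. The k-mer formulation is what the fast paths use; the dynamic
programming longest-common-substring is kept for core extraction and as the
reference the fast paths must agree with.
"""

from __future__ import annotations

from typing import Iterable


def kmers(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return set()
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_kmer(a: str, b: str, k: int) -> bool:
    """True iff a and b share a contiguous identical substring of length >= k."""
    if len(a) > len(b):
        a, b = b, a
    return not kmers(a, k).isdisjoint(kmers(b, k))


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous substring common to a and b (O(n*m))."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def maximal_common_substring(seqs: Iterable[str]) -> str:
    """Longest substring present in every sequence; leftmost-in-first on ties.

    The first sequence (in the given order) anchors the enumeration, so ties
    among equally long common substrings resolve to the one starting earliest
    in that sequence.
    """
    seqs = list(seqs)
    if not seqs:
        return ""
    first, rest = seqs[0], seqs[1:]
    if not rest:
        return first
    for length in range(len(first), 0, -1):
        for start in range(len(first) - length + 1):
            cand = first[start : start + length]
            if all(cand in s for s in rest):
                return cand
    return ""
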