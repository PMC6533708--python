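"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, recursion, direct set
comprehension) and shares no code with the implementations it checks.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, permutations


def local_alignment_score_bruteforce(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Optimal local alignment score with linear gap penalties, as the max
    over all substring pairs of a recursively enumerated global score."""

    @lru_cache(maxsize=None)
    def nw(x: str, y: str) -> float:
        if not x:
            return gap * len(y)
        if not y:
            return gap * len(x)
        sub = match if x[0] == y[0] else mismatch
        return max(nw(x[1:], y[1:]) + sub,
                   nw(x[1:], y) + gap,
                   nw(x, y[1:]) + gap)

    best = 0.0
    for i1, i2 in combinations(range(len(a) + 1), 2):
        for j1, j2 in combinations(range(len(b) + 1), 2):
            best = max(best, nw(a[i1:i2], b[j1:j2]))
    return best


def lcs3(a: str, b: str, c: str) -> int:
    """Length of the longest common subsequence of three strings — the
    maximum possible number of gap-free identical columns of any 3-way
    alignment of identical-scoring sequences."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, k: int) -> int:
        if i == len(a) or j == len(b) or k == len(c):
            return 0
        if a[i] == b[j] == c[k]:
            return 1 + rec(i + 1, j + 1, k + 1)
        return max(rec(i + 1, j, k), rec(i, j + 1, k), rec(i, j, k + 1))

    return rec(0, 0, 0)


def bidirectional_filter_bruteforce(hits, min_id, min_cov, max_ev):
    """Set-comprehension re-statement of the reciprocal-pass rule."""
    def ok(h):
        return (h.pct_identity >= min_id and h.query_cov >= min_cov
                and (h.evalue is None or h.evalue <= max_ev))

    by_dir = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in by_dir or h.score > by_dir[key].score:
            by_dir[key] = h
    return {
        frozenset((q, s))
        for (q, s), h in by_dir.items()
        if (s, q) in by_dir and ok(h) and ok(by_dir[(s, q)])
    }


def screen_bruteforce(binary_rows, pos_idx, neg_idx, min_pos, max_neg):
    """Row-wise re-implementation of the presence screen on a 0/1 matrix
    given as a dict row_id -> tuple of ints."""
    return {
        rid for rid, row in binary_rows.items()
        if sum(row[i] for i in pos_idx) >= min_pos
        and sum(row[i] for i in neg_idx) <= max_neg
    }


def pan_core_exhaustive(binary):
    """Mean pan/core curves by enumerating every genome ordering of a
    families x genomes 0/1 matrix (list of row tuples)."""
    n = len(binary[0])
    pans = []
    cores = []
    for order in permutations(range(n)):
        pan_row, core_row = [], []
        for k in range(1, n + 1):
            cols = order[:k]
            pan_row.append(sum(1 for row in binary
                               if any(row[c] for c in cols)))
            core_row.append(sum(1 for row in binary
                                if all(row[c] for c in cols)))
        pans.append(pan_row)
        cores.append(core_row)
    m = len(pans)
    mean_pan = [sum(p[k] for p in pans) / m for k in range(n)]
    mean_core = [sum(c[k] for c in cores) / m for k in range(n)]
    return mean_pan, mean_core


def tree_distance_matrix(newick: str):
    """Leaf-to-leaf path-length matrix of a newick tree (additive metric),
    via dendropy's independent path computation."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = [[pdm.patristic_distance(t1, t2) for t2 in taxa] for t1 in taxa]
    return labels, mat
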