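"""Single-copy-core supertree machinery.

Per-family center-star protein alignments are stripped of every column
containing a gap (the "ungapped" convention that makes variable-length
orthologs concatenable), concatenated into a supermatrix, converted to
p-distances (fraction of differing columns) and resolved with canonical
neighbor joining. Column-resampling bootstrap attaches integer supports to
internal edges; the tree is rooted at the midpoint of the outgroup's
pendant edge. Trees are dendropy objects throughout, so standard Newick
output and bipartition handling come for free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from brevipan.clustering import GeneFamily
from brevipan.config import RunConfig
from brevipan.records import GAP

logger = logging.getLogger(__name__)


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over the amino-acid alphabet + gap."""

    taxa: list[str]
    rows: np.ndarray  # (n_taxa, n_cols) uint8
    family_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.taxa):
            raise ValueError("row/taxa shape mismatch")
        if not self.family_lengths:
            self.family_lengths = [self.rows.shape[1]]

    @property
    def length(self) -> int:
        return int(self.rows.shape[1])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)].tobytes().decode()

    @classmethod
    def from_strings(cls, taxa: list[str], rows: list[str],
                     family_lengths: list[int] | None = None
                     ) -> "MultipleAlignment":
        if len({len(r) for r in rows}) > 1:
            raise ValueError("aligned rows differ in length")
        arr = (np.frombuffer("".join(rows).encode(), dtype=np.uint8)
               .reshape(len(rows), -1).copy()
               if rows and rows[0] else
               np.empty((len(rows), 0), dtype=np.uint8))
        return cls(taxa=list(taxa), rows=arr,
                   family_lengths=family_lengths or [])


def select_single_copy_core(
    families: list[GeneFamily], genome_ids: list[str]
) -> list[GeneFamily]:
    """Families with exactly one member in every genome (outgroup included)."""
    out = [
        fam for fam in families
        if all(fam.count_in(g) == 1 for g in genome_ids)
        and fam.genomes <= set(genome_ids)
    ]
    if not out:
        raise ValueError(
            "no universal single-copy families; relax similarity thresholds "
            "or check the genome set")
    return out


def _global_aligner(config: RunConfig | None,
                    scoring: str = "matrix") -> Align.PairwiseAligner:
    config = config or RunConfig()
    al = Align.PairwiseAligner()
    al.mode = "global"
    if scoring == "identity":
        al.match_score = 1.0
        al.mismatch_score = -1.0
        al.open_gap_score = -1.0
        al.extend_gap_score = -1.0
    else:
        al.substitution_matrix = substitution_matrices.load(
            config.substitution_matrix)
        al.open_gap_score = -config.gap_open
        al.extend_gap_score = -config.gap_extend
    return al


def align_family(
    sequences: dict[str, str],
    config: RunConfig | None = None,
    scoring: str = "matrix",
    aligner: Align.PairwiseAligner | None = None,
) -> MultipleAlignment:
    """Center-star progressive alignment followed by gap-column removal.

    The center is the sequence maximizing summed pairwise global alignment
    score (ties break on taxon label); other sequences are merged via their
    pairwise alignment to the center under "once a gap, always a gap". All
    columns containing a gap are then removed, so the result is strictly
    gap-free (possibly empty, with a warning).
    """
    if any(not s for s in sequences.values()):
        raise ValueError("empty sequence in family")
    taxa = sorted(sequences)
    if len(taxa) == 1:
        return MultipleAlignment.from_strings(taxa, [sequences[taxa[0]]])
    if aligner is None:
        aligner = _global_aligner(config, scoring)
    # pick the center
    score_sum = {t: 0.0 for t in taxa}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            s = aligner.score(sequences[a], sequences[b])
            score_sum[a] += s
            score_sum[b] += s
    center = min(taxa, key=lambda t: (-score_sum[t], t))
    c_seq = sequences[center]
    L = len(c_seq)

    # pairwise alignments to the center: per sequence, insertions before
    # each center position plus the residue (or gap) aligned to it
    others = [t for t in taxa if t != center]
    ins: dict[str, list[str]] = {}
    match: dict[str, list[str]] = {}
    for t in others:
        aln = aligner.align(c_seq, sequences[t])[0]
        gc, gs = str(aln[0]), str(aln[1])
        cur_ins: list[str] = [""] * (L + 1)
        cur_match: list[str] = [GAP] * L
        ci = 0
        for x, y in zip(gc, gs):
            if x == GAP:
                cur_ins[ci] += y
            else:
                cur_match[ci] = y
                ci += 1
        ins[t] = cur_ins
        match[t] = cur_match

    max_ins = [max((len(ins[t][i]) for t in others), default=0)
               for i in range(L + 1)]
    rows: dict[str, list[str]] = {t: [] for t in taxa}
    for i in range(L + 1):
        for t in taxa:
            block = "" if t == center else ins[t][i]
            rows[t].append(block + GAP * (max_ins[i] - len(block)))
        if i < L:
            rows[center].append(c_seq[i])
            for t in others:
                rows[t].append(match[t][i])
    full = {t: "".join(rows[t]) for t in taxa}

    # remove every column containing a gap
    arr = (np.frombuffer("".join(full[t] for t in taxa).encode(),
                         dtype=np.uint8)
           .reshape(len(taxa), -1))
    keep = ~(arr == ord(GAP)).any(axis=0)
    out = arr[:, keep].copy()
    if out.shape[1] == 0:
        logger.warning("family alignment has no conserved columns")
    return MultipleAlignment(taxa=taxa, rows=out)


def concatenate(alignments: list[MultipleAlignment]) -> MultipleAlignment:
    """Row-wise concatenation into a supermatrix, keeping per-family column
    provenance for the block bootstrap."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa = alignments[0].taxa
    for msa in alignments[1:]:
        if msa.taxa != taxa:
            raise ValueError("taxon sets differ between alignments")
    rows = np.concatenate([msa.rows for msa in alignments], axis=1)
    lengths = [msa.length for msa in alignments]
    return MultipleAlignment(taxa=list(taxa), rows=rows,
                             family_lengths=lengths)


def p_distance(msa: MultipleAlignment) -> pd.DataFrame:
    """Fraction of differing columns between every pair of rows."""
    if msa.length < 1:
        raise ValueError("alignment of length 0")
    arr = msa.rows
    n = len(msa.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i + 1:] != arr[i]).mean(axis=1)
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return pd.DataFrame(d, index=msa.taxa, columns=msa.taxa)


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou-Nei).

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch; ties in the Q matrix break on the lexicographically
    smallest (label, label) pair. The returned tree is unrooted with a
    trifurcating seed node.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    names: list[str] = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
        names.append(lab)

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))),
        )
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        new.add_child(ni)
        new.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        dn = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = dn[keep]
        d[:-1, -1] = dn[keep]
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # final three-point closed form
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = tree.seed_node
    for node, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree.is_rooted = False
    return tree


def _pdist_from_array(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i + 1:] != arr[i]).mean(axis=1)
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return d


def bootstrap(
    msa: MultipleAlignment,
    reps: int = 1000,
    seed: int = 0,
    per_family_blocks: bool = False,
    support_display_min: int = 250,
) -> tuple[dendropy.Tree, list[str]]:
    """NJ tree with integer bootstrap supports on internal edges.

    Columns are resampled with replacement ``reps`` times (uniformly by
    default, or whole per-family blocks) and the tree rebuilt per
    replicate; the support of an internal edge is the number of replicates
    containing its bipartition. Returns the annotated tree and the list of
    internal edges flagged below ``support_display_min`` (flagged, not
    removed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if msa.length < 1:
        raise ValueError("alignment shorter than 1 column")
    rng = np.random.default_rng(seed)
    main = neighbor_joining(p_distance(msa))
    main.encode_bipartitions()
    counts: dict[int, int] = {}
    L = msa.length
    bounds = np.cumsum([0] + msa.family_lengths)
    for _ in range(reps):
        if per_family_blocks:
            picks = rng.integers(0, len(msa.family_lengths),
                                 size=len(msa.family_lengths))
            cols = np.concatenate(
                [np.arange(bounds[p], bounds[p + 1]) for p in picks])
        else:
            cols = rng.integers(0, L, size=L)
        arr = msa.rows[:, cols]
        rep_dist = pd.DataFrame(_pdist_from_array(arr), index=msa.taxa,
                                columns=msa.taxa)
        rep_tree = neighbor_joining(rep_dist)
        rep_tree.migrate_taxon_namespace(main.taxon_namespace)
        rep_tree.encode_bipartitions()
        for edge in rep_tree.preorder_edge_iter():
            key = edge.bipartition.split_bitmask
            counts[key] = counts.get(key, 0) + 1
    flagged: list[str] = []
    for edge in main.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head is main.seed_node:
            continue
        support = counts.get(edge.bipartition.split_bitmask, 0)
        head.label = str(support)
        if support < support_display_min:
            flagged.append(
                f"{head.label}:{sorted(t.label for t in edge.bipartition.leafset_taxa(main.taxon_namespace))}")
    return main, flagged


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root at the midpoint of the outgroup's pendant edge."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_id:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_id!r} not found in tree")
    elen = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=elen / 2, length2=elen / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def supertree(
    families: list[GeneFamily],
    sequences: dict[str, str],
    genome_ids: list[str],
    outgroup: str | None = None,
    reps: int = 1000,
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[dendropy.Tree, list[str]]:
    """End-to-end single-copy-core supertree.

    Selects universal single-copy families, aligns each (center-star,
    ungapped), concatenates, and runs bootstrapped NJ; roots on the
    outgroup when given.
    """
    config = config or RunConfig()
    sc = select_single_copy_core(families, genome_ids)
    alignments = []
    for fam in sc:
        per_taxon = {g: sequences[fam.members[g][0]] for g in genome_ids}
        msa = align_family(per_taxon, config)
        if msa.length:
            alignments.append(msa)
    if not alignments:
        raise ValueError("no aligned columns across single-copy families")
    supermatrix = concatenate(alignments)
    tree, flagged = bootstrap(
        supermatrix, reps=reps, seed=seed,
        support_display_min=config.support_display_min)
    if outgroup is not None:
        tree = root_with_outgroup(tree, outgroup)
    return tree, flagged
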