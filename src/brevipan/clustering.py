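"""Similarity graph, Markov clustering (MCL) and gene-family classification.

MCL is implemented in-package with the numerics pinned down for
determinism: self-loops at the node's maximum incident weight (min 1e-3),
column normalization, expansion by matrix squaring, entrywise inflation,
pruning below ``prune_threshold`` with renormalization, convergence when
the largest entry change drops below ``epsilon``. Clustering a disjoint
union of graphs equals the union of per-component clusterings, so the
iteration runs independently per connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from brevipan.records import ProteinRecord

logger = logging.getLogger(__name__)

CLASS_LABELS = ("core_single", "core_multi", "dispensable", "unique")


@dataclass
class GeneFamily:
    """An MCL cluster with members grouped by genome."""

    family_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    family_class: str | None = None

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def genomes(self) -> set[str]:
        return set(self.members)

    def count_in(self, genome_id: str) -> int:
        return len(self.members.get(genome_id, []))


def build_graph(
    qualified_pairs: dict[tuple[str, str], float],
    all_gene_ids: list[str] | None = None,
) -> nx.Graph:
    """Undirected weighted similarity graph from qualified pairs.

    ``all_gene_ids`` adds isolated nodes for genes without any qualified
    partner (they become singleton families).
    """
    g = nx.Graph()
    if all_gene_ids is not None:
        g.add_nodes_from(all_gene_ids)
    for (a, b), w in qualified_pairs.items():
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if w <= 0:
            raise ValueError(f"non-positive weight on ({a}, {b})")
        g.add_edge(a, b, weight=w)
    return g


def _mcl_component(
    nodes: list[str],
    graph: nx.Graph,
    inflation: float,
    max_iterations: int,
    epsilon: float,
    prune_threshold: float,
    validate: bool = False,
) -> list[set[str]]:
    n = len(nodes)
    if n == 1:
        return [set(nodes)]
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.subgraph(nodes).edges(data=True):
        w = data["weight"]
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    # self-loops: max incident weight, floor 1e-3
    np.fill_diagonal(m, np.maximum(m.max(axis=0), 1e-3))

    def normalize(x: np.ndarray) -> np.ndarray:
        colsum = x.sum(axis=0)
        colsum[colsum == 0.0] = 1.0
        x = x / colsum
        if validate:
            assert np.all(np.abs(x.sum(axis=0) - 1.0) < 1e-9), \
                "column stochasticity violated"
        return x

    m = normalize(m)
    converged = False
    for _ in range(max_iterations):
        prev = m
        m = normalize(m @ m)             # expansion
        m = normalize(np.power(m, inflation))  # inflation
        m[m < prune_threshold] = 0.0     # pruning
        m = normalize(m)
        if np.max(np.abs(m - prev)) < epsilon:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations on a %d-node component; "
            "interpreting current matrix", max_iterations, n)

    # attractors: nodes with positive diagonal mass; each node joins the
    # cluster of the lexicographically smallest attractor that attracts it
    attractors = [i for i in range(n) if m[i, i] > prune_threshold]
    if not attractors:
        attractors = list(range(n))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    # merge attractors sharing any support (nodes sharing an attractor row)
    for i in attractors:
        for j in np.nonzero(m[i] > 0)[0]:
            if j in attractors:
                union(i, int(j))
    assignment: dict[int, int] = {}
    for j in range(n):
        attracting = [i for i in attractors if m[i, j] > 0]
        if not attracting:
            assignment[j] = -j - 1  # unattracted: own singleton
        else:
            # deterministic tie-break: lexicographically smallest attractor
            best = min(attracting, key=lambda i: nodes[i])
            assignment[j] = find(best)
    clusters: dict[int, set[str]] = {}
    for j, c in assignment.items():
        clusters.setdefault(c, set()).add(nodes[j])
    return list(clusters.values())


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iterations: int = 100,
    epsilon: float = 1e-6,
    prune_threshold: float = 1e-5,
    validate: bool = False,
) -> list[set[str]]:
    """Markov clustering of a weighted similarity graph.

    Returns a partition (every node in exactly one cluster), deterministic
    given node ids: nodes are processed in sorted order and clusters are
    returned sorted by their smallest member.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    out: list[set[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        out.extend(_mcl_component(nodes, graph, inflation, max_iterations,
                                  epsilon, prune_threshold, validate))
    out.sort(key=lambda c: min(c))
    return out


def build_families(
    partition: list[set[str]], records: list[ProteinRecord]
) -> list[GeneFamily]:
    """One GeneFamily per cluster, members grouped by genome.

    Family ids are assigned in order of each cluster's smallest gene id.
    """
    genome_of = {r.gene_id: r.genome_id for r in records}
    seen: set[str] = set()
    families: list[GeneFamily] = []
    for idx, cluster in enumerate(sorted(partition, key=min), 1):
        fam = GeneFamily(family_id=f"F{idx:05d}")
        for gene in sorted(cluster):
            if gene not in genome_of:
                raise KeyError(f"gene {gene!r} in partition but not in records")
            if gene in seen:
                raise ValueError(f"gene {gene!r} appears in two clusters")
            seen.add(gene)
            fam.members.setdefault(genome_of[gene], []).append(gene)
        families.append(fam)
    return families


def classify_families(
    families: list[GeneFamily], all_genome_ids: list[str]
) -> dict[str, int]:
    """Label families in place and return per-class summary counts.

    core_single: exactly one member in every genome; core_multi: at least
    one in every genome, two or more somewhere; unique: members in exactly
    one genome; dispensable: everything else. The summary also reports
    ``core`` = core_single + core_multi and ``n_families``.
    """
    if not all_genome_ids:
        raise ValueError("empty genome list")
    universe = set(all_genome_ids)
    counts = {label: 0 for label in CLASS_LABELS}
    for fam in families:
        extra = fam.genomes - universe
        if extra:
            raise ValueError(
                f"{fam.family_id}: genomes {sorted(extra)} not in genome list")
        sizes = [fam.count_in(g) for g in all_genome_ids]
        if all(s >= 1 for s in sizes):
            label = "core_single" if all(s == 1 for s in sizes) else "core_multi"
        elif sum(1 for s in sizes if s >= 1) == 1:
            label = "unique"
        else:
            label = "dispensable"
        fam.family_class = label
        counts[label] += 1
    counts["core"] = counts["core_single"] + counts["core_multi"]
    counts["n_families"] = len(families)
    return counts


def representative_products(
    families: list[GeneFamily], records: list[ProteinRecord]
) -> dict[str, str]:
    """Most common member product per family; ties break lexicographically."""
    product_of = {r.gene_id: r.product for r in records}
    out: dict[str, str] = {}
    for fam in families:
        tally: dict[str, int] = {}
        for genes in fam.members.values():
            for g in genes:
                p = product_of[g]
                tally[p] = tally.get(p, 0) + 1
        out[fam.family_id] = min(
            tally, key=lambda p: (-tally[p], p))
    return out


def write_families(families: list[GeneFamily], path: str) -> None:
    rows = []
    for fam in families:
        for genome in sorted(fam.members):
            for gene in fam.members[genome]:
                rows.append({
                    "family_id": fam.family_id,
                    "class": fam.family_class or "",
                    "genome_id": genome,
                    "gene_id": gene,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_families(path: str) -> list[GeneFamily]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fams: dict[str, GeneFamily] = {}
    for fam_id, cls, genome_id, gene_id in df.itertuples(index=False):
        fam = fams.setdefault(
            fam_id, GeneFamily(family_id=fam_id, family_class=cls or None))
        fam.members.setdefault(genome_id, []).append(gene_id)
    return [fams[k] for k in sorted(fams)]
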