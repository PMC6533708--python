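"""Plasmid gene-content sharedness and uniqueness classification.

Plasmid similarity is gene-content based: the directional similarity
sim(p, q) is the fraction of p's genes that have a qualified similarity
partner on q (or share a gene family with a gene of q). A plasmid is
*unique* when its best sharedness with any other plasmid — taking the
larger of the two directions — stays below the unique threshold (default
0.10); a pair is *similar* when both directions reach the similar threshold
(default 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from brevipan.clustering import GeneFamily
from brevipan.records import ProteinRecord


@dataclass
class PlasmidProfile:
    """Gene and family content of one plasmid replicon."""

    plasmid_id: str   # genome_id:replicon_id
    genome_id: str
    gene_ids: list[str] = field(default_factory=list)
    family_ids: set[str] = field(default_factory=set)


def build_plasmid_profiles(
    records: list[ProteinRecord],
    families: list[GeneFamily] | None = None,
) -> list[PlasmidProfile]:
    fam_of: dict[str, str] = {}
    if families is not None:
        for fam in families:
            for genes in fam.members.values():
                for g in genes:
                    fam_of[g] = fam.family_id
    profiles: dict[str, PlasmidProfile] = {}
    for r in records:
        if r.replicon_type != "plasmid":
            continue
        pid = f"{r.genome_id}:{r.replicon_id}"
        prof = profiles.setdefault(
            pid, PlasmidProfile(plasmid_id=pid, genome_id=r.genome_id))
        prof.gene_ids.append(r.gene_id)
        if r.gene_id in fam_of:
            prof.family_ids.add(fam_of[r.gene_id])
    return [profiles[k] for k in sorted(profiles)]


def plasmid_similarity(
    p: PlasmidProfile,
    q: PlasmidProfile,
    qualified_pairs: dict[tuple[str, str], float] | None = None,
    gene_to_family: dict[str, str] | None = None,
) -> float:
    """Directional fraction of p's genes with a qualifying partner on q."""
    if p.plasmid_id == q.plasmid_id:
        raise ValueError("plasmid compared against itself")
    if not p.gene_ids:
        raise ValueError(f"plasmid {p.plasmid_id} has no genes")
    q_genes = set(q.gene_ids)
    q_fams = ({gene_to_family[g] for g in q.gene_ids if g in gene_to_family}
              if gene_to_family else set())
    n = 0
    for g in p.gene_ids:
        if gene_to_family and gene_to_family.get(g) in q_fams:
            n += 1
            continue
        if qualified_pairs is not None and any(
            (tuple(sorted((g, h))) in qualified_pairs) for h in q_genes
        ):
            n += 1
    return n / len(p.gene_ids)


def classify_plasmids(
    profiles: list[PlasmidProfile],
    qualified_pairs: dict[tuple[str, str], float] | None = None,
    gene_to_family: dict[str, str] | None = None,
    similar_threshold: float = 0.90,
    unique_threshold: float = 0.10,
) -> tuple[pd.DataFrame, list[str], list[tuple[str, str]]]:
    """All directional similarities, unique plasmids, and similar pairs.

    Returns (similarity matrix as DataFrame with sim(row, col), list of
    unique plasmid ids, list of similar (p, q) pairs with p < q).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 plasmids")
    ids = [p.plasmid_id for p in profiles]
    sim = pd.DataFrame(0.0, index=ids, columns=ids)
    for p in profiles:
        for q in profiles:
            if p.plasmid_id == q.plasmid_id:
                sim.loc[p.plasmid_id, q.plasmid_id] = 1.0
                continue
            sim.loc[p.plasmid_id, q.plasmid_id] = plasmid_similarity(
                p, q, qualified_pairs, gene_to_family)
    unique: list[str] = []
    for pid in ids:
        others = [o for o in ids if o != pid]
        best = max(max(sim.loc[pid, o], sim.loc[o, pid]) for o in others)
        if best < unique_threshold:
            unique.append(pid)
    similar: list[tuple[str, str]] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if min(sim.loc[a, b], sim.loc[b, a]) >= similar_threshold:
                similar.append((a, b))
    return sim, unique, similar
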