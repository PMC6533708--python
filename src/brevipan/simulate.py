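"""Synthetic pan-genome generator with known ground truth.

Emulates a multi-genome protein universe with a planted family structure:
core families (every genome), shell families (a genome-frequency spectrum),
cloud/unique families (one genome each) and niche families planted to be
present in at least ``niche_min_pos`` spoiler genomes and absent from every
non-spoiler — the pattern the presence/absence screens look for. Family
members are independently mutated copies of a per-family ancestor protein
(star phylogeny); an optional guide-tree mode accumulates substitutions
along the branches of a fixed tree instead, for phylogeny validation.

Shell families are always planted with at least one non-spoiler carrier so
that only niche families can satisfy a spoiler-specific screen; the
expected per-site identity between two genome copies of one family is
(1-r)^2 + r^2/19 for substitution rate r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from brevipan.records import AMINO_ACIDS, GenomeMeta, ProteinRecord

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_NICHE_LABELS = ("silage", "food", "gut", "brewery")


@dataclass
class SimSpec:
    """Study conditions of a simulated pan-genome.

    ``substitution_rate`` is the per-site amino-acid replacement
    probability from the family ancestor to each genome copy;
    ``paralog_prob`` is the per family per genome probability of one
    duplicated (re-mutated) member; ``plasmid_frac`` the fraction of genes
    assigned to plasmid replicons. ``shell_spectrum``, when given, is a
    list of occupancy fractions in (0,1) sampled per shell family;
    otherwise occupancies are uniform over 2..n_genomes-1.
    """

    n_genomes: int = 12
    n_spoilers: int = 7
    n_core_families: int = 800
    n_shell_families: int = 300
    n_unique_per_genome: int = 5
    n_niche_families: int = 20
    niche_min_pos: int = 4
    shell_spectrum: list[float] | None = None
    paralog_prob: float = 0.0
    substitution_rate: float = 0.02
    mean_protein_len: float = 300.0
    sd_protein_len: float = 75.0
    min_protein_len: int = 50
    plasmid_frac: float = 0.2
    n_plasmids_per_genome: tuple[int, int] = (1, 4)
    niche_replicon: str = "chromosome"  # chromosome | plasmid | any
    hypothetical_frac: float = 0.2
    guide_tree: str | None = None  # newick; branch lengths are per-site
    #                                replacement probabilities
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_spoilers <= self.n_genomes:
            raise ValueError("n_spoilers must be <= n_genomes")
        if self.n_niche_families > 0 and self.niche_min_pos > self.n_spoilers:
            raise ValueError("infeasible: niche_min_pos > n_spoilers")
        if not 0.0 <= self.substitution_rate <= 0.5:
            raise ValueError("substitution_rate must be in [0, 0.5]")
        if self.n_shell_families > 0 and self.n_genomes < 3:
            raise ValueError("shell families need >= 3 genomes")
        if self.shell_spectrum is not None and any(
            not 0.0 < f < 1.0 for f in self.shell_spectrum
        ):
            raise ValueError("shell_spectrum fractions must be in (0,1)")
        if self.niche_replicon not in ("chromosome", "plasmid", "any"):
            raise ValueError(f"bad niche_replicon {self.niche_replicon!r}")


@dataclass
class SyntheticTruth:
    """Planted structure: gene -> family, family -> class, ancestors."""

    gene_to_family: dict[str, str] = field(default_factory=dict)
    family_class: dict[str, str] = field(default_factory=dict)
    family_ancestor: dict[str, str] = field(default_factory=dict)

    def families(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, f in self.gene_to_family.items():
            out.setdefault(f, set()).add(g)
        return out

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.family_class.values():
            counts[c] = counts.get(c, 0) + 1
        return counts

    def to_families(self, records) -> list:
        """Regroup emitted genes by planted family ids into GeneFamily
        objects (ground-truth clustering)."""
        from brevipan.clustering import GeneFamily

        genome_of = {r.gene_id: r.genome_id for r in records}
        fams: dict[str, GeneFamily] = {}
        for gene, fid in sorted(self.gene_to_family.items()):
            fam = fams.setdefault(fid, GeneFamily(family_id=fid))
            fam.members.setdefault(genome_of[gene], []).append(gene)
        return [fams[k] for k in sorted(fams)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "family_id": f,
             "family_class": self.family_class[f]}
            for g, f in sorted(self.gene_to_family.items())
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _seq_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def random_protein(length: int, rng: np.random.Generator) -> np.ndarray:
    return _AA[rng.integers(0, 20, size=length)]


def mutate_array(anc: np.ndarray, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Replace each site independently with probability ``rate`` by a
    uniformly chosen different residue."""
    if anc.size == 0:
        raise ValueError("empty ancestor sequence")
    out = anc.copy()
    mask = rng.random(anc.size) < rate
    n = int(mask.sum())
    if n:
        idx = np.searchsorted(_AA, out[mask])
        shifted = (idx + rng.integers(1, 20, size=n)) % 20
        out[mask] = _AA[shifted]
    return out


def mutate_sequence(ancestor: str, rate: float,
                    rng: np.random.Generator) -> str:
    """String-in/string-out wrapper around :func:`mutate_array`."""
    if not ancestor:
        raise ValueError("empty ancestor sequence")
    if not 0.0 <= rate <= 0.5:
        raise ValueError("rate must be in [0, 0.5]")
    return _seq_to_str(mutate_array(
        np.frombuffer(ancestor.encode(), dtype=np.uint8), rate, rng))


def expected_pairwise_identity(rate: float) -> float:
    """Expected per-site identity of two independent copies of one
    ancestor: both untouched, or both hit the same replacement."""
    return (1.0 - rate) ** 2 + rate**2 / 19.0


def _draw_length(spec: SimSpec, rng: np.random.Generator) -> int:
    ln = rng.normal(spec.mean_protein_len, spec.sd_protein_len)
    return max(spec.min_protein_len, int(round(ln)))


def _evolve_on_tree(tree: dendropy.Tree, anc: np.ndarray,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve ``anc`` along the guide tree; edge length = per-site
    replacement probability on that edge. Returns leaf sequences."""
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): anc}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            cur = anc
        else:
            p = min(max(node.edge.length or 0.0, 0.0), 0.5)
            cur = mutate_array(seqs[id(node.parent_node)], p, rng)
        seqs[id(node)] = cur
        if node.is_leaf():
            leaves[node.taxon.label] = cur
    return leaves


def simulate_pangenome(
    spec: SimSpec,
) -> tuple[list[ProteinRecord], list[GenomeMeta], SyntheticTruth]:
    """Generate an annotated protein universe with planted family truth.

    Deterministic: identical spec (including seed) gives byte-identical
    output. Genomes are ``G01..Gnn``; the first ``n_spoilers`` are the
    spoiler (niche-positive) group.
    """
    rng = np.random.default_rng(spec.seed)
    genomes = [f"G{i + 1:02d}" for i in range(spec.n_genomes)]
    spoilers = genomes[: spec.n_spoilers]
    non_spoilers = genomes[spec.n_spoilers:]

    guide = None
    if spec.guide_tree is not None:
        guide = dendropy.Tree.get(data=spec.guide_tree, schema="newick",
                                  preserve_underscores=True)
        taxa = {t.label for t in guide.taxon_namespace}
        if taxa != set(genomes):
            raise ValueError(
                f"guide tree taxa {sorted(taxa)} != genomes {genomes}")

    # --- plan family memberships -----------------------------------------
    plan: list[tuple[str, str, list[str]]] = []  # (family_id, class, genomes)
    fid = 0

    def next_id() -> str:
        nonlocal fid
        fid += 1
        return f"FAM{fid:05d}"

    for _ in range(spec.n_core_families):
        plan.append((next_id(), "core", list(genomes)))
    for _ in range(spec.n_shell_families):
        if spec.shell_spectrum is not None:
            frac = spec.shell_spectrum[
                int(rng.integers(0, len(spec.shell_spectrum)))]
            k = min(spec.n_genomes - 1, max(2, round(frac * spec.n_genomes)))
        else:
            k = int(rng.integers(2, spec.n_genomes))  # 2..n-1
        # force >=1 non-spoiler so only niche families are spoiler-specific
        while True:
            members = list(rng.choice(genomes, size=k, replace=False))
            if not non_spoilers or set(members) & set(non_spoilers):
                break
        plan.append((next_id(), "shell", sorted(members)))
    for g in genomes:
        for _ in range(spec.n_unique_per_genome):
            plan.append((next_id(), "unique", [g]))
    for _ in range(spec.n_niche_families):
        k = int(rng.integers(spec.niche_min_pos, spec.n_spoilers + 1))
        members = sorted(rng.choice(spoilers, size=k, replace=False))
        plan.append((next_id(), "niche", members))

    # --- per-genome plasmid layout ---------------------------------------
    lo, hi = spec.n_plasmids_per_genome
    n_plasmids = {g: int(rng.integers(lo, hi + 1)) for g in genomes}

    truth = SyntheticTruth()
    genes_by_genome: dict[str, list[tuple[str, str, str]]] = {
        g: [] for g in genomes
    }  # (gene_id, family_id, sequence)
    gene_replicon_class: dict[str, str] = {}

    for family_id, cls, members in plan:
        anc = random_protein(_draw_length(spec, rng), rng)
        truth.family_class[family_id] = cls
        truth.family_ancestor[family_id] = _seq_to_str(anc)
        if guide is not None:
            leaf_seqs = _evolve_on_tree(guide, anc, rng)
        for g in members:
            if guide is not None:
                seq = leaf_seqs[g]
            else:
                seq = mutate_array(anc, spec.substitution_rate, rng)
            copies = [seq]
            if spec.paralog_prob > 0 and rng.random() < spec.paralog_prob:
                base = leaf_seqs[g] if guide is not None else anc
                copies.append(
                    mutate_array(base, spec.substitution_rate, rng))
            for ci, cseq in enumerate(copies, 1):
                gene_id = f"{g}_{family_id}_{ci}"
                truth.gene_to_family[gene_id] = family_id
                genes_by_genome[g].append((gene_id, family_id,
                                           _seq_to_str(cseq)))
                if cls == "niche" and spec.niche_replicon != "any":
                    gene_replicon_class[gene_id] = spec.niche_replicon
                elif n_plasmids[g] > 0 and rng.random() < spec.plasmid_frac:
                    gene_replicon_class[gene_id] = "plasmid"
                else:
                    gene_replicon_class[gene_id] = "chromosome"

    # --- materialize records ----------------------------------------------
    records: list[ProteinRecord] = []
    metas: list[GenomeMeta] = []
    for gi, g in enumerate(genomes):
        spoiler = g in spoilers
        label = ("beer" if spoiler
                 else _NICHE_LABELS[gi % len(_NICHE_LABELS)])
        meta = GenomeMeta(genome_id=g, niche_label=label, spoiler=spoiler)
        cursors: dict[str, int] = {}
        for gene_id, family_id, seq in genes_by_genome[g]:
            rc = gene_replicon_class[gene_id]
            if rc == "plasmid" and n_plasmids[g] > 0:
                rep = f"{g}_p{int(rng.integers(1, n_plasmids[g] + 1))}"
            else:
                rep = f"{g}_chr"
            start = cursors.get(rep, 1)
            end = start + 3 * len(seq) + 2
            cursors[rep] = end + 51
            hypo = (truth.family_class[family_id] != "niche"
                    and rng.random() < spec.hypothetical_frac)
            product = ("hypothetical protein" if hypo
                       else f"{truth.family_class[family_id]} protein "
                            f"{family_id}")
            records.append(ProteinRecord(
                gene_id=gene_id, genome_id=g, replicon_id=rep,
                replicon_type=("plasmid" if rep != f"{g}_chr"
                               else "chromosome"),
                start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=product, sequence=seq,
            ))
        meta.replicon_lengths = {rep: c + 49 for rep, c in cursors.items()}
        metas.append(meta)
    return records, metas, truth
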