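"""Shipped transcriptions of the published per-genome summary table and the
chromosomal / plasmid beer-spoiler gene lists.

These small TSVs let the statistics and screen modules be exercised against
the printed values without re-running the genome-scale pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from brevipan.pancurve import PresenceAbsenceMatrix

#: The seven beer-spoiler strains heading the presence/absence gene lists.
SPOILER_STRAINS = (
    "TMW1.2108", "TMW1.2111", "TMW1.2112", "TMW1.2113",
    "UCCLB95", "UCCLBBS124", "UCCLBBS449",
)


def _path(name: str):
    return resources.files("brevipan.data") / name


def load_genome_summary() -> pd.DataFrame:
    """Per-genome chromosomal summary (19 strains), indexed by genome."""
    with resources.as_file(_path("table3_summary.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", index_col="genome_id")
    df["spoiler"] = df["spoiler"].astype(bool)
    return df


def _load_gene_list(name: str) -> tuple[PresenceAbsenceMatrix,
                                        dict[str, str], dict[str, str]]:
    with resources.as_file(_path(name)) as p:
        df = pd.read_csv(p, sep="\t", comment="#", index_col="family_id")
    products = df["product"].to_dict()
    categories = df["category"].to_dict()
    counts = df.drop(columns=["product", "category"]).astype(int)
    return (PresenceAbsenceMatrix(counts=counts, replicon_filter="all"),
            products, categories)


def load_spoiler_chromosome_genes():
    """58-gene chromosomal beer-spoiler list: (matrix, products, categories)."""
    return _load_gene_list("table5_matrix.tsv")


def load_spoiler_plasmid_genes():
    """25-gene plasmid-only beer-spoiler list: (matrix, products, categories)."""
    return _load_gene_list("table6_matrix.tsv")
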