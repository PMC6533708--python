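"""Group-contrast presence/absence screens and functional categorization.

The niche screen is a deterministic set rule: a gene family passes when it
is present in at least ``min_pos`` genomes of the positive group (e.g.
beer-spoiler strains) and in at most ``max_neg`` genomes of the negative
group (default 0, i.e. specifically absent from non-spoilers). Functional
categories are assigned by an ordered, configurable product-keyword map
(first matching rule wins) with a hypothetical/unknown fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from brevipan.pancurve import PresenceAbsenceMatrix

FALLBACK_CATEGORY = "hypothetical/unknown"


@dataclass
class ScreenSpec:
    positive: set[str]
    negative: set[str]
    min_pos: int = 4
    max_neg: int = 0

    def __post_init__(self) -> None:
        if not self.positive:
            raise ValueError("positive group is empty")
        if self.positive & self.negative:
            raise ValueError(
                f"groups overlap: {sorted(self.positive & self.negative)}")
        if self.min_pos < 1 or self.max_neg < 0:
            raise ValueError("min_pos must be >=1 and max_neg >=0")


@dataclass
class CategoryRules:
    """Ordered (category, keywords) rules; first match wins."""

    rules: list[tuple[str, list[str]]] = field(default_factory=list)
    fallback: str = FALLBACK_CATEGORY

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty category rules")

    def assign(self, product: str) -> str:
        p = product.lower()
        for category, keywords in self.rules:
            if any(kw.lower() in p for kw in keywords):
                return category
        return self.fallback

    @classmethod
    def from_yaml(cls, path: str) -> "CategoryRules":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(rules=[(d["category"], list(d["keywords"]))
                          for d in data["rules"]],
                   fallback=data.get("fallback", FALLBACK_CATEGORY))


#: Default product-keyword rules mirroring the functional groups commonly
#: reported for beer-adaptation gene lists. Order matters.
DEFAULT_RULES = CategoryRules(rules=[
    ("oxidoreduction", ["flavodoxin", "reductase", "peroxidase",
                        "short-chain dehydrogenase", "oxidase"]),
    ("transcription", ["transcriptional regulator", "sigma", "internalin",
                       "rna polymerase"]),
    ("transport", ["transporter", "permease", "antiporter", "pts",
                   "efflux"]),
    ("membrane_cell_surface", ["membrane protein", "cell surface",
                               "cell wall", "mucus-binding", "lpxtg",
                               "glycosyltransferase", "acyltransferase"]),
    ("mobilome", ["transposase", "mobilization", "relaxase", "prophage",
                  "integrase"]),
])


def screen(matrix: PresenceAbsenceMatrix, spec: ScreenSpec) -> list[str]:
    """Family ids passing the group-contrast presence rule.

    Ordered by descending positive-group occupancy, then family id.
    """
    missing = (spec.positive | spec.negative) - set(matrix.genome_ids)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    df = matrix.counts
    pos_cols = sorted(spec.positive)
    neg_cols = sorted(spec.negative)
    pos_n = (df[pos_cols] >= 1).sum(axis=1)
    neg_n = (df[neg_cols] >= 1).sum(axis=1) if neg_cols else 0
    hit = df.index[(pos_n >= spec.min_pos) & (neg_n <= spec.max_neg)]
    return sorted(hit, key=lambda f: (-int(pos_n[f]), f))


def strain_share(
    matrix: PresenceAbsenceMatrix, family_ids: list[str], genome_id: str
) -> tuple[int, float]:
    """How many of the listed families a genome carries (count, fraction)."""
    if genome_id not in matrix.counts.columns:
        raise ValueError(f"unknown genome {genome_id!r}")
    missing = set(family_ids) - set(matrix.counts.index)
    if missing:
        raise ValueError(f"families not in matrix: {sorted(missing)}")
    if not family_ids:
        return 0, 0.0
    count = int((matrix.counts.loc[list(family_ids), genome_id] >= 1).sum())
    return count, count / len(family_ids)


def categorize(
    products: dict[str, str], rules: CategoryRules = DEFAULT_RULES
) -> dict[str, tuple[int, float]]:
    """Assign one representative product per family to a category.

    Returns category -> (count, fraction of the family list). Categories
    with zero hits are omitted; fractions sum to 1 over assigned families.
    """
    counts: dict[str, int] = {}
    for product in products.values():
        cat = rules.assign(product)
        counts[cat] = counts.get(cat, 0) + 1
    total = len(products)
    return {c: (n, n / total) for c, n in sorted(counts.items())}
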