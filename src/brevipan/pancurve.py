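"""Pan/core-genome accumulation curves, curve fits and the open/closed call.

Pan size after k genomes is the number of gene families present in at least
one of the first k genomes of a random genome ordering; core size is the
number present in all k. The mean pan curve is fit with the power law
P(n) = a*n^b (log-log least squares) and the pan-genome is called *closed*
when the exponent b falls below a threshold (default 0.5); the mean core
curve is fit with the decaying exponential C(n) = c*exp(d*n) + k0, whose
offset k0 estimates the asymptotic core size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from brevipan.clustering import GeneFamily
from brevipan.records import ProteinRecord

logger = logging.getLogger(__name__)

REPLICON_FILTERS = ("all", "chromosome", "plasmid")

# below this many genomes every ordering is enumerated (7! = 5040)
ENUMERATE_MAX_ORDERINGS = 5040


@dataclass
class PresenceAbsenceMatrix:
    """Families x genomes member counts with replicon-filter provenance."""

    counts: pd.DataFrame          # int counts, families as rows
    replicon_filter: str = "all"

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    def binary(self) -> np.ndarray:
        return (self.counts.to_numpy() >= 1)


@dataclass
class PanCoreCurves:
    """Per-permutation pan/core trajectories plus fits and verdict."""

    orderings: list[tuple[str, ...]]
    pan: np.ndarray    # (n_orderings, n_genomes)
    core: np.ndarray
    exhaustive: bool = False
    pan_fit: tuple[float, float] | None = None          # (a, b)
    core_fit: tuple[float, float, float] | None = None  # (c, d, k0)
    verdict: str | None = None
    threshold: float | None = None

    @property
    def mean_pan(self) -> np.ndarray:
        return self.pan.mean(axis=0)

    @property
    def mean_core(self) -> np.ndarray:
        return self.core.mean(axis=0)

    @property
    def median_pan(self) -> np.ndarray:
        return np.median(self.pan, axis=0)

    @property
    def median_core(self) -> np.ndarray:
        return np.median(self.core, axis=0)

    def new_genes(self) -> np.ndarray:
        """Mean number of new families contributed by the k-th genome."""
        return np.diff(self.mean_pan)


def build_presence_matrix(
    families: list[GeneFamily],
    records: list[ProteinRecord],
    replicon_filter: str = "all",
    genome_ids: list[str] | None = None,
) -> PresenceAbsenceMatrix:
    """Materialize family membership counts on replicons passing the filter.

    Rows that become all-zero under a chromosome/plasmid filter are dropped
    (logged with a count).
    """
    if replicon_filter not in REPLICON_FILTERS:
        raise ValueError(f"unknown replicon filter {replicon_filter!r}")
    rtype = {r.gene_id: r.replicon_type for r in records}
    if genome_ids is None:
        genome_ids = sorted({r.genome_id for r in records})
    data = np.zeros((len(families), len(genome_ids)), dtype=int)
    gidx = {g: i for i, g in enumerate(genome_ids)}
    for fi, fam in enumerate(families):
        for genome, genes in fam.members.items():
            n = sum(
                1 for g in genes
                if replicon_filter == "all" or rtype[g] == replicon_filter
            )
            data[fi, gidx[genome]] = n
    df = pd.DataFrame(data, index=[f.family_id for f in families],
                      columns=genome_ids)
    keep = df.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("presence matrix (%s): dropped %d all-zero rows",
                    replicon_filter, n_dropped)
    return PresenceAbsenceMatrix(counts=df.loc[keep],
                                 replicon_filter=replicon_filter)


def accumulation(
    matrix: PresenceAbsenceMatrix,
    n_permutations: int = 100,
    seed: int = 0,
) -> PanCoreCurves:
    """Pan/core trajectories over genome-order permutations.

    When the total number of orderings is at most 5040 (7 genomes) all
    orderings are enumerated instead of sampled.
    """
    genomes = matrix.genome_ids
    n = len(genomes)
    if n < 2:
        raise ValueError("accumulation needs at least 2 genomes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    present = matrix.binary()  # families x genomes
    exhaustive = math.factorial(n) <= ENUMERATE_MAX_ORDERINGS
    if exhaustive:
        orderings = [tuple(p) for p in permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        orderings = [tuple(rng.permutation(n)) for _ in range(n_permutations)]
    pan = np.empty((len(orderings), n), dtype=int)
    core = np.empty((len(orderings), n), dtype=int)
    for oi, order in enumerate(orderings):
        cum = np.cumsum(present[:, list(order)], axis=1)
        pan[oi] = (cum >= 1).sum(axis=0)
        core[oi] = (cum == np.arange(1, n + 1)).sum(axis=0)
    named = [tuple(genomes[i] for i in order) for order in orderings]
    return PanCoreCurves(orderings=named, pan=pan, core=core,
                         exhaustive=exhaustive)


def fit_pan_powerlaw(
    curves: PanCoreCurves, threshold: float = 0.5,
    use: str = "mean",
) -> tuple[float, float, str]:
    """Fit P(n) = a*n^b to the central pan curve by log-log regression.

    Returns (a, b, verdict); verdict is ``closed`` iff b < threshold.
    """
    y = curves.mean_pan if use == "mean" else curves.median_pan
    if len(y) < 3:
        raise ValueError("pan curve must have length >= 3")
    if np.any(y <= 0):
        raise ValueError("pan curve values must be positive")
    n = np.arange(1, len(y) + 1)
    res = stats.linregress(np.log(n), np.log(y))
    a, b = math.exp(res.intercept), res.slope
    verdict = "closed" if b < threshold else "open"
    curves.pan_fit = (a, b)
    curves.verdict = verdict
    curves.threshold = threshold
    return a, b, verdict


def fit_core_exponential(
    curves: PanCoreCurves, use: str = "mean",
) -> tuple[float, float, float]:
    """Fit C(n) = c*exp(d*n) + k0 to the central core curve.

    Initialized from (C(1) - C(max), a log-slope estimate, C(max)); the
    offset k0 is the asymptotic core-genome estimate.
    """
    y = np.asarray(curves.mean_core if use == "mean" else curves.median_core,
                   dtype=float)
    if len(y) < 4:
        raise ValueError("core curve must have length >= 4")
    n = np.arange(1, len(y) + 1, dtype=float)
    c0 = y[0] - y[-1]
    if c0 > 0 and y[1] - y[-1] > 0:
        d0 = min(-1e-3, math.log((y[1] - y[-1]) / c0))
    else:
        d0 = -0.5
    p0 = (max(c0, 1e-6), d0, y[-1])

    def model(x, c, d, k0):
        return c * np.exp(d * x) + k0

    try:
        popt, _ = optimize.curve_fit(model, n, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - fit failure path
        resid = y - model(n, *p0)
        raise RuntimeError(
            f"core exponential fit failed (init {p0}, residuals {resid})"
        ) from exc
    c, d, k0 = (float(v) for v in popt)
    curves.core_fit = (c, d, k0)
    return c, d, k0


def new_gene_rate(curves: PanCoreCurves, first_k: int) -> float:
    """Mean new genes per added genome over additions 2..first_k+1 of the
    central pan curve."""
    diffs = curves.new_genes()
    if first_k < 1 or first_k > len(diffs):
        raise ValueError(f"window {first_k} exceeds curve length {len(diffs)}")
    return float(diffs[:first_k].mean())


def write_curves(curves: PanCoreCurves, path: str) -> None:
    n = curves.pan.shape[1]
    df = pd.DataFrame({
        "k": np.arange(1, n + 1),
        "pan_mean": curves.mean_pan,
        "pan_median": curves.median_pan,
        "core_mean": curves.mean_core,
        "core_median": curves.median_core,
    })
    df.to_csv(path, sep="\t", index=False)
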