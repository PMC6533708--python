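"""All-against-all protein similarity and the bidirectional filter.

The internal aligner is affine-gap Smith-Waterman (via Bio.Align's
PairwiseAligner) under BLOSUM62 with gap open 11 / extend 1, so ingested
BLAST tabular hits and internal hits are comparable. No E-value is computed
internally; the E-value criterion applies only to ingested hits.

A k-mer prefilter (default k=4) skips pairs sharing fewer than an adaptive
minimum number of distinct k-mers before any alignment is attempted; the
threshold scales with sequence length (``prefilter_frac``) and degenerates
to "share at least one k-mer" for short sequences, so pairs that would pass
the 30 %/80 % filter at moderate divergence are never lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import sparse

from brevipan.config import RunConfig
from brevipan.records import ProteinRecord, SimilarityHit

logger = logging.getLogger(__name__)


@dataclass
class AlignmentResult:
    """A local pairwise alignment: gapped strings plus summary statistics."""

    aligned_query: str
    aligned_subject: str
    matches: int
    aln_length: int
    score: float
    query_cov: float
    subject_cov: float

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.matches / self.aln_length if self.aln_length else 0.0


def make_aligner(config: RunConfig | None = None) -> Align.PairwiseAligner:
    config = config or RunConfig()
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        config.substitution_matrix)
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _stats_from_coordinates(
    a: str, b: str, coords: np.ndarray, score: float
) -> tuple[int, int, float, float]:
    """(matches, aln_length, query_cov, subject_cov) from an alignment's
    block-coordinate array."""
    dq = np.diff(coords[0])
    ds = np.diff(coords[1])
    aln_length = int(np.maximum(dq, ds).sum())
    qa = np.frombuffer(a.encode(), dtype=np.uint8)
    sa = np.frombuffer(b.encode(), dtype=np.uint8)
    matches = 0
    for k in range(len(dq)):
        if dq[k] and ds[k]:  # diagonal block
            q0, q1 = coords[0, k], coords[0, k + 1]
            s0 = coords[1, k]
            matches += int((qa[q0:q1] == sa[s0:s0 + (q1 - q0)]).sum())
    qcov = (coords[0, -1] - coords[0, 0]) / len(a)
    scov = (coords[1, -1] - coords[1, 0]) / len(b)
    return matches, aln_length, float(qcov), float(scov)


def align_pair(
    a: str, b: str, config: RunConfig | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Identity is matches over alignment columns (gaps included); coverage of
    each sequence is the aligned span over its full length.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    if aligner is None:
        aligner = make_aligner(config)
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:
        # no positive-scoring local alignment exists: the optimum is empty
        return AlignmentResult(aligned_query="", aligned_subject="",
                               matches=0, aln_length=0, score=0.0,
                               query_cov=0.0, subject_cov=0.0)
    coords = aln.coordinates
    matches, aln_length, qcov, scov = _stats_from_coordinates(
        a, b, coords, aln.score)
    gapped_q, gapped_s = str(aln[0]), str(aln[1])
    return AlignmentResult(
        aligned_query=gapped_q, aligned_subject=gapped_s,
        matches=matches, aln_length=aln_length, score=float(aln.score),
        query_cov=qcov, subject_cov=scov,
    )


def _kmer_candidate_pairs(
    seqs: list[str], k: int, frac: float
) -> np.ndarray:
    """Index pairs (i < j) sharing at least max(1, ceil(frac * min(#kmers)))
    distinct k-mers."""
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    n_kmers = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        kms = {s[j:j + k] for j in range(len(s) - k + 1)}
        n_kmers[i] = len(kms)
        idx = np.fromiter(
            (vocab.setdefault(km, len(vocab)) for km in kms),
            dtype=np.int64, count=len(kms))
        rows.append(np.full(len(kms), i, dtype=np.int64))
        cols.append(idx)
    X = sparse.csr_matrix(
        (np.ones(sum(len(r) for r in rows), dtype=np.int32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(seqs), len(vocab)))
    shared = sparse.triu(X @ X.T, k=1).tocoo()
    if shared.nnz == 0:
        return np.empty((0, 2), dtype=np.int64)
    need = np.maximum(
        1, np.ceil(frac * np.minimum(n_kmers[shared.row],
                                     n_kmers[shared.col])))
    keep = shared.data >= need
    return np.column_stack([shared.row[keep], shared.col[keep]])


def all_vs_all(
    records: list[ProteinRecord], config: RunConfig | None = None
) -> list[SimilarityHit]:
    """Directed similarity hits for all ordered pairs passing a permissive
    raw-score floor, after the k-mer prefilter.

    Alignment is computed once per unordered pair (the local alignment is
    symmetric) and emitted in both directions. Deterministic: records are
    processed in sorted gene_id order.
    """
    if len(records) < 2:
        raise ValueError("all_vs_all needs at least 2 records")
    config = config or RunConfig()
    recs = sorted(records, key=lambda r: r.gene_id)
    ids = [r.gene_id for r in recs]
    seqs = [r.sequence for r in recs]
    pairs = _kmer_candidate_pairs(seqs, config.kmer_size,
                                  config.prefilter_frac)
    logger.info("all_vs_all: %d sequences, %d candidate pairs",
                len(recs), len(pairs))
    aligner = make_aligner(config)
    hits: list[SimilarityHit] = []
    for i, j in pairs:
        a, b = seqs[i], seqs[j]
        try:
            aln = aligner.align(a, b)[0]
        except IndexError:  # no positive-scoring local alignment
            continue
        if aln.score < config.raw_score_floor:
            continue
        matches, aln_length, qcov, scov = _stats_from_coordinates(
            a, b, aln.coordinates, aln.score)
        pid = 100.0 * matches / aln_length if aln_length else 0.0
        hits.append(SimilarityHit(
            query_id=ids[i], subject_id=ids[j], pct_identity=pid,
            aln_length=aln_length, query_cov=qcov, subject_cov=scov,
            score=float(aln.score)))
        hits.append(SimilarityHit(
            query_id=ids[j], subject_id=ids[i], pct_identity=pid,
            aln_length=aln_length, query_cov=scov, subject_cov=qcov,
            score=float(aln.score)))
    return hits


def filter_bidirectional(
    hits: list[SimilarityHit], config: RunConfig | None = None
) -> dict[tuple[str, str], float]:
    """Undirected qualified pairs under the bidirectional filter.

    A pair {a, b} is retained iff hits a->b and b->a both exist and both
    satisfy identity >= min_identity_pct, query coverage >=
    min_coverage_frac and (when an E-value is present) evalue <=
    max_evalue. Keys are sorted (a, b) tuples; the value is the edge weight
    used for clustering: pct_identity x min(query_cov, subject_cov),
    averaged over the two directions and rescaled to [0, 1].
    """
    config = config or RunConfig()
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or h.score > prev.score:
            best[key] = h

    def passes(h: SimilarityHit) -> bool:
        if h.pct_identity < config.min_identity_pct:
            return False
        if h.query_cov < config.min_coverage_frac:
            return False
        if h.evalue is not None and h.evalue > config.max_evalue:
            return False
        return True

    out: dict[tuple[str, str], float] = {}
    for (q, s), h in best.items():
        if q > s:
            continue
        rev = best.get((s, q))
        if rev is None or not passes(h) or not passes(rev):
            continue
        w = (h.pct_identity * min(h.query_cov, h.subject_cov)
             + rev.pct_identity * min(rev.query_cov, rev.subject_cov)) / 2.0
        out[(q, s)] = min(1.0, w / 100.0)
    return out


def write_qualified_pairs(pairs: dict[tuple[str, str], float],
                          path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for (a, b), w in sorted(pairs.items()):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def read_qualified_pairs(path: str) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: not a qualified-pairs table")
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            out[(a, b) if a <= b else (b, a)] = float(w)
    return out
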