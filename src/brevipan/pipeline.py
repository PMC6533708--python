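"""End-to-end convenience: proteins -> qualified pairs -> families."""

from __future__ import annotations

from dataclasses import dataclass, field

from brevipan import clustering, similarity
from brevipan.clustering import GeneFamily
from brevipan.config import RunConfig
from brevipan.records import ProteinRecord, SimilarityHit


@dataclass
class ClusteringResult:
    hits: list[SimilarityHit]
    qualified_pairs: dict[tuple[str, str], float]
    families: list[GeneFamily]
    class_counts: dict[str, int] = field(default_factory=dict)


def cluster_proteomes(
    records: list[ProteinRecord],
    genome_ids: list[str],
    config: RunConfig | None = None,
    hits: list[SimilarityHit] | None = None,
) -> ClusteringResult:
    """All-vs-all similarity, bidirectional filtering, MCL and family
    classification in one call. Precomputed ``hits`` (e.g. ingested tabular
    output) skip the internal aligner."""
    config = config or RunConfig()
    if hits is None:
        hits = similarity.all_vs_all(records, config)
    pairs = similarity.filter_bidirectional(hits, config)
    graph = clustering.build_graph(pairs, [r.gene_id for r in records])
    partition = clustering.mcl(
        graph, config.inflation, config.max_iterations,
        config.epsilon, config.prune_threshold)
    families = clustering.build_families(partition, records)
    counts = clustering.classify_families(families, genome_ids)
    return ClusteringResult(hits=hits, qualified_pairs=pairs,
                            families=families, class_counts=counts)
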