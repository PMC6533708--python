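import networkx as nx
import numpy as np
import pytest

from brevipan.clustering import (build_families, build_graph,
                                 classify_families, mcl, read_families,
                                 representative_products, write_families)
from brevipan.config import RunConfig
from brevipan.pipeline import cluster_proteomes
from brevipan.records import ProteinRecord
from brevipan.simulate import SimSpec, simulate_pangenome


def _triangle(g, nodes, w=1.0):
    a, b, c = nodes
    g.add_edge(a, b, weight=w)
    g.add_edge(b, c, weight=w)
    g.add_edge(a, c, weight=w)


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        _triangle(g, "abc")
        _triangle(g, "xyz")
        clusters = mcl(g, validate=True)
        assert sorted(map(sorted, clusters)) == [list("abc"), list("xyz")]

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        clusters = mcl(g)
        assert sorted(map(sorted, clusters)) == [[c] for c in "abcde"]

    def test_planted_blocks_recovered(self, rng):
        blocks = [[f"b{k}n{i}" for i in range(10)] for k in range(3)]
        g = nx.Graph()
        for block in blocks:
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    g.add_edge(a, b, weight=0.9)
        # two random cross edges with tiny weight
        g.add_edge(blocks[0][0], blocks[1][3], weight=0.05)
        g.add_edge(blocks[1][7], blocks[2][2], weight=0.05)
        clusters = mcl(g, inflation=1.5, validate=True)
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, blocks))

    def test_partition_property(self, rng):
        g = nx.gnm_random_graph(25, 40, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(
            g, {e: float(rng.uniform(0.1, 1.0)) for e in g.edges}, "weight")
        clusters = mcl(g)
        all_nodes = [n for c in clusters for n in c]
        assert len(all_nodes) == g.number_of_nodes()
        assert len(set(all_nodes)) == len(all_nodes)

    def test_disjoint_union_equals_union_of_components(self):
        g1 = nx.Graph()
        _triangle(g1, "abc", 0.8)
        g2 = nx.Graph()
        _triangle(g2, "xyz", 0.6)
        g2.add_edge("x", "w", weight=0.6)
        combined = nx.union(g1, g2)
        got = sorted(map(sorted, mcl(combined)))
        want = sorted(map(sorted, mcl(g1) + mcl(g2)))
        assert got == want

    def test_monotone_stability_on_planted_blocks(self):
        g = nx.Graph()
        _triangle(g, "abc", 0.9)
        _triangle(g, "xyz", 0.9)
        g.add_edge("a", "x", weight=0.05)
        clusters = mcl(g)
        for cluster in clusters:
            sub = g.subgraph(cluster).copy()
            assert sorted(map(sorted, mcl(sub))) == [sorted(cluster)]

    def test_empty_graph_error(self):
        with pytest.raises(ValueError):
            mcl(nx.Graph())

    def test_build_graph_rejects_self_loops(self):
        with pytest.raises(ValueError):
            build_graph({("a", "a"): 0.5})


def _rec(gene, genome, product="p"):
    return ProteinRecord(gene_id=gene, genome_id=genome,
                         replicon_id=f"{genome}_chr",
                         replicon_type="chromosome", start=1, end=9,
                         strand="+", product=product, sequence="MKV")


class TestFamilies:
    def test_build_families_toy(self):
        records = [_rec("a1", "g1"), _rec("b1", "g2"), _rec("c1", "g1")]
        fams = build_families([{"a1", "b1"}, {"c1"}], records)
        assert len(fams) == 2
        assert fams[0].members == {"g1": ["a1"], "g2": ["b1"]}
        assert fams[1].members == {"g1": ["c1"]}

    def test_build_families_unknown_gene(self):
        with pytest.raises(KeyError):
            build_families([{"zz"}], [_rec("a1", "g1")])

    def test_classification_rules(self):
        records = ([_rec(f"a{i}", f"g{i}") for i in range(3)]
                   + [_rec("a0b", "g0")]
                   + [_rec(f"u{i}", "g0") for i in range(3)]
                   + [_rec("d1", "g0"), _rec("d2", "g1")])
        fams2 = build_families(
            [{"a0", "a1", "a2"},
             {"u0"}, {"u1", "u2"},
             {"d1", "d2"}],
            records)
        counts = classify_families(fams2, ["g0", "g1", "g2"])
        by_id = {f.family_id: f.family_class for f in fams2}
        assert by_id["F00001"] == "core_single"
        assert counts["unique"] == 2  # {u0} and {u1,u2} both single-genome
        assert counts["dispensable"] == 1
        assert counts["core"] == 1

    def test_core_multi_and_unique(self):
        records = [_rec("a1", "g1"), _rec("a2", "g1"), _rec("b1", "g2"),
                   _rec("c1", "g3"), _rec("x1", "g1"), _rec("x2", "g1"),
                   _rec("x3", "g1")]
        fams = build_families([{"a1", "a2", "b1", "c1"},
                               {"x1", "x2", "x3"}], records)
        classify_families(fams, ["g1", "g2", "g3"])
        assert fams[0].family_class == "core_multi"
        assert fams[1].family_class == "unique"

    def test_empty_genome_list(self):
        with pytest.raises(ValueError):
            classify_families([], [])

    def test_representative_product_tiebreak(self):
        records = [_rec("a1", "g1", "zeta protein"),
                   _rec("a2", "g2", "alpha protein"),
                   _rec("a3", "g3", "zeta protein"),
                   _rec("b1", "g1", "beta"), _rec("b2", "g2", "alpha")]
        fams = build_families([{"a1", "a2", "a3"}, {"b1", "b2"}], records)
        products = representative_products(fams, records)
        assert products[fams[0].family_id] == "zeta protein"  # majority
        assert products[fams[1].family_id] == "alpha"  # tie -> lexicographic

    def test_families_tsv_roundtrip(self, tmp_path, small_sim):
        records, _, truth = small_sim
        fams = truth.to_families(records)
        classify_families(fams, sorted({r.genome_id for r in records}))
        p = tmp_path / "families.tsv"
        write_families(fams, str(p))
        back = read_families(str(p))
        assert [(f.family_id, f.family_class, f.members) for f in fams] == \
            [(f.family_id, f.family_class, f.members) for f in back]


class TestPipelineRecovery:
    def test_small_pipeline_matches_truth(self, small_sim, small_clustering):
        from sklearn.metrics import rand_score

        records, _, truth = small_sim
        res = small_clustering
        assert len(res.families) == len(truth.family_class)
        genes = sorted(r.gene_id for r in records)
        pred = {g: f.family_id for f in res.families
                for gl in f.members.values() for g in gl}
        a = [truth.gene_to_family[g] for g in genes]
        b = [pred[g] for g in genes]
        assert rand_score(a, b) == 1.0

    def test_paralog_classification_recovery(self):
        spec = SimSpec(n_genomes=4, n_spoilers=0, n_core_families=30,
                       n_shell_families=0, n_unique_per_genome=3,
                       n_niche_families=0, paralog_prob=0.3,
                       substitution_rate=0.02, seed=21)
        records, metas, truth = simulate_pangenome(spec)
        res = cluster_proteomes(records, [m.genome_id for m in metas],
                                RunConfig())
        true_fams = truth.to_families(records)
        want = classify_families(true_fams,
                                 [m.genome_id for m in metas])
        assert res.class_counts == want
        assert want["core_multi"] > 0  # paralogs actually planted
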