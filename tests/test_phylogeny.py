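import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from brevipan.clustering import GeneFamily
from brevipan.phylogeny import (MultipleAlignment, align_family, bootstrap,
                                concatenate, neighbor_joining, p_distance,
                                root_with_outgroup,
                                select_single_copy_core, supertree)
from brevipan.simulate import SimSpec, simulate_pangenome
from oracles import lcs3, tree_distance_matrix


def _fam(fid, members):
    return GeneFamily(family_id=fid, members={
        g: [f"{g}_{fid}_{i}" for i in range(n)]
        for g, n in members.items() if n})


def _rf(newick_a, tree_b):
    ta = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=tree_b.taxon_namespace,
                           preserve_underscores=True)
    ta.encode_bipartitions()
    tree_b.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tree_b)


class TestSelectSingleCopyCore:
    def test_toy_selection(self):
        fams = [_fam("f1", {"a": 1, "b": 1, "c": 1}),
                _fam("f2", {"a": 2, "b": 1, "c": 1}),
                _fam("f3", {"a": 1, "b": 1, "c": 0})]
        got = select_single_copy_core(fams, ["a", "b", "c"])
        assert [f.family_id for f in got] == ["f1"]

    def test_outgroup_missing_excludes_family(self):
        fams = [_fam("f1", {"a": 1, "b": 1, "og": 1}),
                _fam("f2", {"a": 1, "b": 1, "og": 0})]
        got = select_single_copy_core(fams, ["a", "b", "og"])
        assert [f.family_id for f in got] == ["f1"]

    def test_empty_result_is_error(self):
        fams = [_fam("f1", {"a": 1})]
        with pytest.raises(ValueError, match="single-copy"):
            select_single_copy_core(fams, ["a", "b"])

    def test_simulated_universal_families_recovered(self, small_sim,
                                                    small_clustering,
                                                    small_spec):
        records, metas, _ = small_sim
        got = select_single_copy_core(
            small_clustering.families, [m.genome_id for m in metas])
        assert len(got) == small_spec.n_core_families


class TestAlignFamily:
    def test_identical_sequences_unchanged(self):
        msa = align_family({"a": "MKVLA", "b": "MKVLA", "c": "MKVLA"})
        assert msa.length == 5
        assert all(msa.row(t) == "MKVLA" for t in "abc")

    def test_gap_column_removed_matches_lcs_oracle(self):
        msa = align_family({"a": "MKV", "b": "MKV", "c": "MV"},
                           scoring="identity")
        assert msa.length == 2
        # the surviving gap-free identical columns cannot exceed (and here
        # attain) the longest common subsequence of the three inputs
        assert msa.length == lcs3("MKV", "MKV", "MV")
        assert msa.row("a") == msa.row("c") == "MV"

    def test_no_conserved_columns(self, caplog):
        # with mismatches costlier than gaps the optimal global alignment of
        # unrelated sequences is all-gap: every column is removed
        from Bio import Align
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = 1.0
        al.mismatch_score = -5.0
        al.open_gap_score = -1.0
        al.extend_gap_score = -1.0
        msa = align_family({"a": "AAAA", "b": "WWWW"}, aligner=al)
        assert msa.length == 0

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            align_family({"a": "", "b": "MKV"})


class TestConcatenate:
    def test_lengths_add(self):
        m1 = MultipleAlignment.from_strings(["a", "b"], ["M" * 10, "K" * 10])
        m2 = MultipleAlignment.from_strings(["a", "b"], ["V" * 10, "L" * 10])
        sm = concatenate([m1, m2])
        assert sm.length == 20
        assert sm.family_lengths == [10, 10]

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            concatenate([])

    def test_taxon_mismatch_error(self):
        m1 = MultipleAlignment.from_strings(["a", "b"], ["MM", "KK"])
        m2 = MultipleAlignment.from_strings(["a", "c"], ["MM", "KK"])
        with pytest.raises(ValueError):
            concatenate([m1, m2])

    def test_order_invariance_of_distances(self, rng):
        taxa = ["a", "b", "c"]
        msas = []
        for _ in range(4):
            rows = ["".join("ACDEFG"[i] for i in rng.integers(0, 6, 30))
                    for _ in taxa]
            msas.append(MultipleAlignment.from_strings(taxa, rows))
        d1 = p_distance(concatenate(msas))
        d2 = p_distance(concatenate(msas[::-1]))
        pd.testing.assert_frame_equal(d1, d2)


class TestPDistance:
    def test_identical_rows(self):
        msa = MultipleAlignment.from_strings(["a", "b"], ["MKVA", "MKVA"])
        assert (p_distance(msa).to_numpy() == 0).all()

    def test_quarter_difference(self):
        msa = MultipleAlignment.from_strings(["a", "b"], ["AAAA", "AAAT"])
        assert p_distance(msa).loc["a", "b"] == 0.25

    def test_equals_direct_recomputation(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        rows = ["".join("ACDEFG"[i] for i in rng.integers(0, 6, 40))
                for _ in taxa]
        msa = MultipleAlignment.from_strings(taxa, rows)
        d = p_distance(msa)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                want = sum(x != y for x, y in zip(rows[i], rows[j])) / 40
                assert d.loc[a, b] == pytest.approx(want)

    def test_zero_length_error(self):
        msa = MultipleAlignment.from_strings(["a", "b"], ["", ""])
        with pytest.raises(ValueError):
            p_distance(msa)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]],
                         index=list("abc"), columns=list("abc"))
        tree = neighbor_joining(d)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_recovery(self):
        nwk = "((A:1.0,B:2.0):3.0,C:4.0,D:5.0);"
        labels, mat = tree_distance_matrix(nwk)
        d = pd.DataFrame(mat, index=labels, columns=labels)
        tree = neighbor_joining(d)
        assert _rf(nwk, tree) == 0
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0})

    def test_all_zero_distances_star(self):
        labels = [f"t{i}" for i in range(5)]
        d = pd.DataFrame(np.zeros((5, 5)), index=labels, columns=labels)
        tree = neighbor_joining(d)
        assert all((e.length or 0.0) == 0.0
                   for e in tree.preorder_edge_iter())
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(labels)

    def test_random_additive_trees_recovered(self, rng):
        # random 4-8 taxon trees with positive branch lengths are exactly
        # recovered from their path-length (additive) matrices
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 9))
            taxa = [f"T{i}" for i in range(n)]
            ns = dendropy.TaxonNamespace(taxa)
            gen = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                taxon_namespace=ns,
                rng=__import__("random").Random(seed))
            for e in gen.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(r.uniform(0.1, 2.0))
            gen.is_rooted = False
            nwk = gen.as_string(schema="newick")
            labels, mat = tree_distance_matrix(nwk)
            d = pd.DataFrame(mat, index=labels, columns=labels)
            tree = neighbor_joining(d)
            assert _rf(nwk, tree) == 0

    def test_matches_scikit_bio_on_noisy_matrix(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = [f"t{i}" for i in range(6)]
        base = rng.uniform(0.2, 1.0, size=(6, 6))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = neighbor_joining(pd.DataFrame(d, index=labels,
                                             columns=labels))
        theirs = skbio_nj(DistanceMatrix(d, ids=labels))
        assert _rf(str(theirs).strip(), ours) == 0

    def test_input_validation(self):
        d = pd.DataFrame([[0, 1], [1, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(d)
        bad = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]],
                           index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            neighbor_joining(bad)


GUIDE = ("((G01:0.05,(G02:0.05,G03:0.05):0.08):0.2,"
         "(G04:0.05,(G05:0.05,G06:0.05):0.08):0.2);")


@pytest.fixture(scope="module")
def guided_sim():
    spec = SimSpec(n_genomes=6, n_spoilers=0, n_core_families=40,
                   n_shell_families=0, n_unique_per_genome=0,
                   n_niche_families=0, guide_tree=GUIDE,
                   mean_protein_len=120.0, sd_protein_len=20.0, seed=17)
    return simulate_pangenome(spec)


@pytest.fixture(scope="module")
def guided_supermatrix(guided_sim):
    records, metas, truth = guided_sim
    fams = truth.to_families(records)
    genomes = [m.genome_id for m in metas]
    sequences = {r.gene_id: r.sequence for r in records}
    msas = [align_family({g: sequences[f.members[g][0]] for g in genomes})
            for f in fams]
    return concatenate(msas)


class TestBootstrapAndRooting:
    def test_clean_clades_get_full_support(self, guided_supermatrix):
        tree, flagged = bootstrap(guided_supermatrix, reps=25, seed=3,
                                  support_display_min=10)
        supports = [int(n.label) for n in tree.preorder_internal_node_iter()
                    if n.label is not None]
        assert supports and all(s == 25 for s in supports)
        assert flagged == []
        assert _rf(GUIDE, tree) == 0

    def test_single_rep_supports_binary(self, guided_supermatrix):
        tree, _ = bootstrap(guided_supermatrix, reps=1, seed=0,
                            support_display_min=1)
        supports = [int(n.label) for n in tree.preorder_internal_node_iter()
                    if n.label is not None]
        assert set(supports) <= {0, 1}

    def test_same_seed_bit_reproducible(self, guided_supermatrix):
        t1, _ = bootstrap(guided_supermatrix, reps=10, seed=42)
        t2, _ = bootstrap(guided_supermatrix, reps=10, seed=42)
        assert (t1.as_string(schema="newick")
                == t2.as_string(schema="newick"))

    def test_rooting_on_outgroup(self, guided_supermatrix):
        tree, _ = bootstrap(guided_supermatrix, reps=5, seed=1)
        rooted = root_with_outgroup(tree, "G01")
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        labels = [{lf.taxon.label for lf in c.leaf_iter()}
                  for c in children]
        assert {"G01"} in labels
        rerooted = root_with_outgroup(rooted, "G01")
        assert _rf(rooted.as_string(schema="newick"), rerooted) == 0

    def test_rooting_unknown_outgroup(self, guided_supermatrix):
        tree, _ = bootstrap(guided_supermatrix, reps=2, seed=1)
        with pytest.raises(ValueError):
            root_with_outgroup(tree, "nope")


def test_supertree_end_to_end_recovers_guide_topology(guided_sim):
    records, metas, truth = guided_sim
    fams = truth.to_families(records)
    sequences = {r.gene_id: r.sequence for r in records}
    tree, _ = supertree(fams, sequences, [m.genome_id for m in metas],
                        outgroup="G01", reps=10, seed=2)
    # outgroup sits directly at the root
    root_clades = [{lf.taxon.label for lf in c.leaf_iter()}
                   for c in tree.seed_node.child_nodes()]
    assert {"G01"} in root_clades
    unrooted = tree.clone(depth=1)
    unrooted.deroot()
    unrooted.is_rooted = False
    assert _rf(GUIDE, unrooted) == 0
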