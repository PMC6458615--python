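import numpy as np
import pandas as pd
import pytest
from _oracles import random_additive_tree

from panclade import phylogeny
from panclade.phylogeny import (
    SnpMatrix,
    bipartitions,
    bootstrap_support,
    center_star_msa,
    concat_and_extract_snps,
    nj_tree,
    parse_tree,
    root_at_outgroup,
    snp_distance_matrix,
)


class TestCenterStar:
    def test_identical_sequences_unchanged(self):
        seqs = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
        assert center_star_msa(seqs) == seqs

    def test_small_case_exact(self):
        aln = center_star_msa({"a": "ACGT", "b": "AGT", "c": "ACGT"})
        assert aln["a"] == "ACGT"
        assert aln["c"] == "ACGT"
        assert aln["b"] == "A-GT"

    def test_alignment_length_at_least_max_input(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            seqs = {
                f"t{i}": "".join(rng.choice(list("ACGT"), rng.integers(5, 20)))
                for i in range(4)
            }
            aln = center_star_msa(seqs)
            lengths = {len(v) for v in aln.values()}
            assert len(lengths) == 1
            assert lengths.pop() >= max(len(v) for v in seqs.values())
            # gap removal recovers the inputs
            for t, s in seqs.items():
                assert aln[t].replace("-", "") == s

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            center_star_msa({})


class TestSnpExtraction:
    def test_single_difference_single_column(self):
        aln = {"g1": {"a": "ACGTAC", "b": "ACGAAC"}}
        snps = concat_and_extract_snps(aln, ["g1"])
        assert snps.n_sites == 1
        assert snps.provenance == [("g1", 3)]

    def test_gap_column_dropped_even_if_polymorphic(self):
        aln = {"g1": {"a": "A-G", "b": "ATG", "c": "ACG"}}
        snps = concat_and_extract_snps(aln, ["g1"])
        assert snps.n_sites == 0

    def test_taxa_mismatch_names_gene(self):
        aln = {"g1": {"a": "AC", "b": "AC"}, "g2": {"a": "AC", "c": "AC"}}
        with pytest.raises(ValueError, match="g2"):
            concat_and_extract_snps(aln, ["g1", "g2"])

    def test_snp_count_matches_direct_recount(self, two_lineage_clade):
        """SNP columns equal the positionwise discrepancies of core genes."""
        ds = two_lineage_clade
        cds_of = ds.cds_sets()
        taxa = [g.strain_id for g in ds.genomes]
        expected = 0
        alignments = {}
        for fam in ds.truth.families_of_class("core"):
            seqs = {t: cds_of[t][f"{t}_{fam}"] for t in taxa}
            assert len({len(s) for s in seqs.values()}) == 1  # no indels simulated
            arr = np.array([list(seqs[t]) for t in taxa])
            expected += sum(
                1 for j in range(arr.shape[1]) if len(set(arr[:, j])) >= 2
            )
            alignments[fam] = center_star_msa(seqs)
        snps = concat_and_extract_snps(alignments, sorted(alignments))
        assert snps.n_sites == expected


class TestDistances:
    def _snps(self):
        rows = ["AAAAAA", "CAAAAA", "ACAAAA", "AACAAA"]  # pairwise p <= 1/3
        cols = np.array([list(r) for r in rows])
        return SnpMatrix(taxa=["a", "b", "c", "d"], columns=cols, provenance=[("g", i) for i in range(6)])

    def test_p_distance_below_jc(self):
        snps = self._snps()
        p = snp_distance_matrix(snps, "p")
        jc = snp_distance_matrix(snps, "jc")
        off = ~np.eye(4, dtype=bool)
        assert np.all(p.to_numpy()[off] <= jc.to_numpy()[off] + 1e-12)

    def test_jc_undefined_at_saturation(self):
        cols = np.array([list("AC"), list("AC"), list("AC"), list("AC")]).T
        snps = SnpMatrix(["a", "b"], cols.reshape(2, -1), [("g", i) for i in range(4)])
        with pytest.raises(ValueError, match="0.75"):
            snp_distance_matrix(snps, "jc")


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these additive distances
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        newick = nj_tree(d)
        assert bipartitions(newick) == {frozenset("AB")} or bipartitions(newick) == {
            frozenset("CD")
        }
        tree = parse_tree(newick)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 3], [2, 0, 5], [3, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = parse_tree(nj_tree(d))
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        # la=(dab+dac-dbc)/2=0, lb=(dab+dbc-dac)/2=2, lc=(dac+dbc-dab)/2=3
        assert lengths == pytest.approx({"A": 0, "B": 2, "C": 3})

    def test_equidistant_tie_break_joins_first_pair(self):
        d = pd.DataFrame(
            1 - np.eye(4), index=list("ABCD"), columns=list("ABCD")
        )
        from panclade.phylogeny import split_key
        assert split_key(set("AB"), list("ABCD")) in bipartitions(nj_tree(d))

    def test_invalid_matrix_rejected(self):
        bad = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(bad)

    def test_recovers_random_additive_trees_exactly(self):
        """NJ is consistent: additive distances give back the true topology."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_taxa = int(rng.integers(4, 9))
            true_newick = random_additive_tree(rng, n_taxa)
            tree = parse_tree(true_newick)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(t.label for t in tree.taxon_namespace)
            by_label = {t.label: t for t in tree.taxon_namespace}
            d = pd.DataFrame(
                [
                    [
                        0.0 if a == b else pdm.patristic_distance(by_label[a], by_label[b])
                        for b in taxa
                    ]
                    for a in taxa
                ],
                index=taxa, columns=taxa,
            )
            assert bipartitions(nj_tree(d)) == bipartitions(true_newick)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        true_newick = random_additive_tree(rng, 6)
        tree = parse_tree(true_newick)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(t.label for t in tree.taxon_namespace)
        by_label = {t.label: t for t in tree.taxon_namespace}
        mat = np.array(
            [
                [
                    0.0 if a == b else pdm.patristic_distance(by_label[a], by_label[b])
                    for b in taxa
                ]
                for a in taxa
            ]
        )
        ours = bipartitions(nj_tree(pd.DataFrame(mat, index=taxa, columns=taxa)))
        theirs = bipartitions(str(skbio_nj(skbio.DistanceMatrix(mat, ids=taxa))))
        assert ours == theirs


class TestBootstrap:
    def _uniform_snps(self, n_cols=20):
        # every column supports the split ab|cd
        col = ["A", "A", "C", "C"]
        cols = np.tile(np.array(col).reshape(4, 1), (1, n_cols))
        return SnpMatrix(["a", "b", "c", "d"], cols, [("g", i) for i in range(n_cols)])

    def test_uniform_signal_full_support(self):
        sup = bootstrap_support(self._uniform_snps(), n_reps=50, seed=0)
        from panclade.phylogeny import split_key
        assert sup.supports[split_key({"a", "b"}, ["a", "b", "c", "d"])] == 100.0

    def test_supports_bounded_and_root_independent(self, two_lineage_clade):
        ds = two_lineage_clade
        cds_of = ds.cds_sets()
        taxa = [g.strain_id for g in ds.genomes]
        alignments = {
            fam: center_star_msa({t: cds_of[t][f"{t}_{fam}"] for t in taxa})
            for fam in ds.truth.families_of_class("core")[:10]
        }
        snps = concat_and_extract_snps(alignments, sorted(alignments))
        sup = bootstrap_support(snps, n_reps=30, seed=1)
        assert all(0 <= v <= 100 for v in sup.supports.values())
        rerooted = root_at_outgroup(sup.newick, "L01")
        assert bipartitions(rerooted) == bipartitions(sup.newick)

    def test_lineage_split_strongly_supported(self, two_lineage_clade):
        """The P|L bipartition gets >= 95% support in >= 18 of 20 runs."""
        ds = two_lineage_clade
        cds_of = ds.cds_sets()
        taxa = [g.strain_id for g in ds.genomes]
        alignments = {
            fam: center_star_msa({t: cds_of[t][f"{t}_{fam}"] for t in taxa})
            for fam in ds.truth.families_of_class("core")
        }
        snps = concat_and_extract_snps(alignments, sorted(alignments))
        from panclade.phylogeny import split_key
        split = split_key({t for t in taxa if t.startswith("L")}, taxa)
        wins = 0
        for seed in range(20):
            sup = bootstrap_support(snps, n_reps=50, seed=seed)
            if sup.supports.get(split, 0) >= 95:
                wins += 1
        assert wins >= 18
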