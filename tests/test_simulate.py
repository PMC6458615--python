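import math

import numpy as np
import pytest

from panclade.io import gc_fraction, translate_cds
from panclade.simulate import (
    BranchLengths,
    CladeConfig,
    CladeConfigError,
    HgtClusterSpec,
    cluster_gc_check,
    evolve_sequence,
    insert_hgt_cluster,
    random_sequence,
    simulate_clade,
)


class TestEvolveSequence:
    def test_zero_branch_is_identity(self):
        s = random_sequence(1000, 0.5, np.random.default_rng(0))
        assert evolve_sequence(s, 0.0, 1) == s

    def test_jc_expected_divergence(self):
        # closed form: p = (3/4)(1 - e^(-4d/3)); at d=0.1, p = 0.09365
        n = 100_000
        s = random_sequence(n, 0.5, np.random.default_rng(0))
        t = evolve_sequence(s, 0.1, 123)
        p_obs = sum(a != b for a, b in zip(s, t)) / n
        p_exp = 0.75 * (1 - math.exp(-0.4 / 3))
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_saturation_approaches_three_quarters(self):
        n = 50_000
        s = random_sequence(n, 0.5, np.random.default_rng(0))
        t = evolve_sequence(s, 10.0, 5)
        p_obs = sum(a != b for a, b in zip(s, t)) / n
        assert abs(p_obs - 0.75) < 0.01

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", -0.1, 0)

    def test_ambiguous_bases_untouched(self):
        assert evolve_sequence("NNNN", 5.0, 0) == "NNNN"


class TestHgtInsertion:
    def test_gc_targeting_17kb_cluster(self):
        # mimics a 38.6%-GC cluster inside a 46.7%-GC genome
        rng = np.random.default_rng(3)
        genome = random_sequence(40_000, 0.467, rng)
        spec = HgtClusterSpec("lan", 11, 0.386, ["g"], gene_length=1500)
        assert spec.total_length >= 17_000
        new_seq, interval, _genes = insert_hgt_cluster(genome, spec, 11)
        region = new_seq[interval.start : interval.end]
        assert len(new_seq) == len(genome) + spec.total_length
        assert 0.376 <= gc_fraction(region) <= 0.396

    def test_zero_gene_cluster_rejected(self):
        spec = HgtClusterSpec("bad", 0, 0.4, ["g"])
        with pytest.raises(CladeConfigError, match="n_genes"):
            insert_hgt_cluster("A" * 1000, spec, 0)

    def test_locus_out_of_bounds_rejected(self):
        spec = HgtClusterSpec("c", 1, 0.4, ["g"], insertion_locus=5000)
        with pytest.raises(CladeConfigError, match="insertion_locus"):
            insert_hgt_cluster("A" * 100, spec, 0)

    def test_annotation_matches_gene_and_spacer_layout(self):
        spec = HgtClusterSpec("c", 3, 0.5, ["g"], gene_length=300)
        _seq, interval, genes = insert_hgt_cluster("A" * 1000, spec, 0)
        assert interval.length == 3 * 300 + 2 * 100
        assert [e - s for _g, s, e in genes] == [300, 300, 300]


class TestSimulateClade:
    def test_seeded_determinism_byte_identical(self, two_lineage_clade):
        ds2 = simulate_clade(two_lineage_clade.config)
        for a, b in zip(two_lineage_clade.genomes, ds2.genomes):
            assert a.sequences == b.sequences
            assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]

    def test_core_only_clade_has_exact_gene_counts(self):
        cfg = CladeConfig(
            n_genomes=4,
            lineage_assignment=["P", "P", "L", "L"],
            n_core=15,
            n_accessory=0,
            singleton_rate=0.0,
            gene_length_range=(300, 300),
            seed=3,
        )
        ds = simulate_clade(cfg)
        for g in ds.genomes:
            assert len(g.genes) == 15
        fams = {f for (_s, _g), f in ds.truth.gene_to_family.items()}
        assert len(fams) == 15  # pan == core

    def test_truth_round_trip_from_annotations(self, two_lineage_clade):
        # every emitted gene maps to exactly one family, and core families
        # appear exactly once per genome
        ds = two_lineage_clade
        emitted = {(g.strain_id, x.gene_id) for g in ds.genomes for x in g.genes}
        assert emitted == set(ds.truth.gene_to_family)
        counts = ds.truth.presence_counts()
        genome_ids = [g.strain_id for g in ds.genomes]
        for fam in ds.truth.families_of_class("core"):
            assert all(counts[fam].get(g) == 1 for g in genome_ids)
        for fam in ds.truth.families_of_class("singleton"):
            assert sum(counts[fam].values()) == 1

    def test_proteins_translate_from_cds(self, two_lineage_clade):
        for g in two_lineage_clade.genomes:
            for gene in g.genes:
                assert gene.protein == translate_cds(gene.cds)
                assert "*" not in gene.protein

    def test_hgt_cluster_gc_realized(self, two_lineage_clade):
        gcs = cluster_gc_check(two_lineage_clade, "bac")
        assert set(gcs) == {"P01", "P02", "P03"}
        for v in gcs.values():
            assert abs(v - 0.35) < 0.02

    def test_invalid_config_names_field(self):
        cfg = CladeConfig(n_genomes=1, lineage_assignment=["P"])
        with pytest.raises(CladeConfigError, match="n_genomes"):
            simulate_clade(cfg)
        cfg = CladeConfig(accessory_presence_prob=1.5)
        with pytest.raises(CladeConfigError, match="accessory_presence_prob"):
            simulate_clade(cfg)
        cfg = CladeConfig(gene_length_range=(301, 600))
        with pytest.raises(CladeConfigError, match="gene_length_range"):
            simulate_clade(cfg)

    def test_singleton_rate_grows_pangenome(self):
        def pan_size(rate, seed):
            cfg = CladeConfig(
                n_genomes=4,
                lineage_assignment=["P", "P", "L", "L"],
                n_core=10,
                n_accessory=0,
                singleton_rate=rate,
                gene_length_range=(300, 300),
                seed=seed,
            )
            ds = simulate_clade(cfg)
            return len({f for f in ds.truth.gene_to_family.values()})

        lo = np.mean([pan_size(1.0, s) for s in range(5)])
        hi = np.mean([pan_size(6.0, s) for s in range(5)])
        assert hi > lo
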