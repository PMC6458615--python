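import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from panclade import pangenome
from panclade.pangenome import (
    AccumulationCurve,
    accumulation_curves,
    fit_core_decay,
    fit_heaps,
    pan_core_sizes,
    presence_matrix,
    singleton_stats,
)


def _curve(n, pan, core):
    n = np.asarray(n)
    return AccumulationCurve(
        n=n, pan_mean=np.asarray(pan, float), pan_sd=np.zeros_like(n, dtype=float),
        core_mean=np.asarray(core, float), core_sd=np.zeros_like(n, dtype=float),
        n_permutations=1, seed=0,
    )


class TestAccumulation:
    def test_identical_genomes_flat_curves(self):
        mat = pd.DataFrame(np.ones((30, 5), dtype=int))
        curve = accumulation_curves(mat, n_permutations=20, seed=1)
        assert np.all(curve.pan_mean == 30)
        assert np.all(curve.core_mean == 30)
        assert np.all(curve.pan_sd == 0)
        assert np.all(curve.core_sd == 0)

    def test_disjoint_genomes_linear_pan_zero_core(self):
        # 4 genomes with 6 private families each
        mat = pd.DataFrame(np.kron(np.eye(4, dtype=int), np.ones((6, 1), dtype=int)))
        curve = accumulation_curves(mat, n_permutations=10, seed=0)
        assert np.array_equal(curve.pan_mean, 6 * np.arange(1, 5))
        assert np.all(curve.core_mean[1:] == 0)
        assert np.all(curve.pan_sd == 0)

    def test_endpoints_permutation_invariant(self, two_lineage_clade):
        counts = two_lineage_clade.truth.presence_counts()
        ids = [g.strain_id for g in two_lineage_clade.genomes]
        mat = presence_matrix(counts, ids)
        c1 = accumulation_curves(mat, 15, seed=1)
        c2 = accumulation_curves(mat, 15, seed=99)
        pan, core = pan_core_sizes(mat)
        for c in (c1, c2):
            assert c.pan_mean[-1] == pan
            assert c.core_mean[-1] == core
        assert np.all(np.diff(c1.pan_mean) >= 0)
        assert np.all(np.diff(c1.core_mean) <= 0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accumulation_curves(pd.DataFrame(np.empty((0, 3))), 5, 0)


class TestHeapsFit:
    def test_exact_power_law_recovered(self):
        n = np.arange(1, 15)
        fit = fit_heaps(_curve(n, 100 * n**0.5, np.ones_like(n)))
        assert fit.gamma == pytest.approx(0.5, abs=1e-12)
        assert fit.kappa == pytest.approx(100, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.open_pangenome

    def test_flat_data_closed(self):
        n = np.arange(1, 11)
        fit = fit_heaps(_curve(n, np.full_like(n, 500, dtype=float), n))
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)
        assert not fit.open_pangenome

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_heaps(_curve(np.array([1, 2]), [5, 6], [5, 5]))

    def test_singletons_classify_open(self):
        # clades with a steady singleton influx have gamma > 0
        from panclade.simulate import CladeConfig, simulate_clade

        n_open = 0
        for seed in range(20):
            cfg = CladeConfig(
                n_genomes=8, lineage_assignment=["P"] * 4 + ["L"] * 4,
                n_core=20, n_accessory=10, singleton_rate=3.0,
                gene_length_range=(300, 300), seed=seed,
            )
            ds = simulate_clade(cfg)
            mat = presence_matrix(ds.truth.presence_counts(), cfg.genome_ids())
            curve = accumulation_curves(mat, 20, seed=seed)
            if fit_heaps(curve).gamma > 0:
                n_open += 1
        assert n_open >= 19


class TestCoreDecayFit:
    def test_noiseless_recovery(self):
        n = np.arange(1, 15)
        fit = fit_core_decay(_curve(n, n, 1860 + 500 * np.exp(-n / 3)))
        assert abs(fit.omega - 1860) < 1
        assert fit.tau == pytest.approx(3.0, rel=0.01)

    def test_constant_core(self):
        n = np.arange(1, 11)
        fit = fit_core_decay(_curve(n, n, np.full_like(n, 2068, dtype=float)))
        assert fit.omega == pytest.approx(2068, abs=0.5)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-3)

    def test_noisy_recovery_median_within_5pct(self):
        rng = np.random.default_rng(0)
        n = np.arange(1, 15)
        errors = []
        for _ in range(50):
            c = 1860 + 500 * np.exp(-n / 3) + rng.normal(0, 10, n.size)
            fit = fit_core_decay(_curve(n, n, c))
            errors.append(abs(fit.omega - 1860) / 1860)
        assert np.median(errors) <= 0.05

    def test_omega_not_above_observed_min(self):
        rng = np.random.default_rng(1)
        n = np.arange(1, 15)
        c = 2000 + 400 * np.exp(-n / 2.5) + rng.normal(0, 5, n.size)
        fit = fit_core_decay(_curve(n, n, c))
        assert fit.omega <= c.min() + 15  # within noise of the observed floor


class TestSingletonStats:
    def test_small_example(self):
        mat = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 0, 2], [1, 1, 1], [1, 1, 0]] * 2
        )
        n, frac = singleton_stats(mat)
        assert (n, frac) == (6, 0.6)

    def test_all_core_matrix(self):
        mat = pd.DataFrame(np.ones((8, 4), dtype=int))
        assert singleton_stats(mat) == (0, 0.0)

    def test_matches_truth_exactly(self, two_lineage_clade):
        ds = two_lineage_clade
        counts = ds.truth.presence_counts()
        mat = presence_matrix(counts, [g.strain_id for g in ds.genomes])
        n, _frac = singleton_stats(mat)
        truth_singletons = sum(
            1 for fam, row in counts.items() if sum(1 for v in row.values() if v >= 1) == 1
        )
        assert n == truth_singletons


@given(
    arrays(np.int8, (12, 5), elements=st.integers(0, 2)).filter(
        lambda a: a.sum() > 0
    )
)
@settings(max_examples=30, deadline=None)
def test_accumulation_monotone_on_random_matrices(arr):
    """Pan never shrinks and core never grows as genomes accumulate."""
    mat = pd.DataFrame(arr)
    curve = accumulation_curves(mat, n_permutations=5, seed=3)
    assert np.all(np.diff(curve.pan_mean) >= 0)
    assert np.all(np.diff(curve.core_mean) <= 0)
    pan, core = pan_core_sizes(mat)
    assert curve.pan_mean[-1] == pan
    assert curve.core_mean[-1] == core
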