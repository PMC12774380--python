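import numpy as np
import pandas as pd
import pytest

from scase import (
    AllelicDataset,
    FilterConfig,
    ShrinkageConfig,
    TestConfig,
    adjust_bh,
    binomial_mean_test,
    estimate_dispersion,
    estimate_group_models,
)
from scase.testing import test_group_mean as run_group_mean
from scase.testing import test_group_var as run_group_var
from scase.testing import test_mean as run_mean
from scase.testing import test_var as run_var
from tests.conftest import make_bb_dataset

SCFG = ShrinkageConfig(low_theta_threshold=0.005)


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)
        assert (adjust_bh([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_passthrough(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        fdr = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestMeanTest:
    @pytest.fixture(scope="class")
    def fitted(self):
        ds = make_bb_dataset(150, 400, ar=0.5, theta=0.05, seed=1)
        params, model = estimate_dispersion(ds, SCFG)
        return ds, params, model

    def test_balanced_gene_has_tiny_statistic(self, fitted):
        ds, params, model = fitted
        res = run_mean(ds, model, TestConfig(null_ratio=0.5))
        # balanced genes: median LRT near zero, p's not clustered small
        assert np.nanmedian(res["statistic"]) < 2.0
        assert (res["fdr"] < 0.05).sum() == 0

    def test_strong_imbalance_detected(self):
        theta = np.full(100, 0.05)
        ar = np.full(100, 0.5)
        ar[:5] = 0.9
        ds = make_bb_dataset(100, 400, ar=ar, theta=theta, seed=2)
        params, model = estimate_dispersion(ds, SCFG)
        res = run_mean(ds, model, TestConfig())
        assert (res["fdr"].iloc[:5] < 1e-3).all()
        assert (res["log2fc"].iloc[:5] > 1).all()

    def test_untested_genes_reported_na(self, fitted):
        ds, params, model = fitted
        res = run_mean(ds, model, TestConfig(), FilterConfig(min_counts=10**6))
        assert res["p_value"].isna().all()

    def test_null_ratio_shifts_effect_scale(self, fitted):
        ds, params, model = fitted
        res52 = run_mean(ds, model, TestConfig(null_ratio=0.52))
        res50 = run_mean(ds, model, TestConfig(null_ratio=0.50))
        # identical fits, different null: log2fc differs by the odds of x
        delta = np.log2(0.52 / 0.48)
        diff = (res50["log2fc"] - res52["log2fc"]).dropna()
        assert np.allclose(diff, delta, atol=1e-6)


class TestVarTest:
    @pytest.fixture(scope="class")
    def var_setup(self):
        rng = np.random.default_rng(5)
        theta = np.exp(rng.uniform(np.log(0.02), np.log(0.2), 60))
        theta[:8] = 2.0  # strongly overdispersed positives
        ds = make_bb_dataset(60, 300, ar=0.5, theta=theta, seed=6)
        params, model = estimate_dispersion(ds, SCFG)
        return ds, params, model

    def test_positive_controls_detected_with_direction(self, var_setup):
        ds, params, model = var_setup
        res = run_var(ds, model, TestConfig(rng_seed=1, n_permutations=200), params=params)
        assert (res["fdr"].iloc[:8] < 0.05).all()
        assert (res["direction"].iloc[:8] == "over").all()

    def test_reproducible_and_bounded(self, var_setup):
        ds, params, model = var_setup
        cfg = TestConfig(rng_seed=9, n_permutations=100)
        r1 = run_var(ds, model, cfg, params=params)
        r2 = run_var(ds, model, cfg, params=params)
        pd.testing.assert_frame_equal(r1, r2)
        p = r1["p_value"].dropna()
        assert (p >= 1 / 101).all() and (p <= 1).all()

    def test_permutation_count_validated(self):
        with pytest.raises(ValueError, match="100"):
            TestConfig(n_permutations=50)

    def test_requires_params(self, var_setup):
        ds, params, model = var_setup
        with pytest.raises(ValueError, match="params"):
            run_var(ds, model, TestConfig())


class TestGroupTests:
    @staticmethod
    def grouped(theta_by_bin=(1e-3, 1e-3, 1e-3), mu_by_bin=(0.5, 0.5, 0.5),
                n_genes=60, n_cells=300, seed=0):
        rng = np.random.default_rng(seed)
        groups = pd.Categorical(
            np.repeat(["b1", "b2", "b3"], n_cells // 3),
            categories=["b1", "b2", "b3"], ordered=True,
        )
        total = rng.poisson(25, size=(n_genes, n_cells))
        ref = np.zeros_like(total)
        for k in range(3):
            cols = np.asarray(groups.codes) == k
            th = max(theta_by_bin[k], 1e-8)
            p = rng.beta(mu_by_bin[k] / th, (1 - mu_by_bin[k]) / th,
                         size=(n_genes, cols.sum()))
            ref[:, cols] = rng.binomial(total[:, cols], p)
        return AllelicDataset(
            ref, total,
            pd.Index([f"g{i}" for i in range(n_genes)]),
            pd.Index([f"c{j}" for j in range(n_cells)]),
            groups=groups,
        )

    def test_requires_groups_and_multiple_levels(self):
        ds = make_bb_dataset(30, 60, 0.5, 0.05, seed=3)
        with pytest.raises(ValueError, match="group"):
            estimate_group_models(ds, SCFG)
        one = self.grouped(n_genes=30)
        one_level = AllelicDataset(
            one.ref, one.total, one.gene_ids, one.cell_ids,
            groups=pd.Categorical(["only"] * one.n_cells),
        )
        with pytest.raises(ValueError, match="at least 2"):
            estimate_group_models(one_level, SCFG)

    def test_mean_change_detected_variance_not(self):
        ds = self.grouped(mu_by_bin=(0.42, 0.5, 0.58), seed=11)
        est = estimate_group_models(ds, SCFG)
        rm = run_group_mean(ds, est, TestConfig())
        assert (rm["fdr"] < 0.1).mean() > 0.9

    def test_statistic_invariant_to_within_group_shuffle(self):
        ds = self.grouped(mu_by_bin=(0.45, 0.5, 0.55), seed=12)
        est = estimate_group_models(ds, SCFG)
        base = run_group_mean(ds, est, TestConfig())
        rng = np.random.default_rng(1)
        codes = np.asarray(ds.groups.codes)
        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(codes == k)) for k in range(3)]
        )
        ds2 = ds.subset_cells(perm)
        est2 = estimate_group_models(ds2, SCFG)
        shuffled = run_group_mean(ds2, est2, TestConfig())
        # summation order changes at float precision only
        np.testing.assert_allclose(
            base["statistic"], shuffled["statistic"], rtol=1e-3, atol=1e-3
        )

    def test_nonnegative_statistics(self):
        ds = self.grouped(seed=13)
        est = estimate_group_models(ds, SCFG)
        for res in (run_group_mean(ds, est, TestConfig()),
                    run_group_var(ds, est, TestConfig(), FilterConfig())):
            s = res["statistic"].dropna()
            assert (s >= -1e-8).all()

    def test_group_var_detects_dispersion_change(self):
        ds = self.grouped(theta_by_bin=(1e-3, 0.1, 0.4), seed=14, n_cells=600)
        est = estimate_group_models(ds, SCFG)
        rv = run_group_var(ds, est, TestConfig(), FilterConfig())
        assert (rv["fdr"] < 0.1).mean() > 0.8


def test_binomial_test_inflates_on_overdispersed_null():
    """The naive pooled binomial test ignores extra-binomial variance and
    floods overdispersed-but-balanced genes with false calls; the
    moderated beta-binomial mean test does not."""
    ds = make_bb_dataset(150, 300, ar=0.5, theta=0.3, mean_total=60, seed=8)
    naive = binomial_mean_test(ds, 0.5)
    params, model = estimate_dispersion(ds, SCFG)
    moderated = run_mean(ds, model, TestConfig())
    assert (naive["fdr"] < 0.05).mean() > 0.3
    assert (moderated["fdr"] < 0.05).mean() < 0.02
    assert (naive["fdr"] < 0.05).mean() > 10 * (moderated["fdr"] < 0.05).mean()
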