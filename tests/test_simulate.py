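import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scase import (
    AR_GRID,
    SimulationSpec,
    evaluate_performance,
    simulate_allelic,
    simulate_group_scenario,
    simulate_imbalance_dataset,
    simulate_rme_dataset,
    simulate_totals,
    stratify_genes,
)
from scase.simulate import sample_rme_shapes, simulate_rme_allelic


class TestTotals:
    def test_deterministic_given_seed(self):
        spec = SimulationSpec(n_genes=50, n_cells=40, seed=3)
        t1, c1, g1 = simulate_totals(spec)
        t2, c2, g2 = simulate_totals(spec)
        np.testing.assert_array_equal(t1, t2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_full_zero_inflation_gives_empty_matrix(self):
        spec = SimulationSpec(n_genes=20, n_cells=30, zero_inflation=1.0, seed=0)
        totals, _, _ = simulate_totals(spec)
        assert (totals == 0).all()

    def test_means_track_configured_abundances(self):
        lncpm = np.log(np.array([1e4, 1e3, 1e2]))  # fixed absolute CPMs
        spec = SimulationSpec(
            n_genes=3, n_cells=4000, lncpm=tuple(lncpm), median_depth=10000.0,
            zero_inflation=0.0, archetype_lfc_sd=0.0, seed=1,
        )
        totals, _, _ = simulate_totals(spec)
        expected = np.exp(lncpm) / 1e6 * 10000.0
        np.testing.assert_allclose(totals.mean(axis=1), expected, rtol=0.1)

    def test_zero_fraction_increases_with_inflation(self):
        base = SimulationSpec(n_genes=100, n_cells=200, zero_inflation=0.0, seed=2)
        infl = SimulationSpec(n_genes=100, n_cells=200, zero_inflation=0.4, seed=2)
        z0 = (simulate_totals(base)[0] == 0).mean()
        z1 = (simulate_totals(infl)[0] == 0).mean()
        assert z1 > z0 + 0.2


class TestAllelic:
    def test_boundary_ratio_rejected(self):
        totals = np.full((2, 10), 5)
        with pytest.raises(ValueError, match="strictly"):
            simulate_allelic(totals, 1.0, 0.1)

    def test_support_and_pooled_ratio(self):
        rng = np.random.default_rng(4)
        totals = rng.poisson(30, size=(50, 2000))
        ref = simulate_allelic(totals, 0.3, 0.05, seed=5)
        assert (ref <= totals).all()
        pooled = ref.sum(axis=1) / totals.sum(axis=1)
        assert np.abs(pooled - 0.3).max() < 0.03

    def test_tiny_theta_matches_binomial_variance(self):
        totals = np.full((1, 5000), 100)
        ref = simulate_allelic(totals, 0.5, 1e-10, seed=6)
        ratios = ref[0] / 100
        assert np.var(ratios) == pytest.approx(0.25 / 100, rel=0.10)

    def test_large_theta_gives_u_shape(self):
        totals = np.full((1, 5000), 100)
        ref = simulate_allelic(totals, 0.5, 5.0, seed=7)
        ratios = ref[0] / 100
        tail_mass = ((ratios < 0.1) | (ratios > 0.9)).mean()
        binom_tail = 2 * stats.binom.cdf(9, 100, 0.5)
        assert tail_mass > 0.5
        assert tail_mass > 100 * max(binom_tail, 1e-12)


class TestGroupScenario:
    def test_requires_three_bins(self):
        with pytest.raises(ValueError, match="3 bins"):
            SimulationSpec(bins=((0.5, 0.1), (0.5, 0.1)))

    def test_mean_scenario_hits_bin_targets(self):
        spec = SimulationSpec(
            n_genes=150, n_cells=3000, seed=8,
            bins=((0.45, 1e-3), (0.5, 1e-3), (0.55, 1e-3)),
        )
        ds, truth = simulate_group_scenario(spec, n_signal=150)
        codes = np.asarray(ds.groups.codes)
        targets = (0.45, 0.5, 0.55)
        sizes = [int((codes == k).sum()) for k in range(3)]
        assert max(sizes) - min(sizes) <= 1  # equal-sized tertiles
        for k in range(3):
            cols = codes == k
            pooled = ds.ref[:, cols].sum() / ds.total[:, cols].sum()
            assert pooled == pytest.approx(targets[k], abs=0.01)

    def test_variance_scenario_orders_bin_variances(self):
        spec = SimulationSpec(
            n_genes=150, n_cells=3000, seed=9,
            bins=((0.5, 1e-3), (0.5, 0.05), (0.5, 0.2)),
        )
        ds, _ = simulate_group_scenario(spec, n_signal=150)
        codes = np.asarray(ds.groups.codes)
        vs = []
        for k in range(3):
            cols = codes == k
            tot = ds.total[:, cols]
            ok = tot >= 5
            vs.append(np.var((ds.ref[:, cols] / np.where(ok, tot, np.nan))[ok]))
        assert vs[0] < vs[1] < vs[2]

    def test_control_genes_follow_control_params(self):
        spec = SimulationSpec(
            n_genes=100, n_cells=900, seed=10,
            bins=((0.1, 1e-3), (0.5, 1e-3), (0.9, 1e-3)),
        )
        ds, truth = simulate_group_scenario(spec, n_signal=50)
        codes = np.asarray(ds.groups.codes)
        ctl = ~truth["signal"].to_numpy()
        pooled = ds.ref[np.ix_(ctl, codes == 0)].sum() / ds.total[np.ix_(ctl, codes == 0)].sum()
        assert pooled == pytest.approx(0.5, abs=0.02)


class TestRME:
    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError, match="< 1"):
            SimulationSpec(rme=((1.0, 0.5),))
        with pytest.raises(ValueError, match="positive"):
            simulate_rme_allelic(np.full((1, 5), 10), -0.5, 0.5)

    def test_sampled_shape_pairs_satisfy_rules(self):
        rng = np.random.default_rng(11)
        pairs = sample_rme_shapes(500, rng)
        assert (pairs < 1).all() and (pairs > 0).all()
        assert (np.abs(pairs[:, 0] - pairs[:, 1]) < 0.5).all()

    def test_u_shape_mass_matches_betabinom_oracle(self):
        rng = np.random.default_rng(12)
        totals = rng.poisson(20, size=(1, 3000)) + 1
        ref = simulate_rme_allelic(totals, 0.3, 0.3, seed=13)
        ratios = ref[0] / totals[0]
        extreme = ((ratios < 0.25) | (ratios > 0.75)).mean()
        # oracle: P(m/n < 0.25 or > 0.75) under BetaBinomial(n, 0.3, 0.3)
        expected = np.mean(
            [
                stats.betabinom.cdf(np.ceil(0.25 * n) - 1, n, 0.3, 0.3)
                + stats.betabinom.sf(np.floor(0.75 * n), n, 0.3, 0.3)
                for n in totals[0]
            ]
        )
        assert extreme == pytest.approx(expected, abs=0.03)
        # far more extreme-ratio cells than binomial sampling alone produces
        binom_extreme = np.mean(
            [
                stats.binom.cdf(np.ceil(0.25 * n) - 1, n, 0.5)
                + stats.binom.sf(np.floor(0.75 * n), n, 0.5)
                for n in totals[0]
            ]
        )
        assert extreme > binom_extreme + 0.3

    def test_dataset_truth_labels_aligned(self):
        ds, truth = simulate_rme_dataset(n_cells=50, n_rme=20, n_background=30, seed=14)
        assert truth["rme"].sum() == 20
        assert len(truth) == ds.n_genes == 50
        assert (truth["theta"] > 0).all()


class TestStratification:
    def test_dispersion_thresholds(self):
        totals = np.random.default_rng(15).poisson(10, size=(3, 50))
        out = stratify_genes(totals, theta_hat=[0.004, 0.44, 0.46])
        assert list(out["dispersion_stratum"]) == ["low", "medium", "high"]

    def test_expression_quantile_scheme(self):
        rng = np.random.default_rng(16)
        lam = np.exp(np.linspace(0, 8, 100))
        totals = rng.poisson(lam[:, None], size=(100, 200))
        out = stratify_genes(totals)
        counts = out["expression_stratum"].value_counts()
        assert counts["high"] == 10 and counts["medium"] == 50 and counts["low"] == 40
        # the 95th-percentile gene lands in the high stratum
        g95 = np.argsort(out["mean_log_tpm"].to_numpy())[94]
        assert out["expression_stratum"].iloc[g95] == "high"


class TestEvaluation:
    def frame(self, fdr):
        return pd.DataFrame({"fdr": fdr}, index=pd.Index(range(len(fdr))).astype(str))

    def test_arithmetic(self):
        truth = pd.Series([True] * 10 + [False] * 90, index=pd.Index(range(100)).astype(str))
        fdr = np.ones(100)
        fdr[:9] = 0.001
        rep = evaluate_performance(truth, self.frame(fdr), fdr_cutoff=0.1)
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(1.0)

    def test_all_null_no_detections(self):
        truth = pd.Series([False] * 20, index=pd.Index(range(20)).astype(str))
        rep = evaluate_performance(truth, self.frame(np.ones(20)), 0.1)
        assert rep.specificity == 1.0
        assert np.isnan(rep.sensitivity)

    def test_cutoff_one_calls_everything_tested(self):
        truth = pd.Series([True] * 20, index=pd.Index(range(20)).astype(str))
        rep = evaluate_performance(truth, self.frame(np.full(20, 0.99)), fdr_cutoff=1.0)
        assert rep.sensitivity == 1.0

    def test_untested_counting_modes(self):
        truth = pd.Series([True] * 4, index=pd.Index(range(4)).astype(str))
        fdr = np.array([0.01, 0.01, np.nan, np.nan])
        assert evaluate_performance(truth, self.frame(fdr), 0.1).sensitivity == 0.5
        assert (
            evaluate_performance(truth, self.frame(fdr), 0.1, denominator="tested").sensitivity
            == 1.0
        )


def test_power_monotone_along_ar_grid():
    """Mean-test power grows with deviation from balance along the AR grid."""
    from scase import ShrinkageConfig, TestConfig, estimate_dispersion, test_mean

    spec = SimulationSpec(n_genes=240, n_cells=400, seed=17)
    rates = []
    for ar in (0.5, 0.45, 0.4, 0.3):
        assert ar in AR_GRID or ar == 0.5
        ds, truth = simulate_imbalance_dataset(spec, ar, theta=0.01, seed=18)
        params, model = estimate_dispersion(ds, ShrinkageConfig(low_theta_threshold=0.005))
        res = test_mean(ds, model, TestConfig())
        rates.append((res["fdr"] < 0.001).mean())
    assert rates[0] < 0.01
    assert all(b >= a - 0.02 for a, b in zip(rates[1:], rates[2:]))
    assert rates[-1] > rates[1]
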