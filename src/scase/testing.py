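"""Likelihood-ratio tests for allelic imbalance and allelic variance.

Four tests, all built on the beta-binomial likelihood with moderated
dispersion:

* mean       — is a gene's mean allelic ratio different from the
               background ratio x?  chi2(1) LRT.
* var        — does a gene's (shrunken) dispersion deviate from the
               trend expectation at its expression level?  Calibrated by
               parametric permutation (counts re-simulated under the
               trend null, dispersion re-estimated and re-shrunk per
               replicate).
* group_mean — does the mean allelic ratio change across discrete cell
               groups (cell types / pseudotime bins)?  chi2 LRT.
* group_var  — does the allelic dispersion change across groups at a
               shared mean?  chi2 LRT.

Low-variance genes use their empirical dispersion wherever the shrunken
value would otherwise appear (selective shrinkage); this is already
baked into ``DispersionModel.theta_shrunk``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .data import AllelicDataset, FilterConfig, gene_filter_mask
from .shrinkage import DispersionModel, ShrinkageConfig, estimate_dispersion

_EPS_MU = 1e-6
_LOGIT_LO, _LOGIT_HI = -13.0, 13.0
_LOG_TH_LO, _LOG_TH_HI = np.log(1e-6), np.log(100.0)
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class TestConfig:
    """Shared settings for the allelic tests.

    ``null_ratio`` is the background allelic ratio x (0.5 for simulated
    data; the empirical genome-wide value, e.g. 0.52, for real data with
    mapping bias).
    """

    null_ratio: float = 0.5
    n_permutations: int = 500
    fdr_alpha: float = 0.05
    group_df: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.null_ratio < 1:
            raise ValueError("null_ratio must lie strictly in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# vectorized likelihood helpers


def _row_loglik(ref, total, mu, theta):
    """Per-gene summed beta-binomial log-likelihood (binomial coefficient
    omitted — it cancels in every likelihood ratio here)."""
    mu = np.clip(np.atleast_1d(np.asarray(mu, dtype=float)), _EPS_MU, 1 - _EPS_MU)
    theta = np.clip(np.atleast_1d(np.asarray(theta, dtype=float)), 1e-12, None)
    a = (mu / theta)[:, None]
    b = ((1 - mu) / theta)[:, None]
    m = np.asarray(ref, dtype=float)
    n = np.asarray(total, dtype=float)
    terms = (
        gammaln(m + a) + gammaln(n - m + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )
    return terms.sum(axis=1)


def _profile_mu(ref, total, theta):
    """Row-wise MLE of mu at fixed per-gene theta (golden-section on the
    logit scale).  Returns (mu_hat, loglik at mu_hat)."""
    theta = np.asarray(theta, dtype=float)
    lo = np.full(theta.shape, _LOGIT_LO)
    hi = np.full(theta.shape, _LOGIT_HI)

    def f(z):
        return _row_loglik(ref, total, 1.0 / (1.0 + np.exp(-z)), theta)

    lo, hi, _ = _golden_max(f, lo, hi, iters=45)
    z = (lo + hi) / 2.0
    mu = 1.0 / (1.0 + np.exp(-z))
    return mu, _row_loglik(ref, total, mu, theta)


def _golden_max(f, lo, hi, iters):
    """Vectorized golden-section maximization of a unimodal f over [lo, hi].

    Reuses one interior evaluation per iteration: when the bracket
    shrinks to the left the old c becomes the new d (and vice versa).
    """
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc > fd
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c = hi - _INVPHI * (hi - lo)
        d = lo + _INVPHI * (hi - lo)
        fz = f(np.where(left, c, d))
        fc_old = fc
        fc = np.where(left, fz, fd)
        fd = np.where(left, fc_old, fz)
    return lo, hi, np.maximum(fc, fd)


def _theta_use(disp: DispersionModel, mode: str = "selective") -> np.ndarray:
    """Dispersion entering the mean test.

    'selective' (default): the model's shrunken values, which already
    exempt low-variance genes.  'shrunken': shrinkage forced on every
    gene.  'raw': unmoderated per-gene MLEs.
    """
    if mode == "raw":
        return np.asarray(disp.theta_hat, dtype=float)
    if mode == "shrunken":
        scfg = disp.config
        d = scfg.delta_eff
        scale = scfg.N / (scfg.N - 1.0)
        return (scale * disp.theta_hat + d * disp.theta_shared) / (1.0 + d)
    return np.asarray(disp.theta_shrunk, dtype=float)


# ---------------------------------------------------------------------------
# mean test


def test_mean(
    ds: AllelicDataset,
    disp: DispersionModel,
    cfg: TestConfig = TestConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    dispersion: str = "selective",
) -> pd.DataFrame:
    """Allelic-imbalance LRT: H0 mu = x vs H1 mu free, dispersion fixed.

    Returns a gene-indexed frame with statistic, p_value, fdr, the
    fitted mean ``mu_hat`` and the odds-scale ``log2fc`` relative to x.
    Genes failing the coverage filter get NA rows.  ``dispersion``
    selects the moderation mode ('selective', 'shrunken', 'raw'); see
    ``_theta_use``.
    """
    x = cfg.null_ratio
    theta = _theta_use(disp, dispersion)
    tested = gene_filter_mask(ds, filter_cfg) & np.isfinite(theta) & (theta > 0)

    stat = np.full(ds.n_genes, np.nan)
    p = np.full(ds.n_genes, np.nan)
    mu_hat = np.full(ds.n_genes, np.nan)
    if tested.any():
        ref_t, tot_t = ds.ref[tested], ds.total[tested]
        th = theta[tested]
        ll0 = _row_loglik(ref_t, tot_t, np.full(th.shape, x), th)
        mu1, ll1 = _profile_mu(ref_t, tot_t, th)
        s = np.clip(2.0 * (ll1 - ll0), 0.0, None)
        stat[tested] = s
        p[tested] = stats.chi2.sf(s, df=1)
        mu_hat[tested] = mu1

    mu_c = np.clip(mu_hat, _EPS_MU, 1 - _EPS_MU)
    log2fc = np.log2(mu_c / (1 - mu_c)) - np.log2(x / (1 - x))
    return pd.DataFrame(
        {
            "test": "mean",
            "statistic": stat,
            "p_value": p,
            "fdr": adjust_bh(p),
            "mu_hat": mu_hat,
            "log2fc": np.where(np.isfinite(mu_hat), log2fc, np.nan),
            "theta_used": theta,
            "tested": tested,
        },
        index=pd.Index(ds.gene_ids, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# variance test (permutation-calibrated)


def _theta_tables_loglik(m_mat, n_vec, mu, theta_vec, n_unique, n_counts):
    """Beta-binomial log-likelihood of each row of ``m_mat`` at its own
    theta, mean fixed at ``mu``.

    For UMI-scale counts, log-gamma is evaluated on B x (max count + 1)
    tables and gathered, instead of on the full B x cells grid; for
    deeply covered genes (max count larger than the cell number) the
    direct broadcast is cheaper and used instead.
    """
    theta_vec = np.clip(np.atleast_1d(theta_vec), 1e-12, None)
    a = mu / theta_vec
    b = (1.0 - mu) / theta_vec
    t = 1.0 / theta_vec
    B = theta_vec.size
    # one shared data row may be evaluated against several theta values
    m_mat = np.broadcast_to(m_mat, (B, m_mat.shape[1]))
    d_mat = (n_vec[None, :] - m_mat).astype(np.int64)
    k1_max = int(m_mat.max())
    k2_max = int(d_mat.max())
    n_obs = n_vec.size
    s3 = gammaln(t[:, None] + n_unique[None, :]) @ n_counts
    const = n_obs * (gammaln(t) - gammaln(a) - gammaln(b))
    if k1_max + k2_max < 2 * n_obs:
        T1 = gammaln(a[:, None] + np.arange(k1_max + 1)[None, :])
        T2 = gammaln(b[:, None] + np.arange(k2_max + 1)[None, :])
        rows = np.arange(B)[:, None]
        s1 = T1[rows, m_mat].sum(axis=1)
        s2 = T2[rows, d_mat].sum(axis=1)
    else:
        s1 = gammaln(m_mat + a[:, None]).sum(axis=1)
        s2 = gammaln(d_mat + b[:, None]).sum(axis=1)
    return s1 + s2 - s3 + const


def _profile_theta_rows(m_mat, n_vec, mu, n_unique, n_counts, iters=30):
    """Row-wise MLE of theta at fixed mu via golden section on log theta."""
    B = m_mat.shape[0]
    lo = np.full(B, _LOG_TH_LO)
    hi = np.full(B, _LOG_TH_HI)

    def f(z):
        return _theta_tables_loglik(m_mat, n_vec, mu, np.exp(z), n_unique, n_counts)

    lo, hi, _ = _golden_max(f, lo, hi, iters=iters)
    return np.exp((lo + hi) / 2.0)


def _simulate_bb_counts(rng, n_vec, mu, theta, size):
    """Draw ``size`` x len(n_vec) beta-binomial counts (gamma-free:
    Beta then Binomial; near-zero theta falls back to pure binomial)."""
    if theta < 1e-8:
        return rng.binomial(n_vec[None, :].astype(np.int64), mu, size=(size, n_vec.size))
    a, b = mu / theta, (1 - mu) / theta
    pmat = rng.beta(a, b, size=(size, n_vec.size))
    return rng.binomial(n_vec[None, :].astype(np.int64), pmat)


def test_var(
    ds: AllelicDataset,
    disp: DispersionModel,
    cfg: TestConfig = TestConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    params: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Allelic-variance test against the trend expectation.

    Observed statistic: LR between the trend dispersion (null) and the
    gene's shrunken dispersion (alternative), mean held at the gene's
    MLE.  Empirical p-value: reference counts are re-simulated B times
    under the null (BetaBinomial(n_ij, mu_hat, theta_shared)); each
    replicate's dispersion is re-estimated by MLE and re-shrunk against
    the *original* trend, and p = (1 + #{LR_perm >= LR_obs}) / (1 + B).
    ``direction`` is 'over' when the shrunken dispersion exceeds the
    trend value, else 'under'.
    """
    if params is None:
        raise ValueError("test_var needs the per-gene parameter table (params=)")
    B = cfg.n_permutations
    scfg = disp.config
    scale = scfg.N / (scfg.N - 1.0)
    d_eff = scfg.delta_eff

    tested = (
        gene_filter_mask(ds, filter_cfg)
        & np.isfinite(disp.theta_shrunk)
        & np.isfinite(disp.theta_shared)
        & np.isfinite(params["mu"].to_numpy(dtype=float))
    )
    stat = np.full(ds.n_genes, np.nan)
    p = np.full(ds.n_genes, np.nan)
    direction = np.full(ds.n_genes, "", dtype=object)
    ratio = np.full(ds.n_genes, np.nan)

    mu_all = np.clip(params["mu"].to_numpy(dtype=float), _EPS_MU, 1 - _EPS_MU)
    for i in np.flatnonzero(tested):
        n_row = ds.total[i]
        keep = n_row > 0
        n_vec = n_row[keep].astype(np.int64)
        m_obs = ds.ref[i][keep].astype(np.int64)
        mu = float(mu_all[i])
        th_sh = float(disp.theta_shared[i])
        th_wl = float(disp.theta_shrunk[i])
        n_unique, n_counts = np.unique(n_vec, return_counts=True)
        n_counts = n_counts.astype(float)

        # observed statistic passes through the identical functional as
        # every permutation replicate (profile dispersion MLE at the
        # gene's fixed mean, then shrinkage), so the empirical p-value
        # compares like with like
        th_obs = float(_profile_theta_rows(m_obs[None, :], n_vec, mu, n_unique, n_counts)[0])
        if th_obs < scfg.low_theta_threshold:
            th_obs_wl = th_obs
        else:
            th_obs_wl = (scale * th_obs + d_eff * th_sh) / (1.0 + d_eff)
        obs_ll = _theta_tables_loglik(
            m_obs[None, :], n_vec, mu, np.array([th_obs_wl, th_sh]), n_unique, n_counts
        )
        lr_obs = max(2.0 * (obs_ll[0] - obs_ll[1]), 0.0)

        rng = np.random.default_rng([cfg.rng_seed, i])
        m_sim = _simulate_bb_counts(rng, n_vec, mu, th_sh, B)
        th_star = _profile_theta_rows(m_sim, n_vec, mu, n_unique, n_counts)
        low = th_star < scfg.low_theta_threshold
        th_star_wl = np.where(
            low, th_star, (scale * th_star + d_eff * th_sh) / (1.0 + d_eff)
        )
        ll_alt = _theta_tables_loglik(m_sim, n_vec, mu, th_star_wl, n_unique, n_counts)
        ll_null = _theta_tables_loglik(
            m_sim, n_vec, mu, np.full(B, th_sh), n_unique, n_counts
        )
        lr_perm = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)

        stat[i] = lr_obs
        p[i] = (1.0 + np.sum(lr_perm >= lr_obs - 1e-12)) / (1.0 + B)
        direction[i] = "over" if th_wl > th_sh else "under"
        ratio[i] = th_wl / th_sh

    return pd.DataFrame(
        {
            "test": "var",
            "statistic": stat,
            "p_value": p,
            "fdr": adjust_bh(p),
            "direction": direction,
            "theta_ratio": ratio,
            "theta_shrunk": disp.theta_shrunk,
            "theta_shared": disp.theta_shared,
            "tested": tested,
        },
        index=pd.Index(ds.gene_ids, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# group tests


@dataclass
class GroupEstimates:
    """Global and per-group parameter/dispersion fits for group tests."""

    global_params: pd.DataFrame
    global_model: DispersionModel
    group_params: dict
    group_models: dict

    @property
    def levels(self):
        return list(self.group_params)


def estimate_group_models(
    ds: AllelicDataset,
    shrink_cfg: ShrinkageConfig = ShrinkageConfig(),
    exclude_low_variance: bool = False,
    selective: bool = False,
) -> GroupEstimates:
    """Fit beta-binomial parameters, trend and shrinkage globally and per
    group.

    Two deliberate departures from the single-dataset pipeline: the
    trend is fit on all genes (in group designs whole parameter regimes
    can fall below the low-variance cutoff, and excluding them would
    anchor the trend only on noise-inflated sparse genes), and shrinkage
    is non-selective (exempting low-dispersion genes lets per-group
    dispersion estimates fit noise in the alternative, which inflates
    the group LRTs on homogeneous data).
    """
    if ds.groups is None:
        raise ValueError("dataset has no group labels")
    from dataclasses import replace as _replace

    shrink_cfg = _replace(shrink_cfg, selective=selective)
    levels = list(ds.groups.categories)
    if len(levels) < 2:
        raise ValueError("group tests need at least 2 groups")
    gp, gm = estimate_dispersion(ds, shrink_cfg, exclude_low_variance=exclude_low_variance)
    group_params, group_models = {}, {}
    codes = np.asarray(ds.groups.codes)
    for k, lev in enumerate(levels):
        sub = ds.subset_cells(codes == k)
        pp, mm = estimate_dispersion(sub, shrink_cfg, exclude_low_variance=exclude_low_variance)
        group_params[lev] = pp
        group_models[lev] = mm
    return GroupEstimates(gp, gm, group_params, group_models)


def _group_coverage_ok(ds: AllelicDataset, min_counts: int, min_cells: int) -> np.ndarray:
    codes = np.asarray(ds.groups.codes)
    ok = np.ones(ds.n_genes, dtype=bool)
    for k in range(len(ds.groups.categories)):
        cells = codes == k
        ok &= (ds.total[:, cells] >= min_counts).sum(axis=1) >= min_cells
    return ok


def _group_lrt(
    ds: AllelicDataset,
    est: GroupEstimates,
    cfg: TestConfig,
    filter_cfg: FilterConfig,
    which: str,
    null_dispersion: str = "shrunken",
) -> pd.DataFrame:
    if ds.groups is None:
        raise ValueError("dataset has no group labels")
    levels = est.levels
    codes = np.asarray(ds.groups.codes)
    mu_glob = np.clip(
        est.global_params["mu"].to_numpy(dtype=float), _EPS_MU, 1 - _EPS_MU
    )
    tested = gene_filter_mask(ds, filter_cfg) & _group_coverage_ok(
        ds, filter_cfg.min_counts, filter_cfg.min_cells
    )
    if null_dispersion == "trend":
        th0 = np.asarray(est.global_model.theta_shared, dtype=float)
    else:
        th0 = np.asarray(est.global_model.theta_shrunk, dtype=float)
    tested &= np.isfinite(th0) & (th0 > 0) & np.isfinite(mu_glob)

    # group_mean uses a matched-dispersion null by default: H0 shares the
    # alternative's per-group dispersions and differs only in the mean, so
    # gene-specific dispersion noise cancels from the LRT instead of
    # leaking into it at high coverage
    matched_null = which == "group_mean" and null_dispersion == "matched"

    ll0 = np.full(ds.n_genes, np.nan)
    ll0_acc = np.zeros(ds.n_genes)
    ll1 = np.zeros(ds.n_genes)
    effects = {}
    ok_groups = np.ones(ds.n_genes, dtype=bool)
    for k, lev in enumerate(levels):
        cells = codes == k
        gmodel = est.group_models[lev]
        gparams = est.group_params[lev]
        th_g = np.asarray(gmodel.theta_shrunk, dtype=float)
        mu_g = np.clip(gparams["mu"].to_numpy(dtype=float), _EPS_MU, 1 - _EPS_MU)
        if which == "group_mean":
            mu_use = mu_g
            effects[f"mu_{lev}"] = gparams["mu"].to_numpy(dtype=float)
        else:
            mu_use = mu_glob
            effects[f"theta_{lev}"] = th_g
        ok_groups &= np.isfinite(th_g) & (th_g > 0) & np.isfinite(mu_use)
        sub_ok = np.isfinite(mu_use) & np.isfinite(th_g) & (th_g > 0)
        if sub_ok.any():
            sub = np.ix_(sub_ok, cells)
            contrib = np.zeros(ds.n_genes)
            contrib[sub_ok] = _row_loglik(
                ds.ref[sub], ds.total[sub], mu_use[sub_ok], th_g[sub_ok]
            )
            ll1 += contrib
            if matched_null:
                contrib0 = np.zeros(ds.n_genes)
                contrib0[sub_ok] = _row_loglik(
                    ds.ref[sub], ds.total[sub], mu_glob[sub_ok], th_g[sub_ok]
                )
                ll0_acc += contrib0
    tested &= ok_groups

    if tested.any():
        if matched_null:
            ll0[tested] = ll0_acc[tested]
        else:
            ll0[tested] = _row_loglik(
                ds.ref[tested], ds.total[tested], mu_glob[tested], th0[tested]
            )
    stat = np.where(tested, np.clip(2.0 * (ll1 - ll0), 0.0, None), np.nan)
    p = np.where(tested, stats.chi2.sf(stat, df=cfg.group_df), np.nan)
    out = pd.DataFrame(
        {
            "test": which,
            "statistic": stat,
            "p_value": p,
            "fdr": adjust_bh(p),
            "tested": tested,
        },
        index=pd.Index(ds.gene_ids, name="gene_id"),
    )
    for name, val in effects.items():
        out[name] = val
    return out


def test_group_mean(
    ds: AllelicDataset,
    est: GroupEstimates,
    cfg: TestConfig = TestConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    null_dispersion: str = "matched",
) -> pd.DataFrame:
    """Group-level change in mean allelic ratio.

    H1 lets the mean vary by group, each group at its own shrunken
    dispersion.  The default null ("matched") shares those same
    per-group dispersions and only constrains the mean, so the LRT
    isolates the mean change and per-gene dispersion noise cancels.
    ``null_dispersion='shrunken'`` / ``'trend'`` instead evaluate H0 at
    a single global dispersion (the gene's moderated value, or the
    trend value); both leak dispersion noise into the statistic on
    deeply covered genes.  chi2 with ``cfg.group_df`` degrees of
    freedom (1 by default, matching the published operating
    characteristics; L-1 is the classical choice).
    """
    return _group_lrt(ds, est, cfg, filter_cfg, "group_mean", null_dispersion)


def test_group_var(
    ds: AllelicDataset,
    est: GroupEstimates,
    cfg: TestConfig = TestConfig(),
    filter_cfg: FilterConfig = FilterConfig(min_cells=15),
) -> pd.DataFrame:
    """Group-level change in allelic dispersion at a shared mean.

    H0: global shrunken dispersion; H1: group-specific shrunken
    dispersions, mean fixed at the global MLE.  The default coverage
    filter is stricter (>= 15 cells with >= 5 reads per group), as
    variance changes need more information than mean changes.
    """
    return _group_lrt(ds, est, cfg, filter_cfg, "group_var")


# ---------------------------------------------------------------------------
# naive comparator


def binomial_mean_test(ds: AllelicDataset, x: float = 0.5) -> pd.DataFrame:
    """Pooled per-gene exact binomial test against ratio ``x``.

    Ignores overdispersion entirely — included as the naive baseline
    whose false-positive inflation on overdispersed data motivates the
    beta-binomial model.
    """
    p = np.full(ds.n_genes, np.nan)
    for i in range(ds.n_genes):
        n = int(ds.total[i].sum())
        if n == 0:
            continue
        k = int(ds.ref[i].sum())
        p[i] = stats.binomtest(k, n, x).pvalue
    return pd.DataFrame(
        {"test": "binomial", "p_value": p, "fdr": adjust_bh(p)},
        index=pd.Index(ds.gene_ids, name="gene_id"),
    )
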