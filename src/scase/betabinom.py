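"""Beta-binomial probability computations and per-gene maximum likelihood.

Per-cell reference counts m_j out of totals n_j are modeled as
BetaBinomial(n_j, alpha, beta).  The mean allelic ratio is
mu = alpha/(alpha+beta) and the dispersion theta = 1/(alpha+beta);
theta -> 0 recovers the binomial, theta > 1 gives U-shaped (bimodal)
per-cell allelic ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, psi
from scipy.stats import betabinom as _betabinom

# Shape-parameter bounds: alpha+beta capped so (near-)monoallelic genes
# report a boundary fit instead of diverging.
_SUM_CAP = 1e6
_SUM_FLOOR = 1e-6
_LOG_LO, _LOG_HI = np.log(1e-8), np.log(1e6)


@dataclass
class GeneBBParams:
    """Per-gene beta-binomial estimate."""

    alpha: float
    beta: float
    mu: float
    theta: float
    loglik: float
    converged: bool
    n_cells_used: int
    mean_total: float
    at_boundary: bool = False


def bb_logpmf(m, n, alpha, beta):
    """log P(m | n, alpha, beta) for the beta-binomial distribution."""
    m = np.asarray(m)
    n = np.asarray(n)
    if np.any(m < 0) or np.any(m > n):
        raise ValueError("require 0 <= m <= n")
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(beta) <= 0):
        raise ValueError("shape parameters must be positive")
    out = _betabinom.logpmf(m, n, alpha, beta)
    if out.ndim == 0:
        return float(out)
    return out


def _loglik_terms(m, n, a, b):
    # log-gamma form; supports broadcasting of (a, b) against (m, n)
    return (
        gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        + gammaln(m + a) + gammaln(n - m + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def bb_loglik(ref, total, mu, theta) -> float:
    """Summed log-likelihood in the (mu, theta) parameterization.

    Equals sum of ``bb_logpmf`` with alpha = mu/theta, beta = (1-mu)/theta.
    Cells with total = 0 contribute exactly 0.
    """
    if not (0 < mu < 1):
        raise ValueError("mu must lie strictly in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    ref = np.asarray(ref, dtype=float)
    total = np.asarray(total, dtype=float)
    if ref.size == 0:
        return 0.0
    if np.any(ref < 0) or np.any(ref > total):
        raise ValueError("require 0 <= ref <= total")
    return float(np.sum(_loglik_terms(ref, total, mu / theta, (1 - mu) / theta)))


def _neg_loglik_and_grad(logab, m, n):
    a, b = np.exp(np.clip(logab, _LOG_LO, _LOG_HI))
    t = a + b
    ll = np.sum(_loglik_terms(m, n, a, b))
    common = psi(t) - psi(n + t)
    da = np.sum(psi(m + a) - psi(a) + common)
    db = np.sum(psi(n - m + b) - psi(b) + common)
    # chain rule for log-parameters
    return -ll, np.array([-da * a, -db * b])


def _moment_init(m, n):
    tot = n.sum()
    mu0 = float(np.clip(m.sum() / tot, 1e-3, 1 - 1e-3))
    r = m / n
    v = float(np.var(r))
    denom = mu0 * (1 - mu0)
    inv_n = float(np.mean(1.0 / n))
    if v <= 0 or denom <= 0 or inv_n >= 1:
        return 1.0, 1.0
    rho = (v / denom - inv_n) / (1 - inv_n)
    rho = float(np.clip(rho, 1e-4, 0.99))
    s = 1.0 / rho - 1.0
    s = float(np.clip(s, 1e-3, _SUM_CAP))
    return mu0 * s, (1 - mu0) * s


def fit_bb_mle(
    ref, total, init: Optional[tuple[float, float]] = None
) -> GeneBBParams:
    """Maximum-likelihood beta-binomial fit for one gene.

    Optimizes in (log alpha, log beta) with L-BFGS-B and analytic
    gradients, so positivity holds by construction.  Cells with zero
    total are excluded from the likelihood.  Near-monoallelic genes run
    into the parameter cap and are reported with ``at_boundary=True``
    rather than raising.
    """
    ref = np.asarray(ref, dtype=float)
    total = np.asarray(total, dtype=float)
    keep = total > 0
    m, n = ref[keep], total[keep]
    if m.size == 0:
        raise ValueError("no cells with non-zero total counts")
    if np.any(m < 0) or np.any(m > n):
        raise ValueError("require 0 <= ref <= total")

    if init is None:
        a0, b0 = _moment_init(m, n)
    else:
        a0, b0 = init
    x0 = np.log(np.clip([a0, b0], np.exp(_LOG_LO), np.exp(_LOG_HI)))
    opts = dict(maxiter=500, ftol=1e-11, gtol=1e-8)
    res = optimize.minimize(
        _neg_loglik_and_grad,
        x0,
        args=(m, n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(_LOG_LO, _LOG_HI)] * 2,
        options=opts,
    )
    # the log-likelihood flattens along the theta -> 0 valley; a second
    # start from the uninformative corner guards against stalls there
    if init is None and np.max(np.abs(x0)) > 2.0:
        res2 = optimize.minimize(
            _neg_loglik_and_grad,
            np.zeros(2),
            args=(m, n),
            jac=True,
            method="L-BFGS-B",
            bounds=[(_LOG_LO, _LOG_HI)] * 2,
            options=opts,
        )
        if res2.fun < res.fun:
            res = res2
    a, b = np.exp(np.clip(res.x, _LOG_LO, _LOG_HI))
    at_boundary = False
    s = a + b
    if s > _SUM_CAP:  # rescale preserving mu
        a, b = a * _SUM_CAP / s, b * _SUM_CAP / s
        at_boundary = True
    if s < _SUM_FLOOR:
        a, b = a * _SUM_FLOOR / s, b * _SUM_FLOOR / s
        at_boundary = True
    if max(res.x) >= _LOG_HI - 1e-9 or min(res.x) <= _LOG_LO + 1e-9:
        at_boundary = True
    ll = float(np.sum(_loglik_terms(m, n, a, b)))
    return GeneBBParams(
        alpha=float(a),
        beta=float(b),
        mu=float(a / (a + b)),
        theta=float(1.0 / (a + b)),
        loglik=ll,
        converged=bool(res.success) and np.isfinite(ll),
        n_cells_used=int(m.size),
        mean_total=float(n.mean()),
        at_boundary=at_boundary,
    )


def fit_bb_many(ref: np.ndarray, total: np.ndarray, gene_ids=None) -> pd.DataFrame:
    """Row-wise ``fit_bb_mle`` over a gene x cell matrix pair.

    Genes with no informative cells get NaN parameters (converged=False)
    instead of raising, so callers can keep gene alignment.
    """
    n_genes = ref.shape[0]
    if gene_ids is None:
        gene_ids = pd.RangeIndex(n_genes)
    rows = []
    for i in range(n_genes):
        if not np.any(total[i] > 0):
            rows.append(
                dict(alpha=np.nan, beta=np.nan, mu=np.nan, theta=np.nan,
                     loglik=np.nan, converged=False, n_cells_used=0,
                     mean_total=np.nan, at_boundary=False)
            )
            continue
        p = fit_bb_mle(ref[i], total[i])
        rows.append(p.__dict__)
    df = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"))
    return df


def write_params_table(params: pd.DataFrame, path) -> None:
    cols = ["alpha", "beta", "mu", "theta", "loglik", "converged",
            "n_cells_used", "mean_total"]
    params[cols].to_csv(path, sep="\t")


def read_params_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
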