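"""Synthetic droplet scRNA-seq allelic counts and benchmarking utilities.

Totals are drawn from a parametric zero-inflated negative binomial:
gene relative abundances are log-normal on the ln-CPM scale (spread
chosen so the expression strata used for benchmarking — top 10% "high",
next 50% "medium", remaining 40% "low" — span a dynamic range matching
the highly-variable-gene panels this emulates), cells carry gamma size factors
and one of two archetype states scaling gene means (a stand-in for
low-dimensional latent cell structure), and cells sit on a pseudotime
axis that group scenarios cut into tertiles.  Reference-allele counts
are then drawn per gene from a beta-binomial at configurable mean
allelic ratio and dispersion; RME genes use U-shaped shape pairs (both
parameters < 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import AllelicDataset

#: Allelic-ratio grid used for imbalance power sweeps.
AR_GRID = (
    0.10, 0.30, 0.35, 0.40, 0.42, 0.45, 0.46, 0.47, 0.48, 0.49, 0.50,
    0.51, 0.52, 0.53, 0.54, 0.55, 0.57, 0.60, 0.65, 0.70, 0.90,
)

#: Cell-number sweep for RME robustness runs.
RME_CELL_NUMBERS = (10, 20, 50, 100, 250, 500, 1000)


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of a synthetic allelic experiment."""

    n_genes: int = 2000
    n_cells: int = 3000
    # totals model (ZINB)
    lncpm_sd: float = 2.1
    median_depth: float = 60000.0
    nb_size: float = 1.0
    zero_inflation: float = 0.05
    sf_shape: float = 10.0
    archetype_lfc_sd: float = 0.35
    lncpm: Optional[tuple] = None  # explicit per-gene ln-CPM values (absolute)
    # allelic model
    ar_grid: tuple = AR_GRID
    theta_range: tuple = (1e-4, 1.0)  # log-uniform stand-in when no list given
    theta_source: Optional[tuple] = None
    n_replicates: int = 5
    bins: Optional[tuple] = None  # ((mu_g, theta_g),) * 3
    rme: Optional[tuple] = None   # ((alpha, beta),) pairs, both < 1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        for ar in self.ar_grid:
            if not 0 < ar < 1:
                raise ValueError(f"allelic ratio {ar} outside (0, 1)")
        if self.bins is not None and len(self.bins) != 3:
            raise ValueError("group scenarios use exactly 3 bins")
        if self.rme is not None:
            for a, b in self.rme:
                if a >= 1 or b >= 1:
                    raise ValueError("RME shape pairs require both parameters < 1")


def _gene_ids(n):
    return pd.Index([f"g{i:05d}" for i in range(n)])


def _cell_ids(n):
    return pd.Index([f"c{i:05d}" for i in range(n)])


def simulate_totals(spec: SimulationSpec, rng: Optional[np.random.Generator] = None):
    """Draw the ZINB total-count matrix.

    Returns ``(totals, cells, genes)``: an int64 gene x cell matrix, a
    per-cell frame (pseudotime, archetype, size_factor) and a per-gene
    frame (lncpm).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    G, C = spec.n_genes, spec.n_cells
    if spec.lncpm is not None:
        # explicit ln-CPM values are taken at face value (no renormalization),
        # so a small panel can sit at a chosen absolute coverage
        lncpm = np.asarray(spec.lncpm, dtype=float)
        if lncpm.shape != (G,):
            raise ValueError("lncpm override must have one value per gene")
        rel = np.exp(lncpm) / 1e6
    else:
        draws = rng.normal(0.0, spec.lncpm_sd, size=G)
        rel = np.exp(draws)
        rel = rel / rel.sum()
        lncpm = np.log(rel * 1e6)

    pseudotime = rng.uniform(0.0, 1.0, size=C)
    archetype = (pseudotime > 0.5).astype(int)
    sf = rng.gamma(spec.sf_shape, 1.0 / spec.sf_shape, size=C)
    lfc = rng.normal(0.0, spec.archetype_lfc_sd, size=G)

    lam = rel[:, None] * (spec.median_depth * sf)[None, :]
    lam = lam * np.exp(lfc[:, None] * archetype[None, :])
    r = spec.nb_size
    shape_gamma = rng.gamma(r, 1.0 / r, size=(G, C))
    totals = rng.poisson(lam * shape_gamma)
    if spec.zero_inflation > 0:
        totals[rng.random(size=(G, C)) < spec.zero_inflation] = 0
    cells = pd.DataFrame(
        {"pseudotime": pseudotime, "archetype": archetype, "size_factor": sf},
        index=_cell_ids(C),
    )
    genes = pd.DataFrame({"lncpm": lncpm}, index=_gene_ids(G))
    return totals.astype(np.int64), cells, genes


def simulate_allelic(
    totals: np.ndarray,
    ar,
    theta,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw reference counts from BetaBinomial(totals, ar, theta) per gene."""
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = np.asarray(totals)
    G, C = totals.shape
    ar = np.broadcast_to(np.asarray(ar, dtype=float), (G,)).copy()
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (G,)).copy()
    if np.any((ar <= 0) | (ar >= 1)):
        raise ValueError("allelic ratios must lie strictly in (0, 1)")
    if np.any(theta <= 0):
        raise ValueError("dispersions must be positive")
    near_binom = theta < 1e-8
    th = np.where(near_binom, 1.0, theta)
    p = rng.beta((ar / th)[:, None], ((1 - ar) / th)[:, None], size=(G, C))
    p[near_binom, :] = ar[near_binom, None]
    return rng.binomial(totals, p).astype(np.int64)


def simulate_rme_allelic(
    totals: np.ndarray,
    alpha,
    beta,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> np.ndarray:
    """Reference counts with explicit (alpha, beta) shape pairs (RME)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = np.asarray(totals)
    G, C = totals.shape
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (G,))
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("shape parameters must be positive")
    p = rng.beta(alpha[:, None], beta[:, None], size=(G, C))
    return rng.binomial(totals, p).astype(np.int64)


def _tertile_groups(pseudotime: np.ndarray) -> pd.Categorical:
    order = np.argsort(np.argsort(pseudotime, kind="stable"), kind="stable")
    n = pseudotime.size
    edges = [round(n / 3), round(2 * n / 3)]
    labels = np.where(order < edges[0], "bin1", np.where(order < edges[1], "bin2", "bin3"))
    return pd.Categorical(labels, categories=["bin1", "bin2", "bin3"], ordered=True)


def simulate_group_scenario(
    spec: SimulationSpec,
    n_signal: Optional[int] = None,
    control_bins: tuple = ((0.5, 1e-3),) * 3,
) -> tuple[AllelicDataset, pd.DataFrame]:
    """Three-bin pseudotime scenario with signal and control genes.

    Signal genes follow ``spec.bins`` — per-bin (mean ratio, dispersion)
    pairs, e.g. mean change (0.45, 0.5, 0.55) at constant dispersion
    1e-3, or variance change (1e-3, 0.05, 0.2) at mean 0.5.  Control
    genes use ``control_bins`` (constant 0.5 / 1e-3) in every bin.
    Returns the grouped dataset and a truth frame.
    """
    if spec.bins is None:
        raise ValueError("spec.bins must define the 3-bin scenario")
    rng = np.random.default_rng(spec.seed)
    totals, cells, genes = simulate_totals(spec, rng)
    groups = _tertile_groups(cells["pseudotime"].to_numpy())
    G = spec.n_genes
    if n_signal is None:
        n_signal = G // 2
    signal = np.zeros(G, dtype=bool)
    signal[:n_signal] = True

    ref = np.zeros_like(totals)
    codes = np.asarray(groups.codes)
    for k in range(3):
        cols = codes == k
        mu_sig, th_sig = spec.bins[k]
        mu_ctl, th_ctl = control_bins[k]
        ar = np.where(signal, mu_sig, mu_ctl)
        th = np.where(signal, th_sig, th_ctl)
        ref[:, cols] = simulate_allelic(totals[:, cols], ar, th, rng=rng)

    ds = AllelicDataset(
        ref, totals, genes.index, cells.index, groups=groups,
        gene_annotations=genes,
    )
    truth = pd.DataFrame(
        {
            "signal": signal,
            "bin_mu": [[b[0] for b in (spec.bins if s else control_bins)] for s in signal],
            "bin_theta": [[b[1] for b in (spec.bins if s else control_bins)] for s in signal],
        },
        index=genes.index,
    )
    return ds, truth


def sample_rme_shapes(
    n: int,
    rng: np.random.Generator,
    lo: float = 0.2,
    hi: float = 0.9,
    max_diff: float = 0.5,
) -> np.ndarray:
    """Independent-uniform RME shape pairs conditioned on |a - b| < max_diff."""
    out = np.empty((0, 2))
    while out.shape[0] < n:
        cand = rng.uniform(lo, hi, size=(2 * n, 2))
        keep = np.abs(cand[:, 0] - cand[:, 1]) < max_diff
        out = np.vstack([out, cand[keep]])
    return out[:n]


def simulate_rme_dataset(
    n_cells: int,
    n_rme: int = 500,
    n_background: int = 500,
    spec: Optional[SimulationSpec] = None,
    shape_pairs: Optional[np.ndarray] = None,
    background_theta_range: tuple = (0.005, 0.3),
    rme_lncpm: tuple = (2.8, 0.5),
    seed: int = 0,
) -> tuple[AllelicDataset, pd.DataFrame]:
    """One RME benchmark replicate: RME genes embedded among background.

    RME genes draw counts from U-shaped beta-binomials (both shapes < 1,
    near-equal); background genes are balanced with moderate dispersion
    so the transcriptome-wide trend — against which the confirming
    variance test operates — looks like a normal dataset.  RME and
    background genes share the same moderate expression band (about one
    count per cell) with heavy-tailed totals (NB size 0.15 by default):
    real RME genes are detected in a minority of cells yet still carry
    multi-read cells, which only a strongly overdispersed totals model
    reproduces at that mean.
    """
    rng = np.random.default_rng(seed)
    G = n_rme + n_background
    lncpm = rng.normal(rme_lncpm[0], rme_lncpm[1], size=G)
    base = spec or SimulationSpec(nb_size=0.15)
    tspec = replace(
        base, n_genes=G, n_cells=n_cells, lncpm=tuple(lncpm), seed=seed
    )
    totals, cells, genes = simulate_totals(tspec, rng)

    if shape_pairs is None:
        shape_pairs = sample_rme_shapes(n_rme, rng)
    else:
        shape_pairs = np.asarray(shape_pairs, dtype=float)
        if shape_pairs.shape != (n_rme, 2):
            raise ValueError("shape_pairs must be (n_rme, 2)")
        if np.any(shape_pairs >= 1):
            raise ValueError("RME shape pairs require both parameters < 1")
    ref = np.zeros_like(totals)
    ref[:n_rme] = simulate_rme_allelic(
        totals[:n_rme], shape_pairs[:, 0], shape_pairs[:, 1], rng=rng
    )
    bg_theta = np.exp(
        rng.uniform(
            np.log(background_theta_range[0]), np.log(background_theta_range[1]),
            size=n_background,
        )
    )
    ref[n_rme:] = simulate_allelic(totals[n_rme:], 0.5, bg_theta, rng=rng)

    ds = AllelicDataset(ref, totals, genes.index, cells.index, gene_annotations=genes)
    truth = pd.DataFrame(
        {
            "rme": np.r_[np.ones(n_rme, bool), np.zeros(n_background, bool)],
            "alpha": np.r_[shape_pairs[:, 0], np.full(n_background, np.nan)],
            "beta": np.r_[shape_pairs[:, 1], np.full(n_background, np.nan)],
            "theta": np.r_[
                1.0 / shape_pairs.sum(axis=1), bg_theta
            ],
        },
        index=genes.index,
    )
    return ds, truth


def simulate_rme(
    cell_numbers: Sequence[int] = RME_CELL_NUMBERS,
    n_rme: int = 500,
    n_replicates: int = 30,
    seed: int = 0,
    **kwargs,
):
    """Yield (n_cells, replicate, dataset, truth) over the cell sweep."""
    for n_cells in cell_numbers:
        for rep in range(n_replicates):
            ds, truth = simulate_rme_dataset(
                n_cells, n_rme=n_rme, seed=int(np.random.SeedSequence([seed, n_cells, rep]).generate_state(1)[0] % (2**31)),
                **kwargs,
            )
            yield n_cells, rep, ds, truth


def simulate_imbalance_dataset(
    spec: SimulationSpec,
    ar,
    theta=None,
    seed: Optional[int] = None,
) -> tuple[AllelicDataset, pd.DataFrame]:
    """Flat (ungrouped) dataset with per-gene allelic ratio and dispersion.

    ``ar`` may be a scalar or per-gene array; dispersions default to a
    log-uniform draw over ``spec.theta_range`` (a stand-in for real-data
    estimates).  Truth frame records both.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    totals, cells, genes = simulate_totals(spec, rng)
    G = spec.n_genes
    ar = np.broadcast_to(np.asarray(ar, dtype=float), (G,)).copy()
    if theta is None:
        lo, hi = spec.theta_range
        theta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (G,)).copy()
    ref = simulate_allelic(totals, ar, theta, rng=rng)
    ds = AllelicDataset(ref, totals, genes.index, cells.index, gene_annotations=genes)
    truth = pd.DataFrame({"ar": ar, "theta": theta}, index=genes.index)
    return ds, truth


# ---------------------------------------------------------------------------
# stratification and evaluation


def stratify_genes(
    totals: np.ndarray,
    theta_hat=None,
    gene_ids=None,
    expr_quantiles: tuple = (0.4, 0.9),
    disp_thresholds: tuple = (0.005, 0.45),
) -> pd.DataFrame:
    """Expression and dispersion strata for benchmarking.

    Expression: mean per-cell log2(CPM+1); the top 10% of genes form the
    "high" stratum, the next 50% "medium", the remaining 40% "low".
    Dispersion: low < 0.005, high >= 0.45, medium between.
    """
    totals = np.asarray(totals, dtype=float)
    depth = totals.sum(axis=0)
    cpm = np.divide(totals, depth, out=np.zeros_like(totals), where=depth > 0) * 1e6
    mean_log_tpm = np.log2(cpm + 1.0).mean(axis=1)
    ranks = pd.Series(mean_log_tpm).rank(pct=True, method="first").to_numpy()
    expr = np.where(
        ranks > expr_quantiles[1], "high",
        np.where(ranks > expr_quantiles[0], "medium", "low"),
    )
    out = pd.DataFrame(
        {"mean_log_tpm": mean_log_tpm, "expression_stratum": expr},
        index=gene_ids if gene_ids is not None else pd.RangeIndex(totals.shape[0]),
    )
    if theta_hat is not None:
        th = np.asarray(theta_hat, dtype=float)
        disp = np.where(
            th < disp_thresholds[0], "low",
            np.where(th >= disp_thresholds[1], "high", "medium"),
        )
        disp = np.where(np.isfinite(th), disp, "NA")
        out["dispersion_stratum"] = disp
    return out


@dataclass
class PerformanceReport:
    """Sensitivity/specificity summary, overall and per stratum."""

    fdr_cutoff: float
    n_signal: int
    n_null: int
    sensitivity: float
    specificity: float
    by_stratum: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "fdr_cutoff": self.fdr_cutoff,
            "n_signal": self.n_signal,
            "n_null": self.n_null,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }
        if self.by_stratum is not None:
            d["by_stratum"] = self.by_stratum.reset_index().to_dict(orient="records")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def evaluate_performance(
    truth,
    results: pd.DataFrame,
    fdr_cutoff: float = 0.1,
    strata: Optional[pd.DataFrame] = None,
    denominator: str = "all",
) -> PerformanceReport:
    """Score detections against truth labels.

    ``truth`` is a boolean per-gene signal indicator aligned (by index)
    with ``results`` (needs an ``fdr`` column).  With the default
    ``denominator='all'`` every simulated gene counts: a signal gene
    that never reached testability is a miss, an untested null gene a
    correct non-rejection.  ``denominator='tested'`` restricts both
    rates to genes with a finite FDR.
    """
    truth = pd.Series(truth).reindex(results.index)
    fdr = results["fdr"]
    tested = np.isfinite(fdr.to_numpy(dtype=float))
    called = tested & (fdr.to_numpy(dtype=float) < fdr_cutoff)
    is_sig = truth.to_numpy(dtype=bool)
    in_denom = tested if denominator == "tested" else np.ones_like(tested)

    n_signal = int((is_sig & in_denom).sum())
    n_null = int((~is_sig & in_denom).sum())
    sens = float(called[is_sig & in_denom].mean()) if n_signal else float("nan")
    spec = float((~called[~is_sig & in_denom]).mean()) if n_null else float("nan")

    by_stratum = None
    if strata is not None:
        rows = []
        cols = [c for c in ("expression_stratum", "dispersion_stratum") if c in strata]
        lab = strata.reindex(results.index)
        for key, idx in lab.groupby(cols, observed=True).groups.items():
            loc = results.index.isin(idx)
            s_sig = is_sig & in_denom & loc
            s_null = ~is_sig & in_denom & loc
            rows.append(
                {
                    **dict(zip(cols, key if isinstance(key, tuple) else (key,))),
                    "n_signal": int(s_sig.sum()),
                    "n_null": int(s_null.sum()),
                    "sensitivity": float(called[s_sig].mean()) if s_sig.any() else np.nan,
                    "specificity": float((~called[s_null]).mean()) if s_null.any() else np.nan,
                }
            )
        by_stratum = pd.DataFrame(rows)
    return PerformanceReport(
        fdr_cutoff=fdr_cutoff,
        n_signal=n_signal,
        n_null=n_null,
        sensitivity=sens,
        specificity=spec,
        by_stratum=by_stratum,
    )
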