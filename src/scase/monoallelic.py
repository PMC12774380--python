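"""Monoallelic, random-monoallelic (RME) and incomplete-XCI classification.

The beta-binomial shape parameters summarize the shape of the per-cell
allelic-ratio distribution: either shape below 1 skews mass toward one
allele; both below 1 gives the U-shaped density characteristic of RME,
where individual cells express one allele or the other but rarely both.
Convention used throughout: alpha is the shape tied to the REFERENCE
allele, so alpha < 1 <= beta means cells rarely express the reference
allele (monoallelic for the alternate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import AllelicDataset

CATEGORIES = (
    "biallelic",
    "monoallelic_ref",
    "monoallelic_alt",
    "rme_candidate",
    "rme_confirmed",
    "incomplete_xci",
)

RME_SHAPE_MAX = 1.0
RME_DIFF_MAX = 0.5
XCI_RATIO_LO, XCI_RATIO_HI = 0.25, 0.75
XCI_MIN_FRACTION = 0.15
XCI_MIN_CELLS = 5


@dataclass
class MonoallelicCall:
    gene_id: object
    category: Optional[str]
    alpha: float = np.nan
    beta: float = np.nan
    fraction_biallelic_cells: float = np.nan
    n_biallelic_cells: int = 0
    var_fdr: float = np.nan


def classify_monoallelic(params, gene_id=None) -> MonoallelicCall:
    """Shape-parameter rule: monoallelic iff alpha < 1 OR beta < 1.

    ``params`` is a GeneBBParams or any object with alpha/beta/converged.
    The side is read off whichever parameter is below 1 when only one
    is; both below 1 marks an RME-shaped gene (refined by
    ``classify_rme``).
    """
    a, b = float(params.alpha), float(params.beta)
    if not getattr(params, "converged", True) or not (np.isfinite(a) and np.isfinite(b)):
        warnings.warn(f"non-converged fit for gene {gene_id!r}; category NA", stacklevel=2)
        return MonoallelicCall(gene_id, None, a, b)
    if a < RME_SHAPE_MAX and b < RME_SHAPE_MAX:
        cat = "rme_candidate"  # provisional; confirmation needs the var test
    elif a < RME_SHAPE_MAX:
        cat = "monoallelic_alt"  # weak reference support
    elif b < RME_SHAPE_MAX:
        cat = "monoallelic_ref"
    else:
        cat = "biallelic"
    return MonoallelicCall(gene_id, cat, a, b)


def classify_rme(
    params,
    var_result: Optional[pd.Series] = None,
    gene_id=None,
    fdr_threshold: float = 0.05,
) -> MonoallelicCall:
    """RME rule: both shapes < 1 and |alpha - beta| < 0.5.

    A candidate becomes ``rme_confirmed`` when the allelic-variance test
    supports it (FDR below threshold, direction 'over').  Without a
    variance result the gene stays a candidate.
    """
    call = classify_monoallelic(params, gene_id)
    if call.category is None:
        return call
    a, b = call.alpha, call.beta
    if not (a < RME_SHAPE_MAX and b < RME_SHAPE_MAX and abs(a - b) < RME_DIFF_MAX):
        if call.category == "rme_candidate":
            # U-shaped but asymmetric: plain monoallelic, skewed side
            call.category = "monoallelic_alt" if a < b else "monoallelic_ref"
        return call
    call.category = "rme_candidate"
    if var_result is not None:
        fdr = float(var_result.get("fdr", np.nan))
        call.var_fdr = fdr
        if (
            np.isfinite(fdr)
            and fdr < fdr_threshold
            and var_result.get("direction", "") == "over"
        ):
            call.category = "rme_confirmed"
    return call


def classify_incomplete_xci(
    ds: AllelicDataset,
    gene,
    x_linked: bool = True,
    min_total: int = 2,
) -> MonoallelicCall:
    """Incomplete X inactivation: biallelic escape in a minority of cells.

    Called when the per-cell allelic ratio falls in [0.25, 0.75] in at
    least 15% of informative cells, with a minimum of five such cells.
    Informative cells need >= ``min_total`` reads (a single read cannot
    show biallelism).
    """
    i = ds.gene_ids.get_loc(gene)
    if not x_linked:
        return MonoallelicCall(gene, None)
    tot = ds.total[i]
    keep = tot >= min_total
    n_inf = int(keep.sum())
    if n_inf == 0:
        return MonoallelicCall(gene, None)
    ratio = ds.ref[i][keep] / tot[keep]
    bi = (ratio >= XCI_RATIO_LO) & (ratio <= XCI_RATIO_HI)
    n_bi = int(bi.sum())
    frac = n_bi / n_inf
    cat = (
        "incomplete_xci"
        if (frac >= XCI_MIN_FRACTION and n_bi >= XCI_MIN_CELLS)
        else None
    )
    return MonoallelicCall(
        gene, cat, fraction_biallelic_cells=frac, n_biallelic_cells=n_bi
    )


def classify_dataset(
    ds: AllelicDataset,
    params: pd.DataFrame,
    var_results: Optional[pd.DataFrame] = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classify every gene; precedence rme_confirmed > rme_candidate >
    incomplete_xci > monoallelic_* > biallelic.

    X-linked status is read from ``ds.gene_annotations['chromosome']``
    when present; otherwise XCI calls are skipped with a warning.
    """
    ann = ds.gene_annotations
    have_chrom = ann is not None and "chromosome" in ann.columns
    if not have_chrom:
        warnings.warn("no chromosome annotation; skipping incomplete-XCI calls", stacklevel=2)
    rows = []
    for gene in ds.gene_ids:
        pr = params.loc[gene]
        var_row = None
        if var_results is not None and gene in var_results.index:
            var_row = var_results.loc[gene]
        call = classify_rme(pr, var_row, gene_id=gene, fdr_threshold=fdr_threshold)
        if (
            have_chrom
            and str(ann.loc[gene, "chromosome"]).lstrip("chr").upper() == "X"
            and call.category in ("monoallelic_ref", "monoallelic_alt")
        ):
            xci = classify_incomplete_xci(ds, gene, x_linked=True)
            if xci.category == "incomplete_xci":
                call.category = "incomplete_xci"
                call.fraction_biallelic_cells = xci.fraction_biallelic_cells
                call.n_biallelic_cells = xci.n_biallelic_cells
        rows.append(
            dict(
                gene_id=gene,
                category=call.category,
                alpha=call.alpha,
                beta=call.beta,
                fraction_biallelic_cells=call.fraction_biallelic_cells,
                n_biallelic_cells=call.n_biallelic_cells,
                var_fdr=call.var_fdr,
            )
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    if have_chrom:
        out["chromosome"] = ann["chromosome"]
    return out
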