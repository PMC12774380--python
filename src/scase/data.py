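"""Allelic count data model, I/O, coverage filters and normalization.

The central container pairs two gene x cell matrices: reference-allele
counts and total allelic counts (reference + alternate).  Everything
downstream — beta-binomial fitting, dispersion shrinkage, the allelic
tests — consumes this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Input data violates a model invariant (e.g. ref > total)."""


class FormatError(ValueError):
    """Input files are malformed or dimensionally inconsistent."""


def _as_dense_int(mat, name: str) -> np.ndarray:
    if sparse.issparse(mat):
        mat = mat.toarray()
    arr = np.asarray(mat)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    if arr.size and np.any(arr < 0):
        g, c = np.argwhere(arr < 0)[0]
        raise ValidationError(f"{name} has a negative entry at gene {g}, cell {c}")
    if arr.size and np.any(arr != np.floor(arr)):
        g, c = np.argwhere(arr != np.floor(arr))[0]
        raise ValidationError(f"{name} has a non-integer entry at gene {g}, cell {c}")
    return arr.astype(np.int64)


@dataclass
class AllelicDataset:
    """Paired reference/total allelic count matrices with metadata.

    Matrices are gene-major (genes x cells), dense int64 internally.
    ``groups`` is an optional per-cell categorical label (cell type or
    pseudotime bin); ``size_factors`` optional per-cell positive scalars;
    ``gene_annotations`` an optional per-gene frame (chromosome,
    imprinted flag, ...) indexed like ``gene_ids``.
    """

    ref: np.ndarray
    total: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    groups: Optional[pd.Categorical] = None
    size_factors: Optional[np.ndarray] = None
    gene_annotations: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.ref = _as_dense_int(self.ref, "ref_counts")
        self.total = _as_dense_int(self.total, "total_counts")
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.ref.shape != self.total.shape:
            raise FormatError(
                f"ref {self.ref.shape} and total {self.total.shape} shapes differ"
            )
        if len(self.gene_ids) == 0:
            raise FormatError("empty gene list")
        if len(self.cell_ids) == 0:
            raise FormatError("empty cell list")
        if self.ref.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.ref.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not self.gene_ids.is_unique or not self.cell_ids.is_unique:
            raise FormatError("gene/cell identifiers must be unique")
        bad = self.ref > self.total
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"ref > total for gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        if self.groups is not None:
            self.groups = pd.Categorical(self.groups)
            if len(self.groups) != self.n_cells:
                raise FormatError("groups must cover every cell")
            if pd.isna(self.groups).any():
                raise ValidationError("groups contain missing labels")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (self.n_cells,):
                raise FormatError("size_factors must have one entry per cell")
            if np.any(self.size_factors <= 0) or not np.all(
                np.isfinite(self.size_factors)
            ):
                raise ValidationError("size_factors must be strictly positive")
        if self.gene_annotations is not None:
            self.gene_annotations = self.gene_annotations.reindex(self.gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_genes(self, mask) -> "AllelicDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        ann = None
        if self.gene_annotations is not None:
            ann = self.gene_annotations.iloc[idx]
        return AllelicDataset(
            self.ref[idx], self.total[idx], self.gene_ids[idx], self.cell_ids,
            groups=self.groups, size_factors=self.size_factors, gene_annotations=ann,
        )

    def subset_cells(self, mask) -> "AllelicDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AllelicDataset(
            self.ref[:, idx], self.total[:, idx], self.gene_ids, self.cell_ids[idx],
            groups=None if self.groups is None else self.groups[idx],
            size_factors=None if self.size_factors is None else self.size_factors[idx],
            gene_annotations=self.gene_annotations,
        )

    def to_anndata(self):
        """Export as an AnnData with ref/total layers (cells x genes)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.total.T.astype(np.float32),
            obs=pd.DataFrame(index=self.cell_ids.astype(str)),
            var=(
                self.gene_annotations.copy()
                if self.gene_annotations is not None
                else pd.DataFrame(index=self.gene_ids.astype(str))
            ),
        )
        adata.layers["ref"] = self.ref.T.astype(np.float32)
        if self.groups is not None:
            adata.obs["group"] = np.asarray(self.groups.astype(str))
        if self.size_factors is not None:
            adata.obs["size_factor"] = self.size_factors
        return adata


@dataclass(frozen=True)
class FilterConfig:
    """Gene coverage thresholds.

    ``min_detected_cells`` is the preprocessing rule (a gene expressed in
    fewer cells is dropped outright); ``min_counts``/``min_cells`` is the
    testing rule (at least ``min_cells`` cells with at least
    ``min_counts`` reads).
    """

    min_counts: int = 5
    min_cells: int = 5
    min_detected_cells: int = 10

    def __post_init__(self):
        if min(self.min_counts, self.min_cells, self.min_detected_cells) < 1:
            raise ValueError("filter thresholds must all be >= 1")


def gene_filter_mask(ds: AllelicDataset, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Boolean keep-flags, aligned with ``ds.gene_ids``."""
    detected = (ds.total > 0).sum(axis=1)
    covered = (ds.total >= cfg.min_counts).sum(axis=1)
    return (detected >= cfg.min_detected_cells) & (covered >= cfg.min_cells)


def filter_genes(
    ds: AllelicDataset, cfg: FilterConfig = FilterConfig()
) -> tuple[AllelicDataset, np.ndarray]:
    """Apply coverage filters; returns (filtered dataset, keep flags)."""
    keep = gene_filter_mask(ds, cfg)
    if not keep.any():
        raise ValidationError("no genes pass filters")
    return ds.subset_genes(keep), keep


def empirical_background_ratio(
    ds: AllelicDataset,
    exclude: Optional[np.ndarray] = None,
    per_gene_mean: bool = False,
) -> float:
    """Global background allelic ratio from autosomal, non-imprinted genes.

    Droplet protocols and reference-biased mapping shift the genome-wide
    ratio away from 0.5; the mean test's null is centred on this value.
    ``exclude`` masks out genes (sex chromosomes, imprinted) that carry
    genuine allelic signal.  Default estimator pools counts,
    sum(ref)/sum(total); ``per_gene_mean`` averages per-gene pooled
    ratios instead.
    """
    include = np.ones(ds.n_genes, dtype=bool)
    if exclude is not None:
        include &= ~np.asarray(exclude, dtype=bool)
    if not include.any():
        raise ValidationError("no genes left after exclusion")
    ref, tot = ds.ref[include], ds.total[include]
    if per_gene_mean:
        gene_tot = tot.sum(axis=1)
        ok = gene_tot > 0
        if not ok.any():
            raise ValidationError("zero total counts after exclusion")
        ratio = float(np.mean(ref.sum(axis=1)[ok] / gene_tot[ok]))
    else:
        denom = tot.sum()
        if denom == 0:
            raise ValidationError("zero total counts after exclusion")
        ratio = float(ref.sum() / denom)
    if ratio in (0.0, 1.0):
        warnings.warn(
            f"background allelic ratio at boundary ({ratio}); data appear fully "
            "monoallelic", stacklevel=2,
        )
    return ratio


def library_size_factors(ds: AllelicDataset) -> np.ndarray:
    """Library-size fallback: cell total / median cell total.

    Proper size-factor estimation (pooled deconvolution etc.) is expected
    to happen upstream; this is a simple stand-in.
    """
    depth = ds.total.sum(axis=0).astype(float)
    med = np.median(depth[depth > 0])
    sf = depth / med
    sf[sf <= 0] = 1.0
    return sf


def normalize_counts(ds: AllelicDataset, size_factors: np.ndarray) -> AllelicDataset:
    """Scale both matrices by per-cell size factors, keeping integer counts.

    Totals are divided and rounded half-to-even; reference counts are
    rounded the same way then clipped to the rounded totals so the
    beta-binomial support constraint survives rounding.  The input
    dataset is not modified.
    """
    sf = np.asarray(size_factors, dtype=float)
    if sf.shape != (ds.n_cells,):
        raise FormatError("size_factors must have one entry per cell")
    if np.any(sf <= 0) or not np.all(np.isfinite(sf)):
        raise ValidationError("size_factors must be strictly positive")
    total = np.rint(ds.total / sf).astype(np.int64)
    ref = np.minimum(np.rint(ds.ref / sf).astype(np.int64), total)
    return AllelicDataset(
        ref, total, ds.gene_ids, ds.cell_ids,
        groups=ds.groups, size_factors=None, gene_annotations=ds.gene_annotations,
    )


# ---------------------------------------------------------------------------
# serialization


def _read_ids(path, what: str) -> pd.Index:
    try:
        ids = pd.read_csv(path, header=None, sep="\t")[0]
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty {what} list in {path}") from None
    return pd.Index(ids)


def read_allelic_dataset(
    ref_path,
    total_path,
    genes_path=None,
    cells_path=None,
    fmt: str = "mtx",
    groups_path=None,
    size_factors_path=None,
) -> AllelicDataset:
    """Read a dataset from MatrixMarket (+ gene/cell TSV sidecars) or CSV.

    ``fmt='mtx'``: each matrix is an integer MatrixMarket file with
    1-based coordinates, genes as rows; sidecars are single-column
    headerless TSVs.  ``fmt='csv'``: dense CSV, gene ids in the first
    column, cell ids as header (sidecar paths are ignored).
    """
    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("mtx format requires genes_path and cells_path")
        genes = _read_ids(genes_path, "gene")
        cells = _read_ids(cells_path, "cell")
        try:
            ref = spio.mmread(str(ref_path))
            total = spio.mmread(str(total_path))
        except Exception as exc:  # malformed MTX
            raise FormatError(f"could not parse MatrixMarket input: {exc}") from exc
        if ref.shape != (len(genes), len(cells)) or total.shape != ref.shape:
            raise FormatError(
                f"matrix dimensions {ref.shape}/{total.shape} do not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    elif fmt == "csv":
        ref_df = pd.read_csv(ref_path, index_col=0)
        total_df = pd.read_csv(total_path, index_col=0)
        if ref_df.empty or total_df.empty:
            raise FormatError("empty CSV matrix")
        if not ref_df.index.equals(total_df.index) or not ref_df.columns.equals(
            total_df.columns
        ):
            raise FormatError("ref and total CSVs have different gene/cell labels")
        genes, cells = ref_df.index, ref_df.columns
        ref, total = ref_df.to_numpy(), total_df.to_numpy()
    else:
        raise FormatError(f"unknown format {fmt!r}")

    groups = sf = None
    if groups_path is not None:
        tab = pd.read_csv(groups_path, sep="\t", header=None, names=["cell", "group"])
        groups = pd.Categorical(tab.set_index("cell")["group"].reindex(cells))
    if size_factors_path is not None:
        tab = pd.read_csv(size_factors_path, sep="\t", header=None, names=["cell", "sf"])
        sf = tab.set_index("cell")["sf"].reindex(cells).to_numpy()
    return AllelicDataset(ref, total, genes, cells, groups=groups, size_factors=sf)


def write_allelic_dataset(ds: AllelicDataset, outdir, fmt: str = "mtx", prefix: str = "") -> None:
    """Serialize in the same dialects ``read_allelic_dataset`` accepts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        spio.mmwrite(
            str(outdir / f"{prefix}ref.mtx"), sparse.coo_matrix(ds.ref), field="integer"
        )
        spio.mmwrite(
            str(outdir / f"{prefix}total.mtx"), sparse.coo_matrix(ds.total), field="integer"
        )
        pd.Series(ds.gene_ids).to_csv(
            outdir / f"{prefix}genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(ds.cell_ids).to_csv(
            outdir / f"{prefix}cells.tsv", sep="\t", index=False, header=False
        )
    elif fmt == "csv":
        pd.DataFrame(ds.ref, index=ds.gene_ids, columns=ds.cell_ids).to_csv(
            outdir / f"{prefix}ref.csv"
        )
        pd.DataFrame(ds.total, index=ds.gene_ids, columns=ds.cell_ids).to_csv(
            outdir / f"{prefix}total.csv"
        )
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if ds.groups is not None:
        pd.DataFrame({"cell": ds.cell_ids, "group": np.asarray(ds.groups.astype(str))}).to_csv(
            outdir / f"{prefix}groups.tsv", sep="\t", index=False, header=False
        )
    if ds.size_factors is not None:
        pd.DataFrame({"cell": ds.cell_ids, "sf": ds.size_factors}).to_csv(
            outdir / f"{prefix}size_factors.tsv", sep="\t", index=False, header=False
        )
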