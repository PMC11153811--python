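"""Single-cell RNA-seq preprocessing: cell QC, gene filtering, size-factor
normalization, TPM computation and highly-variable-gene selection.

QC follows the common outlier convention: a cell is removed when its
log2 total counts or log2 detected genes fall more than 3 scaled median
absolute deviations below the median.  Size factors use a pooling
deconvolution scheme (cells ordered on a ring by library size, pools of
21/26/31 cells solved against the average pseudo-cell by least squares),
which is robust to composition biases that plain library-size scaling
inherits.  TPM normalizes counts by gene length (kb) and rescales each
cell to one million.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix

__all__ = [
    "QCReport",
    "NormalizedMatrix",
    "TPMMatrix",
    "cell_qc_filter",
    "gene_filter",
    "compute_size_factors",
    "normalize",
    "compute_tpm",
    "select_hvgs",
]


@dataclass
class QCReport:
    metrics: pd.DataFrame  # per-cell log2 totals / log2 detected + removal flag
    removed: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1), genes x cells."""

    values: np.ndarray
    size_factors: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")


@dataclass
class TPMMatrix:
    """Transcripts per million, genes x cells; each column sums to 1e6."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _mad(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def cell_qc_filter(cm: CountMatrix, n_mads: float = 3.0) -> tuple[CountMatrix, QCReport]:
    """Remove cells > 3 MADs below the median in log2 counts or log2 genes.

    Single pass on log2-transformed metrics with the 1.4826 consistency
    constant.  Raises if every cell would be removed.
    """
    if cm.n_cells < 4:
        raise ValueError("cell QC needs at least 4 cells")
    totals = cm.counts.sum(axis=0).astype(float)
    detected = (cm.counts > 0).sum(axis=0).astype(float)
    log_tot = np.log2(totals + 1)
    log_det = np.log2(detected + 1)
    cut_tot = np.median(log_tot) - n_mads * _mad(log_tot)
    cut_det = np.median(log_det) - n_mads * _mad(log_det)
    keep = (log_tot >= cut_tot) & (log_det >= cut_det)
    if not keep.any():
        raise ValueError(
            f"cell QC removed all cells (cutoffs log2 counts {cut_tot:.2f}, "
            f"log2 genes {cut_det:.2f})"
        )
    report = QCReport(
        metrics=pd.DataFrame(
            {
                "cell_id": cm.cell_ids,
                "total_counts": totals,
                "detected_genes": detected,
                "log2_total": log_tot,
                "log2_detected": log_det,
                "removed": ~keep,
            }
        ),
        removed=list(cm.cell_ids[~keep]),
        thresholds={"log2_total": cut_tot, "log2_detected": cut_det, "n_mads": n_mads},
    )
    return cm.subset_cells(keep), report


def gene_filter(
    cm: CountMatrix, min_fraction: float = 0.05, mode: str = "detected"
) -> CountMatrix:
    """Keep genes detected (>= 1 count) in at least ``min_fraction`` of cells.

    ``mode="mean"`` implements the alternative reading of the rule: an
    average of >= 1 count over ``ceil(min_fraction * n)`` cells, i.e.
    total count >= ceil(0.05 * n).
    """
    n = cm.n_cells
    need = int(np.ceil(min_fraction * n))
    if mode == "detected":
        keep = (cm.counts >= 1).sum(axis=1) >= need
    elif mode == "mean":
        keep = cm.counts.sum(axis=1) >= need
    else:
        raise ValueError(f"unknown gene filter mode {mode!r}")
    if not keep.any():
        raise ValueError("gene filter removed all genes")
    return cm.subset_genes(keep)


def compute_size_factors(
    cm: CountMatrix,
    method: str = "deconvolution",
    pool_sizes: tuple[int, ...] = (21, 26, 31),
) -> np.ndarray:
    """Per-cell size factors, rescaled to geometric mean 1.

    ``deconvolution`` pools cells on a ring ordered by library size; each
    pool's summed profile is compared to the average pseudo-cell (median
    ratio over expressed genes), and per-cell factors are solved from the
    pool-membership system by least squares.  Falls back to library-size
    factors below 20 cells, and per-cell for non-positive solutions.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero counts cannot be normalized")
    libsize = totals / np.exp(np.mean(np.log(totals)))
    if method == "libsize":
        return libsize
    if method != "deconvolution":
        raise ValueError(f"unknown size factor method {method!r}")
    n = cm.n_cells
    if n < 20:
        warnings.warn("fewer than 20 cells: falling back to library-size factors")
        return libsize

    order = np.argsort(totals)
    counts = cm.counts[:, order].astype(float)
    ref = counts.mean(axis=1)
    expressed = ref > 0
    ref_e = ref[expressed]

    rows, cols, data, rhs = [], [], [], []
    r = 0
    for size in pool_sizes:
        size = min(size, n)
        for start in range(n):
            members = (start + np.arange(size)) % n
            pooled = counts[np.ix_(expressed, members)].sum(axis=1)
            theta = np.median(pooled / ref_e)
            for m in members:
                rows.append(r)
                cols.append(m)
                data.append(1.0)
            rhs.append(theta)
            r += 1
    # low-weight anchor rows tie the solution scale to library size
    for i in range(n):
        rows.append(r)
        cols.append(i)
        data.append(0.01)
        rhs.append(0.01 * libsize[order][i])
        r += 1
    a = np.zeros((r, n))
    a[rows, cols] = data
    sol, *_ = np.linalg.lstsq(a, np.asarray(rhs), rcond=None)

    factors = np.empty(n)
    factors[order] = sol
    bad = factors <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} non-positive deconvolution factors; using libsize")
        factors[bad] = libsize[bad] * np.exp(np.mean(np.log(factors[~bad])))
    return factors / np.exp(np.mean(np.log(factors)))


def normalize(cm: CountMatrix, size_factors: np.ndarray) -> NormalizedMatrix:
    """log2(count / size_factor + 1) per gene and cell."""
    sf = np.asarray(size_factors, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    values = np.log2(cm.counts / sf[None, :] + 1.0)
    return NormalizedMatrix(
        values=values, size_factors=sf, gene_ids=cm.gene_ids, cell_ids=cm.cell_ids
    )


def compute_tpm(cm: CountMatrix) -> TPMMatrix:
    """Length-normalized transcripts per million; columns sum to 1e6."""
    rate = cm.counts / (cm.gene_lengths[:, None] / 1000.0)
    colsum = rate.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("cells with zero counts cannot be TPM-normalized")
    return TPMMatrix(
        values=rate / colsum[None, :] * 1e6, gene_ids=cm.gene_ids, cell_ids=cm.cell_ids
    )


def select_hvgs(nm: NormalizedMatrix, n: int = 1000, window: int = 51) -> np.ndarray:
    """Top-n highly variable genes by variance above a mean-variance trend.

    The trend is a rolling median of per-gene variance against mean
    (genes ordered by mean); genes are ranked by the residual.
    Returns the selected gene ids.
    """
    if n > nm.values.shape[0]:
        raise ValueError("cannot select more HVGs than genes")
    means = nm.values.mean(axis=1)
    variances = nm.values.var(axis=1)
    order = np.argsort(means)
    trend_sorted = (
        pd.Series(variances[order]).rolling(window, center=True, min_periods=1).median()
    )
    trend = np.empty_like(variances)
    trend[order] = trend_sorted.to_numpy()
    resid = variances - trend
    top = np.argsort(resid)[::-1][:n]
    return nm.gene_ids[np.sort(top)]
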