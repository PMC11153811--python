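"""Per-gene differential expression between the two clusters.

A gene is a DEG when the normalized counts show a >= 2-fold difference
(|log2FC| >= 1) at FDR <= 0.05 (Welch t-test, Benjamini-Hochberg).  DEGs
are ranked by AUROC distance from 0.5 within each direction.  Two
TPM-gated refinements follow: "Super DEGs" (DEG, >= 10 TPM in at least one
cluster, >= 4-fold) and "Cluster similarity" (not a DEG, >= 10 TPM in at
least one cluster, <= 2-fold), the latter ranked by the overlapping index
(OI), the integral of the pointwise minimum of the two per-cluster kernel
density estimates (0 = disjoint, 1 = identical).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_test_all",
    "bh_adjust",
    "auroc_all",
    "de_table",
    "call_degs",
    "call_super_degs",
    "call_cluster_similar",
    "overlapping_index",
    "rank_similarity",
    "expression_intersection",
]

VAR_FLOOR = 1e-8


def welch_test_all(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch two-sample t-test per gene on normalized log2 values.

    ``labels`` holds cluster ids 1/2; log2FC is cluster1 - cluster2 mean.
    A variance floor prevents zero-division for constant genes; genes with
    equal means and zero variance get p = 1.
    """
    g1 = values[:, labels == 1]
    g2 = values[:, labels == 2]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 3 or n2 < 3:
        raise ValueError("both clusters need at least 3 cells")
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = np.maximum(g1.var(axis=1, ddof=1), VAR_FLOOR)
    v2 = np.maximum(g2.var(axis=1, ddof=1), VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(m1, m2)] = 1.0
    return t, p, m1 - m2


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auroc_all(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-based AUROC per gene for 'expression predicts cluster 1'.

    Mann-Whitney U / (n1 * n2) with ties counted at half weight.
    """
    in1 = labels == 1
    n1, n2 = int(in1.sum()), int((~in1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both clusters must be non-empty")
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, in1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def de_table(
    norm_values: np.ndarray,
    tpm_values: np.ndarray,
    labels: np.ndarray,
    gene_ids: np.ndarray,
    expressing_tpm: float = 1.0,
) -> pd.DataFrame:
    """Full per-gene contrast table (volcano-ready) with all flags set."""
    t, p, lfc = welch_test_all(norm_values, labels)
    fdr = bh_adjust(p)
    auroc = auroc_all(norm_values, labels)
    in1, in2 = labels == 1, labels == 2
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_log_c1": norm_values[:, in1].mean(axis=1),
            "mean_log_c2": norm_values[:, in2].mean(axis=1),
            "log2fc": lfc,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "auroc": auroc,
            "mean_tpm_c1": tpm_values[:, in1].mean(axis=1),
            "mean_tpm_c2": tpm_values[:, in2].mean(axis=1),
            "pct_c1": 100.0 * (tpm_values[:, in1] >= expressing_tpm).mean(axis=1),
            "pct_c2": 100.0 * (tpm_values[:, in2] >= expressing_tpm).mean(axis=1),
        }
    )
    df = call_degs(df)
    df = call_super_degs(df)
    df = call_cluster_similar(df)
    return df


def call_degs(
    df: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Flag DEGs (|log2FC| >= 1 and FDR <= 0.05, boundaries inclusive) and
    rank them by AUROC distance from 0.5, descending, within direction."""
    df = df.copy()
    df["is_deg"] = (df["log2fc"].abs() >= lfc_min) & (df["fdr"] <= fdr_max)
    df["deg_direction"] = np.where(
        ~df["is_deg"], "", np.where(df["log2fc"] > 0, "up_c1", "up_c2")
    )
    df["deg_rank"] = np.nan
    for direction in ("up_c1", "up_c2"):
        sub = df[df["deg_direction"] == direction]
        order = (sub["auroc"] - 0.5).abs().sort_values(ascending=False)
        df.loc[order.index, "deg_rank"] = np.arange(1, len(order) + 1)
    return df


def call_super_degs(
    df: pd.DataFrame, tpm_min: float = 10.0, lfc_min: float = 2.0
) -> pd.DataFrame:
    """Super DEGs: DEG and >= 10 TPM in >= 1 cluster and >= 4-fold."""
    df = df.copy()
    max_tpm = df[["mean_tpm_c1", "mean_tpm_c2"]].max(axis=1)
    df["is_super_deg"] = df["is_deg"] & (max_tpm >= tpm_min) & (df["log2fc"].abs() >= lfc_min)
    return df


def call_cluster_similar(
    df: pd.DataFrame, tpm_min: float = 10.0, lfc_max: float = 1.0
) -> pd.DataFrame:
    """Cluster similarity: not a DEG, >= 10 TPM in >= 1 cluster, <= 2-fold."""
    df = df.copy()
    max_tpm = df[["mean_tpm_c1", "mean_tpm_c2"]].max(axis=1)
    df["is_cluster_similar"] = (
        ~df["is_deg"] & (max_tpm >= tpm_min) & (df["log2fc"].abs() <= lfc_max)
    )
    return df


def overlapping_index(
    sample_a: np.ndarray, sample_b: np.ndarray, n_grid: int = 1024
) -> float:
    """Overlap of two distributions via Gaussian KDE (Silverman bandwidth).

    Both densities are evaluated on a shared uniform grid spanning the
    pooled range +/- 3x the larger bandwidth, renormalized to integrate to
    one on the grid, and OI = sum(min(fa, fb)) * dx.  Samples with fewer
    than two distinct values are treated as point masses and compared by
    equality of their discrete distributions.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    degen_a = np.unique(a).size < 2
    degen_b = np.unique(b).size < 2
    if degen_a or degen_b:
        return _discrete_overlap(a, b)
    kde_a = stats.gaussian_kde(a, bw_method="silverman")
    kde_b = stats.gaussian_kde(b, bw_method="silverman")
    bw = max(kde_a.factor * a.std(ddof=1), kde_b.factor * b.std(ddof=1))
    lo = min(a.min(), b.min()) - 3.0 * bw
    hi = max(a.max(), b.max()) + 3.0 * bw
    grid = np.linspace(lo, hi, n_grid)
    dx = grid[1] - grid[0]
    fa = kde_a(grid)
    fb = kde_b(grid)
    fa /= fa.sum() * dx
    fb /= fb.sum() * dx
    return float(np.minimum(fa, fb).sum() * dx)


def _discrete_overlap(a: np.ndarray, b: np.ndarray) -> float:
    values = np.union1d(np.unique(a), np.unique(b))
    pa = np.array([(a == v).mean() for v in values])
    pb = np.array([(b == v).mean() for v in values])
    return float(np.minimum(pa, pb).sum())


def rank_similarity(
    df: pd.DataFrame,
    tpm_values: np.ndarray,
    labels: np.ndarray,
    gene_ids: np.ndarray,
    oi_threshold: float = 0.8,
) -> pd.DataFrame:
    """OI-ranked table of cluster-similar genes (balloon-plot data).

    OI is computed per gene on the per-cell TPM distributions of the two
    clusters (zeros included); the high-stringency subset has OI >= 0.8.
    Per-cluster mean TPM and coefficient of variation are attached.
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    in1, in2 = labels == 1, labels == 2
    rows = []
    for _, rec in df[df["is_cluster_similar"]].iterrows():
        i = idx[rec["gene_id"]]
        x1, x2 = tpm_values[i, in1], tpm_values[i, in2]
        oi = overlapping_index(x1, x2)
        rows.append(
            {
                "gene_id": rec["gene_id"],
                "oi": oi,
                "mean_tpm_c1": x1.mean(),
                "mean_tpm_c2": x2.mean(),
                "cv_c1": x1.std(ddof=1) / x1.mean() if x1.mean() > 0 else np.nan,
                "cv_c2": x2.std(ddof=1) / x2.mean() if x2.mean() > 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "oi", "mean_tpm_c1", "mean_tpm_c2",
                                      "cv_c1", "cv_c2"])
    out = out.sort_values(["oi", "gene_id"], ascending=[False, True], ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["high_stringency"] = out["oi"] >= oi_threshold
    return out


def expression_intersection(
    mean_tpm_c1: np.ndarray,
    mean_tpm_c2: np.ndarray,
    gene_ids: np.ndarray,
    threshold: float = 1000.0,
) -> dict[str, list]:
    """Genes >= threshold TPM in both clusters vs in exactly one (Venn sets)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hi1 = np.asarray(mean_tpm_c1) >= threshold
    hi2 = np.asarray(mean_tpm_c2) >= threshold
    gene_ids = np.asarray(gene_ids)
    return {
        "intersection": list(gene_ids[hi1 & hi2]),
        "exclusive_c1": list(gene_ids[hi1 & ~hi2]),
        "exclusive_c2": list(gene_ids[~hi1 & hi2]),
    }
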