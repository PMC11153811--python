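"""Multimodal analysis: PCA on electrophysiological features, cohort
statistics with a normality-gated test ladder, and transcriptomic vs
electrophysiological congruence.

The test ladder mirrors standard practice for patch-clamp cohort
comparisons: a Kolmogorov-Smirnov normality check per cohort, then a
two-sample t-test when both cohorts look normal and a Mann-Whitney U test
otherwise, with Sidak correction over the three pairwise cohort
comparisons per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import cluster_agreement
from .ephys import FEATURES_16

__all__ = [
    "FeatureMatrix",
    "ephys_pca",
    "cohort_stats",
    "congruence",
    "overlay_embedding",
]


@dataclass
class FeatureMatrix:
    """Cells x features with raw and z-scored copies and a missing mask."""

    raw: pd.DataFrame
    zscored: pd.DataFrame
    missing: pd.DataFrame

    @classmethod
    def from_features(cls, df: pd.DataFrame, features: list[str] | None = None
                      ) -> "FeatureMatrix":
        features = features or FEATURES_16
        raw = df[features].astype(float)
        missing = raw.isna()
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        z = (raw - mu) / sd.replace(0.0, np.nan)
        return cls(raw=raw, zscored=z, missing=missing)


def ephys_pca(
    fm: FeatureMatrix, n_components: int = 5, seed: int = 0
) -> dict:
    """PCA of the z-scored feature matrix.

    Missing entries are mean-imputed (z = 0) for the embedding only, with a
    logged count; constant features are dropped with a warning.  Component
    signs are fixed so the largest-|loading| entry of each PC is positive.
    Returns scores, explained variance ratios, PC1 loading scores ordered
    by magnitude, and the feature-PC correlation map (vector factor map).
    """
    from sklearn.decomposition import PCA

    z = fm.zscored.copy()
    constant = z.columns[z.isna().all(axis=0)]
    if len(constant):
        warnings.warn(f"dropping constant features: {list(constant)}")
        z = z.drop(columns=constant)
    n_imputed = int(z.isna().to_numpy().sum())
    if n_imputed:
        warnings.warn(f"mean-imputing {n_imputed} missing feature values for PCA")
        z = z.fillna(0.0)
    n_comp = min(n_components, z.shape[1], z.shape[0])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_  # components x features
    for i in range(n_comp):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    pc1 = pd.Series(loadings[0], index=z.columns, name="pc1_loading")
    pc1 = pc1.reindex(pc1.abs().sort_values(ascending=False).index)
    corr = pd.DataFrame(
        {
            f"PC{i + 1}": [
                float(np.corrcoef(z[f], scores[:, i])[0, 1]) for f in z.columns
            ]
            for i in range(min(2, n_comp))
        },
        index=z.columns,
    )
    return {
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "pc1_loadings": pc1,
        "feature_pc_correlation": corr,
        "features": list(z.columns),
        "n_imputed": n_imputed,
    }


def cohort_stats(
    fm: FeatureMatrix,
    cohorts: pd.Series,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pairwise cohort comparison per feature with the normality-gated ladder.

    Normality per cohort via the one-sample KS test against a fitted
    normal (alpha = 0.05); t-test when both cohorts pass, otherwise
    Mann-Whitney U.  Sidak correction over the pairwise family (default:
    the number of cohort pairs, 3 for three cohorts).
    """
    cohorts = pd.Series(cohorts).astype(str)
    levels = sorted(cohorts.unique())
    pairs = list(combinations(levels, 2))
    m = family_size or max(len(pairs), 1)
    rows = []
    for feat in fm.raw.columns:
        for a, b in pairs:
            xa = fm.raw.loc[(cohorts == a).to_numpy(), feat].dropna().to_numpy()
            xb = fm.raw.loc[(cohorts == b).to_numpy(), feat].dropna().to_numpy()
            if len(xa) < 3 or len(xb) < 3:
                continue
            normal = all(_ks_normal(x, alpha) for x in (xa, xb))
            if normal:
                test, (_, p) = "t", stats.ttest_ind(xa, xb, equal_var=False)
            else:
                test, (_, p) = "mannwhitney", stats.mannwhitneyu(
                    xa, xb, alternative="two-sided"
                )
            p = float(p)
            p_corr = float(1.0 - (1.0 - p) ** m)
            rows.append(
                {
                    "feature": feat, "cohort_a": a, "cohort_b": b,
                    "test": test, "p_raw": p, "p_sidak": p_corr,
                    "significant": p_corr <= alpha,
                    "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
                }
            )
    return pd.DataFrame(rows)


def _ks_normal(x: np.ndarray, alpha: float) -> bool:
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return p > alpha


def congruence(
    cluster_labels: np.ndarray, firing_classes: np.ndarray
) -> tuple[float, float, pd.DataFrame]:
    """Fraction of cells whose firing class matches their cluster.

    The class-to-cluster mapping ({Onset, Sustained} -> one cluster,
    {Delayed} -> the other) is chosen to maximize matches, so the measure
    is invariant to cluster relabeling.  Returns (fraction congruent,
    adjusted agreement index, contingency table).
    """
    cl = np.asarray(cluster_labels)
    fc = np.asarray(firing_classes)
    if cl.shape != fc.shape:
        raise ValueError("label sets must cover the same cells")
    mapped = np.where(np.isin(fc, ["Onset", "Sustained"]), 1, 2)
    frac = max(np.mean(mapped == cl), np.mean((3 - mapped) == cl))
    _, ari, _ = cluster_agreement(mapped, cl)
    table = pd.crosstab(pd.Series(fc, name="firing_class"),
                        pd.Series(cl, name="cluster"))
    return float(frac), float(ari), table


def overlay_embedding(
    embedding: pd.DataFrame, firing_classes: pd.Series
) -> pd.DataFrame:
    """Join 2-D embedding coordinates with firing classes for plotting."""
    missing = [c for c in embedding.index if c not in firing_classes.index]
    if missing:
        raise KeyError(f"cells without firing class: {missing[:5]}")
    out = embedding.copy()
    out["firing_class"] = firing_classes.reindex(embedding.index)
    return out
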