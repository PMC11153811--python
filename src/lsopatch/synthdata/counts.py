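"""Negative-binomial count simulation with planted marker genes.

Cells belong to three electrophysiological classes (Onset, Sustained,
Delayed); transcriptomically, Onset + Sustained form cluster 1 and Delayed
forms cluster 2.  Cluster-1 markers (default 250) and cluster-2 markers
(default 100) are up-regulated by log2FC = 1 + |N(0.5, 0.5)|.  A block of
housekeeping genes is highly expressed in every cell; the 7 transmitter
genes follow per-class Bernoulli gates; negative controls are sampled at a
fraction (default 1/8) of the neuronal depth and carry no class signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import CountMatrix, GroundTruth
from .config import TRANSMITTER_GENES, GeneratorConfig
from .traces import realize_cell_ephys

__all__ = ["generate_counts", "gene_table"]

CLASS_TO_CLUSTER = {"Onset": 1, "Sustained": 1, "Delayed": 2, "NegControl": 0}


def _default_rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def gene_table(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene truth: block membership, baseline mean, log2FC.

    ``true_log2fc`` is on the cluster1-minus-cluster2 scale: positive for
    cluster-1 markers, negative for cluster-2 markers.
    """
    n_t = len(TRANSMITTER_GENES)
    n_hk, n_m1, n_m2 = config.n_housekeeping, config.n_markers_c1, config.n_markers_c2
    n_bg = config.n_genes - n_t - n_hk - n_m1 - n_m2
    if n_bg < 0:
        raise ValueError("n_markers_c1 + n_markers_c2 exceed available genes")

    gene_ids = (
        list(TRANSMITTER_GENES)
        + [f"hk_{i + 1:04d}" for i in range(n_hk)]
        + [f"m1_{i + 1:04d}" for i in range(n_m1)]
        + [f"m2_{i + 1:04d}" for i in range(n_m2)]
        + [f"bg_{i + 1:04d}" for i in range(n_bg)]
    )
    block = (
        ["transmitter"] * n_t
        + ["housekeeping"] * n_hk
        + ["marker_c1"] * n_m1
        + ["marker_c2"] * n_m2
        + ["background"] * n_bg
    )

    base = np.empty(config.n_genes)
    base[:n_t] = 0.0  # transmitter genes are fully gate-driven
    base[n_t:n_t + n_hk] = rng.lognormal(
        config.housekeeping_log_mean, config.housekeeping_log_sd, n_hk
    )
    base[n_t + n_hk:] = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, n_m1 + n_m2 + n_bg
    )

    lfc = np.zeros(config.n_genes)
    flag = np.array(["none"] * config.n_genes, dtype=object)
    draw = lambda n: config.marker_lfc_base + np.abs(  # noqa: E731
        rng.normal(config.marker_lfc_mean, config.marker_lfc_sd, n)
    )
    m1 = slice(n_t + n_hk, n_t + n_hk + n_m1)
    m2 = slice(n_t + n_hk + n_m1, n_t + n_hk + n_m1 + n_m2)
    lfc[m1] = draw(n_m1)
    lfc[m2] = -draw(n_m2)
    flag[m1] = "up_c1"
    flag[m2] = "up_c2"

    # transmitter genes: expected log2FC implied by gates x magnitude,
    # mixing Onset/Sustained into cluster 1 by cohort size
    n1 = config.n_onset + config.n_sustained
    for i, g in enumerate(TRANSMITTER_GENES):
        probs = config.transmitter_probs[g]
        mag = config.transmitter_magnitudes[g]
        e1 = (config.n_onset * probs["Onset"] + config.n_sustained * probs["Sustained"])
        e1 = (e1 / n1 if n1 else 0.0) * mag
        e2 = probs["Delayed"] * mag
        t_lfc = np.log2((e1 + 0.5) / (e2 + 0.5))
        lfc[i] = t_lfc
        if t_lfc > 0:
            flag[i] = "up_c1"
        elif t_lfc < 0:
            flag[i] = "up_c2"

    lengths = rng.integers(
        config.gene_length_min_bp, config.gene_length_max_bp + 1, config.n_genes
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "block": block,
            "base_mean": base,
            "de_flag": flag,
            "true_log2fc": lfc,
            "length_bp": lengths,
        }
    )


def generate_counts(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the genes x cells count matrix and its ground truth.

    Counts are NB(mean = libsize_c * base_g * 2^(lfc_g on the matching
    cluster), dispersion) with independent Bernoulli dropout; negative
    controls use ``depth_scale`` x the neuronal library size and receive no
    marker up-regulation or transmitter gating.
    """
    if rng is None:
        rng = _default_rng(config, stream=0)

    genes = gene_table(config, rng)
    classes = config.cell_classes()
    clusters = np.array([CLASS_TO_CLUSTER[c] for c in classes])
    n_cells = config.n_cells
    cell_ids = np.array([f"cell_{i + 1:03d}" for i in range(n_cells)], dtype=object)

    libsize = rng.lognormal(0.0, config.libsize_log_sd, n_cells)
    libsize[clusters == 0] *= config.depth_scale

    base = genes["base_mean"].to_numpy()
    lfc = genes["true_log2fc"].to_numpy()
    is_t = (genes["block"] == "transmitter").to_numpy()

    # per-gene multiplier per cluster; baseline is the non-upregulated level
    mult = np.ones((config.n_genes, n_cells))
    up1 = (lfc > 0) & ~is_t
    up2 = (lfc < 0) & ~is_t
    mult[np.ix_(up1, clusters == 1)] = 2.0 ** lfc[up1][:, None]
    mult[np.ix_(up2, clusters == 2)] = 2.0 ** (-lfc[up2])[:, None]

    mean = base[:, None] * mult * libsize[None, :]

    # transmitter genes: Bernoulli gate x NB magnitude per class
    gates = np.zeros((len(TRANSMITTER_GENES), n_cells), dtype=bool)
    for i, g in enumerate(TRANSMITTER_GENES):
        probs = config.transmitter_probs[g]
        p = np.array([probs.get(c, 0.0) for c in classes])
        gates[i] = rng.random(n_cells) < p
        mean[i] = gates[i] * config.transmitter_magnitudes[g] * libsize

    counts = _sample_nb(mean, config.dispersion, rng)
    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0

    cm = CountMatrix(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(),
        gene_lengths=genes["length_bp"].to_numpy(),
        cell_ids=cell_ids,
    )

    cells = realize_cell_ephys(config, rng)
    cells.insert(0, "cell_id", cell_ids)
    cells["libsize_factor"] = libsize
    truth = GroundTruth(
        cells=cells,
        genes=genes.rename(columns={"length_bp": "length_bp"})[
            ["gene_id", "block", "base_mean", "de_flag", "true_log2fc", "length_bp"]
        ],
    )
    return cm, truth


def _sample_nb(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2; Poisson in the limit disp -> 0."""
    if dispersion < 1e-8:
        return rng.poisson(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)
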