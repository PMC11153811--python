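"""End-to-end orchestration of the patch-seq analysis on synthetic or
user-supplied data.

``run_all`` executes: simulate -> ephys feature extraction -> cell/gene QC
and normalization -> consensus clustering (k selected by silhouette) ->
differential expression with Super-DEG / similarity calls -> transmitter
panel combinations -> multimodal PCA and congruence, and returns a result
bundle with a manifest (seeds, parameter hash, versions) and a summary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__, clustering, diffexpr, multimodal, panels, preprocess
from .ephys import extract_feature_vector, features_to_frame
from .io import config_hash
from .synthdata import GeneratorConfig, generate_counts, iter_tracesets

log = logging.getLogger("lsopatch")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Single source of all pipeline parameters."""

    seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    include_psc: bool = True
    sf_method: str = "deconvolution"
    n_hvgs: int = 1000
    k_min: int = 2
    k_max: int = 10
    expressing_tpm: float = 1.0
    run_graph_cluster: bool = True
    run_tsne: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str, t0: float, **info) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline on generated data; returns the result bundle."""
    bundle: dict = {"config": config.to_dict()}
    gen_cfg = GeneratorConfig(seed=config.seed, **config.generator)

    t0 = time.time()
    cm, truth = generate_counts(gen_cfg)
    bundle["counts"] = cm
    bundle["truth"] = truth
    _stage("simulate", t0, genes=cm.n_genes, cells=cm.n_cells)

    t0 = time.time()
    feats = []
    for cid, ts in iter_tracesets(gen_cfg, truth, include_psc=config.include_psc):
        feats.append(extract_feature_vector(ts))
    features = features_to_frame(feats)
    bundle["features"] = features
    _stage("ephys-features", t0, cells=len(features))

    t0 = time.time()
    cm_qc, qc_report = preprocess.cell_qc_filter(cm)
    cm_f = preprocess.gene_filter(cm_qc)
    sf = preprocess.compute_size_factors(cm_f, method=config.sf_method)
    nm = preprocess.normalize(cm_f, sf)
    tpm = preprocess.compute_tpm(cm_f)
    hvgs = preprocess.select_hvgs(nm, n=min(config.n_hvgs, cm_f.n_genes))
    bundle.update(qc_report=qc_report, counts_filtered=cm_f, normalized=nm,
                  tpm=tpm, hvgs=hvgs)
    _stage("preprocess", t0, removed=len(qc_report.removed), genes=cm_f.n_genes)

    t0 = time.time()
    hvg_mask = np.isin(nm.gene_ids, hvgs)
    x = nm.values[hvg_mask].T  # cells x HVGs
    result = clustering.consensus_cluster(
        x, k_range=range(config.k_min, config.k_max + 1), seed=config.seed
    )
    labels = _canonical_labels(result.labels)
    bundle["clustering"] = result
    bundle["labels"] = labels
    if config.run_graph_cluster:
        graph_labels = clustering.graph_cluster(x, seed=config.seed)
        _, graph_ari, graph_overlap = clustering.cluster_agreement(labels, graph_labels)
        bundle.update(graph_labels=graph_labels, graph_agreement=graph_ari,
                      graph_overlap=graph_overlap)
    scores, loadings, evr = clustering.pca_embed(x, seed=config.seed)
    bundle["expression_pca"] = {"scores": scores, "explained_variance_ratio": evr}
    if config.run_tsne:
        bundle["tsne"] = clustering.tsne_embed(scores[:, :10], seed=config.seed)
    _stage("cluster", t0, k=result.k_selected,
           silhouette=round(result.silhouette_by_k[result.k_selected], 3))

    t0 = time.time()
    de = diffexpr.de_table(nm.values, tpm.values, labels, nm.gene_ids,
                           expressing_tpm=config.expressing_tpm)
    similarity = diffexpr.rank_similarity(de, tpm.values, labels, nm.gene_ids)
    bundle.update(de=de, similarity=similarity)
    _stage("de", t0, degs=int(de["is_deg"].sum()),
           super_degs=int(de["is_super_deg"].sum()))

    t0 = time.time()
    label_df = _label_frame(cm_f.cell_ids, labels, features)
    nt7 = panels.load_panel("nt7")
    bundle["transmitter"] = panels.transmitter_combinations(
        tpm, label_df, nt7, threshold=config.expressing_tpm
    )
    bundle["top_expressed"] = panels.top_expressed(tpm, n=min(50, cm_f.n_genes),
                                                   labels=label_df)
    _stage("panels", t0)

    t0 = time.time()
    fm = multimodal.FeatureMatrix.from_features(features.loc[cm_f.cell_ids])
    bundle["ephys_pca"] = multimodal.ephys_pca(fm, seed=config.seed)
    firing = features.loc[cm_f.cell_ids, "firing_class"].to_numpy()
    frac, ari, table = multimodal.congruence(labels, firing)
    bundle["congruence"] = {"fraction": frac, "ari": ari, "table": table}
    _stage("multimodal", t0, congruence=round(frac, 3))

    bundle["manifest"] = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "parameter_hash": config_hash(config.to_dict()),
    }
    bundle["summary"] = {
        "n_cells_retained": cm_f.n_cells,
        "n_genes_retained": cm_f.n_genes,
        "k_selected": result.k_selected,
        "silhouette_by_k": result.silhouette_by_k,
        "cluster_sizes": dict(zip(*map(list, np.unique(labels, return_counts=True)))),
        "n_degs": int(de["is_deg"].sum()),
        "n_super_degs": int(de["is_super_deg"].sum()),
        "n_cluster_similar": int(de["is_cluster_similar"].sum()),
        "congruence": frac,
    }
    return bundle


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel so cluster 1 is the larger cluster (ties: original order)."""
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    order = values[np.argsort(-counts, kind="stable")]
    mapping = {old: i + 1 for i, old in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def _label_frame(cell_ids: np.ndarray, clusters: np.ndarray,
                 features: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cluster": clusters,
            "firing_class": features.loc[cell_ids, "firing_class"].to_numpy(),
        }
    )
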