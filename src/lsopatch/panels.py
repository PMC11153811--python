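"""Gene-panel summaries and the multi-transmitter combination analysis.

Panels are editable TSV resources keyed by mouse gene symbol (Kv, Nav, Cav,
TRP, HCN, ligand-gated channels, GPCRs, and the 7-gene neurotransmitter
panel).  "Expressing" defaults to TPM >= 1 and is user-adjustable.
Cohorts: the three firing classes, the two transcriptomic clusters, and
all neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd

from .preprocess import TPMMatrix

__all__ = [
    "GenePanel",
    "CombinationTable",
    "load_panel",
    "available_panels",
    "panel_summary",
    "genes_per_cell",
    "transmitter_combinations",
    "top_expressed",
]

BUILTIN_PANELS = ("kv", "nav", "cav", "trp", "hcn", "lgic", "gpcr", "nt7")


@dataclass
class GenePanel:
    name: str
    gene_ids: list[str]
    subgroups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"panel {self.name} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class CombinationTable:
    """Per-cluster combination counts for an UpSet-style analysis."""

    combinations: dict  # cohort -> {frozenset(genes): count}
    percentages: dict  # cohort -> {frozenset(genes): % of cohort}
    set_sizes: pd.DataFrame  # per-gene % expressing per cohort
    combo_sizes: dict  # cohort -> per-cell combination-size array


def available_panels() -> tuple[str, ...]:
    return BUILTIN_PANELS


def load_panel(name: str) -> GenePanel:
    """Load a built-in panel TSV (columns: gene_id, subgroup)."""
    if name not in BUILTIN_PANELS:
        raise ValueError(f"unknown panel {name!r}; choose from {BUILTIN_PANELS}")
    ref = importlib_resources.files("lsopatch") / "resources" / "panels" / f"{name}.tsv"
    df = pd.read_csv(str(ref), sep="\t")
    return GenePanel(
        name=name,
        gene_ids=list(df["gene_id"]),
        subgroups=dict(zip(df["gene_id"], df["subgroup"])),
    )


def _cohort_masks(labels: pd.DataFrame) -> dict[str, np.ndarray]:
    """Cohorts from a per-cell table with firing_class and cluster columns."""
    fc = labels["firing_class"].to_numpy()
    cl = labels["cluster"].to_numpy()
    return {
        "Onset": fc == "Onset",
        "Sustained": fc == "Sustained",
        "Delayed": fc == "Delayed",
        "cluster1": cl == 1,
        "cluster2": cl == 2,
        "all": np.ones(len(labels), dtype=bool),
    }


def _resolve_panel(tpm: TPMMatrix, panel: GenePanel) -> tuple[list[str], list[str]]:
    present = [g for g in panel.gene_ids if g in set(tpm.gene_ids)]
    missing = [g for g in panel.gene_ids if g not in set(tpm.gene_ids)]
    return present, missing


def panel_summary(
    tpm: TPMMatrix,
    labels: pd.DataFrame,
    panel: GenePanel,
    thresholds: tuple[float, ...] = (1.0, 10.0),
    cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cohort mean TPM and % of cells >= each threshold, per panel gene.

    Panel genes absent from the matrix are reported with NaN values, never
    silently dropped.
    """
    masks = _cohort_masks(labels)
    if cohorts is None:
        cohorts = list(masks)
    unknown = [c for c in cohorts if c not in masks]
    if unknown:
        raise ValueError(f"unknown cohorts {unknown}")
    present, missing = _resolve_panel(tpm, panel)
    idx = {g: i for i, g in enumerate(tpm.gene_ids)}
    rows = []
    for cohort in cohorts:
        m = masks[cohort]
        for g in panel.gene_ids:
            row = {"cohort": cohort, "gene_id": g, "missing": g in missing}
            if g in idx:
                x = tpm.values[idx[g], m]
                row["mean_tpm"] = float(x.mean()) if x.size else np.nan
                for thr in thresholds:
                    row[f"pct_ge{thr:g}"] = float(100.0 * (x >= thr).mean()) if x.size else np.nan
            else:
                row["mean_tpm"] = np.nan
                for thr in thresholds:
                    row[f"pct_ge{thr:g}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def genes_per_cell(
    tpm: TPMMatrix,
    labels: pd.DataFrame,
    panel: GenePanel,
    threshold: float = 1.0,
    cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cohort mean / range / histogram of expressed panel genes per cell.

    Reports both denominators: the panel size and the number of panel genes
    expressed anywhere in the sample.
    """
    masks = _cohort_masks(labels)
    if cohorts is None:
        cohorts = list(masks)
    present, _ = _resolve_panel(tpm, panel)
    idx = [int(np.nonzero(tpm.gene_ids == g)[0][0]) for g in present]
    expressed = tpm.values[idx] >= threshold if idx else np.zeros((0, len(labels)))
    per_cell = expressed.sum(axis=0)
    detected_in_sample = int(expressed.any(axis=1).sum())
    rows = []
    for cohort in cohorts:
        m = masks[cohort]
        x = per_cell[m]
        counts = np.bincount(x.astype(int), minlength=len(panel) + 1) if x.size else np.array([])
        rows.append(
            {
                "cohort": cohort,
                "mean": float(x.mean()) if x.size else np.nan,
                "min": int(x.min()) if x.size else -1,
                "max": int(x.max()) if x.size else -1,
                "histogram": counts.tolist(),
                "panel_size": len(panel),
                "panel_detected_in_sample": detected_in_sample,
            }
        )
    return pd.DataFrame(rows)


def transmitter_combinations(
    tpm: TPMMatrix,
    labels: pd.DataFrame,
    panel: GenePanel,
    threshold: float = 1.0,
    cohorts: tuple[str, ...] = ("cluster1", "cluster2", "all"),
) -> CombinationTable:
    """Enumerate per-cell expressed gene subsets of the transmitter panel.

    Cells expressing no panel gene count as the empty combination, so
    per-cohort percentages sum to 100.
    """
    masks = _cohort_masks(labels)
    present, _ = _resolve_panel(tpm, panel)
    idx = [int(np.nonzero(tpm.gene_ids == g)[0][0]) for g in present]
    expressed = tpm.values[idx] >= threshold if idx else np.zeros((0, len(labels)), dtype=bool)

    per_cell_sets = [
        frozenset(g for g, on in zip(present, expressed[:, c]) if on)
        for c in range(len(labels))
    ]
    combos: dict = {}
    pcts: dict = {}
    sizes: dict = {}
    set_rows = []
    for cohort in cohorts:
        m = masks[cohort]
        cells = [s for s, keep in zip(per_cell_sets, m) if keep]
        counts: dict = {}
        for s in cells:
            counts[s] = counts.get(s, 0) + 1
        n = len(cells)
        combos[cohort] = counts
        pcts[cohort] = {s: 100.0 * c / n for s, c in counts.items()} if n else {}
        sizes[cohort] = np.array([len(s) for s in cells])
        for g in present:
            pct = 100.0 * np.mean([g in s for s in cells]) if n else np.nan
            set_rows.append({"cohort": cohort, "gene_id": g, "pct_expressing": pct})
    return CombinationTable(
        combinations=combos,
        percentages=pcts,
        set_sizes=pd.DataFrame(set_rows),
        combo_sizes=sizes,
    )


def top_expressed(tpm: TPMMatrix, n: int = 50, labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Genes ranked by mean TPM over all cells; ties broken by gene id."""
    if n > len(tpm.gene_ids):
        raise ValueError("n exceeds gene count")
    mean_tpm = tpm.values.mean(axis=1)
    df = pd.DataFrame({"gene_id": tpm.gene_ids, "mean_tpm": mean_tpm})
    df = df.sort_values(["mean_tpm", "gene_id"], ascending=[False, True],
                        ignore_index=True).head(n)
    df["rank"] = np.arange(1, len(df) + 1)
    if labels is not None:
        masks = _cohort_masks(labels)
        idx = {g: i for i, g in enumerate(tpm.gene_ids)}
        for cohort, m in masks.items():
            if cohort == "all":
                continue
            df[f"mean_tpm_{cohort}"] = [
                float(tpm.values[idx[g], m].mean()) if m.any() else np.nan
                for g in df["gene_id"]
            ]
    return df
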