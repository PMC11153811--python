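"""Shared data containers for the patch-seq pipeline.

The transcriptomic branch is rooted in :class:`CountMatrix` (genes x cells
integer counts with gene lengths); the electrophysiological branch in
:class:`TraceSet` (stimulus-tagged time series per cell).  ``GroundTruth``
carries generator-side truth and is consumed only by tests and recovery
analyses, never by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "Trace",
    "TraceSet",
    "GroundTruth",
]


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` integer array.
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    gene_lengths
        Gene lengths in bp, used for TPM normalization.
    cell_ids
        Unique cell identifiers, length ``n_cells``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    gene_lengths: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_lengths = np.asarray(self.gene_lengths)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_lengths) != n_genes:
            raise ValueError("gene annotation length does not match count matrix")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell annotation length does not match count matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[mask], self.gene_ids[mask], self.gene_lengths[mask], self.cell_ids
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, mask], self.gene_ids, self.gene_lengths, self.cell_ids[mask]
        )


@dataclass
class Trace:
    """A single stimulus-tagged recording on a uniform time grid.

    ``signal`` is in mV for current-clamp protocols and pA for voltage-clamp
    protocols; ``params`` carries the stimulus description (step amplitude,
    onset/offset in seconds, holding potential, ...).
    """

    signal: np.ndarray
    sampling_rate: float  # Hz
    protocol: str
    units: str  # "mV" or "pA"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds (uniform grid starting at 0)."""
        return np.arange(self.signal.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.signal.size / self.sampling_rate


@dataclass
class TraceSet:
    """All recordings of one cell, keyed by protocol.

    Protocol keys used by the generator and the feature extractor:

    - ``rest`` — 30-s zero-current segment (mV)
    - ``step_<amp>`` — 200-ms current step of ``<amp>`` pA (mV)
    - ``triangular_<i>`` — brief triangular current pulse repeat i (mV)
    - ``vc_step`` — −5 mV voltage-clamp step, current response (pA)
    - ``psc`` — 60-s continuous current recording at V_hold (pA)
    """

    cell_id: str
    traces: dict[str, Trace] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Trace:
        return self.traces[key]

    def __contains__(self, key: str) -> bool:
        return key in self.traces

    def step_traces(self) -> list[Trace]:
        """Current-clamp step family ordered by step amplitude."""
        steps = [t for k, t in self.traces.items() if k.startswith("step_")]
        return sorted(steps, key=lambda t: t.params["amplitude_pa"])

    def triangular_traces(self) -> list[Trace]:
        keys = sorted(
            (k for k in self.traces if k.startswith("triangular_")),
            key=lambda k: int(k.rsplit("_", 1)[1]),
        )
        return [self.traces[k] for k in keys]


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests.

    ``cells`` has one row per cell: ``cell_id``, ``cell_class`` in
    {Onset, Sustained, Delayed, NegControl}, ``cluster`` in {1, 2} (0 for
    negative controls), plus the realized electrophysiological parameters.
    ``genes`` has one row per gene: ``gene_id``, ``de_flag`` in
    {none, up_c1, up_c2} and ``true_log2fc`` on the cluster1-minus-cluster2
    scale.  ``psc_events`` maps cell id -> planted event times/amplitudes.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    psc_events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # cluster is a deterministic function of cell class
        expected = self.cells["cell_class"].map(
            {"Onset": 1, "Sustained": 1, "Delayed": 2, "NegControl": 0}
        )
        if not (self.cells["cluster"] == expected).all():
            raise ValueError("cluster labels inconsistent with cell classes")
        none_rows = self.genes["de_flag"] == "none"
        if not np.allclose(self.genes.loc[none_rows, "true_log2fc"], 0.0):
            raise ValueError("non-DE genes must have true_log2fc == 0")
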