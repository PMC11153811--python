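"""Generator configuration: cohort sizes, count-model laws, per-class
electrophysiology parameters.

Defaults emulate the two LSO neuron classes: principal LSO neurons (pLSO;
Onset and Sustained firing, low input resistance, prominent sag) and lateral
olivocochlear neurons (LOC; Delayed firing, high input resistance, positive
resting potential, no sag), in the proportions of the published cohort
(44 Onset + 12 Sustained + 30 Delayed plus 4 shallow negative controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EphysClassParams",
    "PSCKinetics",
    "GeneratorConfig",
    "default_ephys_params",
    "default_transmitter_probs",
    "default_transmitter_magnitudes",
    "TRANSMITTER_GENES",
]

#: The 7-gene neurotransmitter panel (mouse symbols):
#: vGLUT2, GlyT2, GAD65, DOPA decarboxylase, ChAT, CGRP, urocortin.
TRANSMITTER_GENES = ("Slc17a6", "Slc6a5", "Gad2", "Ddc", "Chat", "Calca", "Ucn")


@dataclass(frozen=True)
class PSCKinetics:
    """Spontaneous postsynaptic current event model for one polarity."""

    rate_hz: float = 2.0
    amp_pa: float = 50.0
    amp_cv: float = 0.1  # relative SD of per-event amplitude
    rise_ms: float = 0.4
    decay_ms: float = 3.0

    def validate(self) -> None:
        if min(self.rate_hz, self.amp_pa, self.rise_ms, self.decay_ms) < 0:
            raise ValueError("PSC kinetics must be non-negative")
        if self.decay_ms <= self.rise_ms:
            raise ValueError("decay time constant must exceed rise time constant")


@dataclass(frozen=True)
class EphysClassParams:
    """Per-class electrophysiological parameter distributions.

    Passive membrane: ``v_rest`` (mV), ``r_in`` (MOhm), ``c_m`` (pF) with the
    implied time constant tau_m = r_in * c_m / 1000 ms.  Firing: rheobase
    (pA), the first-AP latency law at rheobase, and a rate rule above
    rheobase.  AP waveform template and PSC kinetics per polarity.
    """

    name: str
    v_rest_mv: float
    v_rest_sd: float
    r_in_mohm: float
    r_in_cv: float
    c_m_pf: float
    c_m_cv: float
    r_s_mohm: float
    rheobase_pa: float
    rheobase_sd: float
    sag_amp_mv: float  # at the -200 pA step; 0 disables sag and rebound
    sag_amp_cv: float
    # sag kernel (1 - e^(-t/rise))^4 * e^(-t/decay): slow sigmoid activation
    # like I_h, so the fast membrane charging phase stays mono-exponential
    sag_rise_ms: float
    sag_decay_ms: float
    rebound_amp_mv: float
    latency_law: str  # "normal" | "shifted_exp"
    latency_mean_ms: float
    latency_sd_ms: float  # SD for normal, scale for shifted_exp
    latency_min_ms: float
    latency_max_ms: float
    firing_rule: str  # "onset" | "sustained" | "delayed"
    rate0_hz: float  # firing rate at rheobase (sustained/delayed rules)
    rate_slope_hz_per_pa: float
    ap_amplitude_mv: float
    ap_threshold_mv: float
    ap_halfwidth_ms: float
    ap_peak_latency_ms: float  # on the triangular pulse, from pulse onset
    epsc: PSCKinetics
    ipsc: PSCKinetics
    noise_sd_mv: float = 0.5
    noise_sd_pa: float = 3.0

    @property
    def tau_m_ms(self) -> float:
        return self.r_in_mohm * self.c_m_pf / 1000.0

    def validate(self) -> None:
        if not 0 < self.tau_m_ms < 50:
            raise ValueError("implied tau_m must be in (0, 50) ms")
        if self.latency_law == "shifted_exp" and not (
            self.latency_min_ms >= 25 or self.firing_rule != "delayed"
        ):
            raise ValueError("delayed latency law must have support within [25, 180] ms")
        if self.firing_rule == "delayed" and self.latency_max_ms > 180:
            raise ValueError("delayed latency law must have support within [25, 180] ms")
        self.epsc.validate()
        self.ipsc.validate()


def default_ephys_params() -> dict[str, EphysClassParams]:
    """Class parameter defaults.

    pLSO classes: R_in 96 MOhm, V_rest -64 mV, C_m 11 pF, prominent sag and
    rebound; Onset latency ~2.9 ms, Sustained ~7.0 ms.  LOC/Delayed: R_in
    ~300 MOhm, V_rest -43 mV, C_m 6 pF, no sag, first-AP delay 25-180 ms
    with mean ~29.4 ms; PSC kinetics slower than in pLSOs.
    """
    onset = EphysClassParams(
        name="Onset",
        v_rest_mv=-64.0, v_rest_sd=1.5,
        r_in_mohm=96.0, r_in_cv=0.08,
        c_m_pf=11.0, c_m_cv=0.08,
        r_s_mohm=15.0,
        rheobase_pa=250.0, rheobase_sd=30.0,
        sag_amp_mv=4.0, sag_amp_cv=0.15, sag_rise_ms=12.0, sag_decay_ms=40.0,
        rebound_amp_mv=2.0,
        latency_law="normal",
        latency_mean_ms=2.9, latency_sd_ms=0.4,
        latency_min_ms=0.8, latency_max_ms=12.0,
        firing_rule="onset",
        rate0_hz=0.0, rate_slope_hz_per_pa=0.0,
        ap_amplitude_mv=75.0, ap_threshold_mv=-40.0,
        ap_halfwidth_ms=0.5, ap_peak_latency_ms=2.0,
        epsc=PSCKinetics(rate_hz=2.0, amp_pa=60.0, rise_ms=0.25, decay_ms=1.5),
        ipsc=PSCKinetics(rate_hz=2.0, amp_pa=50.0, rise_ms=0.4, decay_ms=3.0),
    )
    sustained = replace(
        onset,
        name="Sustained",
        latency_mean_ms=7.0, latency_sd_ms=0.8,
        latency_min_ms=3.0, latency_max_ms=12.0,
        firing_rule="sustained",
        rate0_hz=10.0, rate_slope_hz_per_pa=0.30,
        sag_amp_mv=3.0,
    )
    delayed = EphysClassParams(
        name="Delayed",
        v_rest_mv=-43.0, v_rest_sd=1.5,
        r_in_mohm=300.0, r_in_cv=0.10,
        c_m_pf=6.0, c_m_cv=0.08,
        r_s_mohm=15.0,
        rheobase_pa=100.0, rheobase_sd=15.0,
        sag_amp_mv=0.0, sag_amp_cv=0.0, sag_rise_ms=12.0, sag_decay_ms=40.0,
        rebound_amp_mv=0.0,
        latency_law="shifted_exp",
        latency_mean_ms=29.4, latency_sd_ms=4.4,  # 25 + Exp(4.4) -> mean 29.4
        latency_min_ms=25.0, latency_max_ms=180.0,
        firing_rule="delayed",
        rate0_hz=20.0, rate_slope_hz_per_pa=0.20,
        ap_amplitude_mv=60.0, ap_threshold_mv=-25.0,
        ap_halfwidth_ms=0.8, ap_peak_latency_ms=2.5,
        epsc=PSCKinetics(rate_hz=2.0, amp_pa=45.0, rise_ms=0.5, decay_ms=3.0),
        ipsc=PSCKinetics(rate_hz=2.0, amp_pa=40.0, rise_ms=0.8, decay_ms=6.0),
    )
    return {"Onset": onset, "Sustained": sustained, "Delayed": delayed}


def default_transmitter_probs() -> dict[str, dict[str, float]]:
    """Per-class Bernoulli gate probabilities for the 7-gene panel.

    Set from the printed per-cohort percentages: e.g. vGLUT2 in ~66% of
    pLSOs (70% Onset, 50% Sustained), CGRP/urocortin in 93%/83% of LOCs.
    """
    table = {
        #            Onset  Sust.  Delayed
        "Slc17a6": (0.70, 0.50, 0.20),
        "Slc6a5":  (0.05, 0.42, 0.17),
        "Gad2":    (0.18, 0.33, 0.67),
        "Ddc":     (0.06, 0.06, 0.30),
        "Chat":    (0.01, 0.01, 0.17),
        "Calca":   (0.02, 0.02, 0.93),
        "Ucn":     (0.02, 0.02, 0.83),
    }
    return {
        g: {"Onset": a, "Sustained": b, "Delayed": c} for g, (a, b, c) in table.items()
    }


def default_transmitter_magnitudes() -> dict[str, float]:
    """Mean count when a transmitter gene's gate is on (CGRP highest)."""
    return {
        "Slc17a6": 30.0,
        "Slc6a5": 20.0,
        "Gad2": 40.0,
        "Ddc": 80.0,
        "Chat": 20.0,
        "Calca": 400.0,
        "Ucn": 100.0,
    }


@dataclass
class GeneratorConfig:
    """Full configuration for the paired transcriptomic + ephys generator.

    The count model is negative binomial:
    ``counts ~ NB(mean = libsize_c * base_g * 2^(lfc_g * 1[cluster match]),
    dispersion)`` with optional independent Bernoulli dropout, a block of
    highly expressed shared housekeeping genes, the 7 transmitter-panel
    genes gated per class, and ``negcontrol_n`` cells at ``depth_scale``
    of the neuronal depth.
    """

    # cohort sizes
    n_onset: int = 44
    n_sustained: int = 12
    n_delayed: int = 30
    negcontrol_n: int = 4
    depth_scale: float = 1.0 / 8.0

    # gene structure
    n_genes: int = 2000
    n_markers_c1: int = 250
    n_markers_c2: int = 100
    n_housekeeping: int = 50

    # marker effect size: log2FC = lfc_base + |Normal(lfc_mean, lfc_sd)|
    marker_lfc_base: float = 1.0
    marker_lfc_mean: float = 0.5
    marker_lfc_sd: float = 0.5

    # per-gene baseline expression: LogNormal(mu, sigma) of the mean count
    baseline_log_mean: float = float(np.log(4.0))
    baseline_log_sd: float = 1.3
    housekeeping_log_mean: float = float(np.log(300.0))
    housekeeping_log_sd: float = 0.5

    dispersion: float = 0.3  # NB dispersion (var = mu + disp * mu^2)
    libsize_log_sd: float = 0.3
    dropout_rate: float = 0.05

    gene_length_min_bp: int = 500
    gene_length_max_bp: int = 5000

    transmitter_probs: dict = field(default_factory=default_transmitter_probs)
    transmitter_magnitudes: dict = field(default_factory=default_transmitter_magnitudes)
    ephys_params: dict = field(default_factory=default_ephys_params)

    # sampling rates (Hz)
    fs_current_clamp: float = 50_000.0
    fs_voltage_clamp: float = 20_000.0
    fs_psc: float = 20_000.0
    fs_rest: float = 5_000.0

    rest_duration_s: float = 30.0
    psc_duration_s: float = 60.0

    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_onset, self.n_sustained, self.n_delayed, self.negcontrol_n,
            self.n_genes, self.n_markers_c1, self.n_markers_c2, self.n_housekeeping,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all cohort/gene counts must be >= 0")
        if not 0 < self.depth_scale < 1:
            raise ValueError("depth_scale must be in (0, 1)")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be a probability")
        n_special = len(TRANSMITTER_GENES) + self.n_housekeeping
        if self.n_markers_c1 + self.n_markers_c2 + n_special > self.n_genes:
            raise ValueError("marker sets plus special genes exceed n_genes")
        for gene, probs in self.transmitter_probs.items():
            for p in probs.values():
                if not 0 <= p <= 1:
                    raise ValueError(f"transmitter gate probability out of [0,1] for {gene}")
        for params in self.ephys_params.values():
            params.validate()

    @property
    def n_neurons(self) -> int:
        return self.n_onset + self.n_sustained + self.n_delayed

    @property
    def n_cells(self) -> int:
        return self.n_neurons + self.negcontrol_n

    def cell_classes(self) -> list[str]:
        """Class label per cell, in generation order."""
        return (
            ["Onset"] * self.n_onset
            + ["Sustained"] * self.n_sustained
            + ["Delayed"] * self.n_delayed
            + ["NegControl"] * self.negcontrol_n
        )
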