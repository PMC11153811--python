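"""Electrophysiological feature extraction from stimulus-tagged traces.

Implements the 16-feature characterization used downstream: resting
potential (30-s average), membrane time constant (mono-exponential fit of
the initial hyperpolarizing response at -200 pA), series and input
resistance from a -5 mV voltage-clamp step, capacitance C_m = tau_m / R_in,
rheobase from the 50-pA step family, firing-pattern classification
(Onset / Sustained / Delayed), voltage sag and rebound, AP waveform metrics
(amplitude, threshold, halfwidth from baseline), and spontaneous PSC
amplitude and kinetics (10-90% rise, 100-37% decay) per polarity, averaging
up to 100 events.

Extraction is deterministic: no randomness enters any measurement.
Missing or unmeasurable quantities are returned as NaN, never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .datatypes import Trace, TraceSet

__all__ = [
    "APRecord",
    "PSCEvent",
    "PSCSummary",
    "EphysFeatures",
    "FEATURES_16",
    "measure_vrest",
    "fit_membrane_time_constant",
    "measure_rin_rs",
    "derive_cm",
    "detect_aps",
    "approximate_rheobase",
    "classify_firing_pattern",
    "measure_sag",
    "detect_pscs",
    "extract_feature_vector",
    "features_to_frame",
]

#: default 16-feature subset used for PCA and cohort statistics
FEATURES_16 = [
    "v_rest", "r_in", "tau_m", "c_m", "rheobase", "first_ap_latency",
    "sag_amp", "ap_amplitude", "ap_halfwidth", "ap_threshold",
    "sepsc_amp", "sepsc_rise", "sepsc_decay",
    "sipsc_amp", "sipsc_rise", "sipsc_decay",
]


@dataclass
class APRecord:
    peak_time: float  # ms from trace start
    peak_v: float
    threshold_v: float
    amplitude: float
    halfwidth: float  # ms
    latency: float  # ms from stimulus onset


@dataclass
class PSCEvent:
    onset_time: float  # s
    polarity: str  # "inward" | "outward"
    amplitude: float  # pA, magnitude


@dataclass
class PSCSummary:
    polarity: str
    n_events: int
    amplitude: float = np.nan
    rise_10_90: float = np.nan
    decay_100_37: float = np.nan
    low_confidence: bool = True
    waveform: np.ndarray | None = None


@dataclass
class EphysFeatures:
    """Per-cell feature vector; NaN marks a missing measurement."""

    cell_id: str = ""
    v_rest: float = np.nan
    r_in: float = np.nan
    r_s: float = np.nan
    tau_m: float = np.nan
    c_m: float = np.nan
    rheobase: float = np.nan
    first_ap_latency: float = np.nan
    sag_amp: float = np.nan
    rebound: bool = False
    ap_amplitude: float = np.nan
    ap_halfwidth: float = np.nan
    ap_threshold: float = np.nan
    sepsc_amp: float = np.nan
    sepsc_rise: float = np.nan
    sepsc_decay: float = np.nan
    sipsc_amp: float = np.nan
    sipsc_rise: float = np.nan
    sipsc_decay: float = np.nan
    firing_class: str | None = None


def features_to_frame(feats: list[EphysFeatures]) -> pd.DataFrame:
    cols = [f.name for f in fields(EphysFeatures)]
    return pd.DataFrame([{c: getattr(x, c) for c in cols} for x in feats]).set_index("cell_id")


# ---------------------------------------------------------------------------


def measure_vrest(trace: Trace) -> float:
    """Resting potential: arithmetic mean of the full rest segment (mV)."""
    if trace.units != "mV":
        raise TypeError("resting potential requires a voltage trace")
    if trace.duration < 1.0:
        raise ValueError("rest segment shorter than 1 s")
    return float(trace.signal.mean())


def _baseline(trace: Trace) -> float:
    """Mean voltage/current before stimulus onset (first 10% if untagged)."""
    onset = trace.params.get("onset_s")
    n = int(onset * trace.sampling_rate) if onset else max(trace.signal.size // 10, 1)
    return float(trace.signal[:n].mean())


def fit_membrane_time_constant(trace: Trace, window_factor: float = 3.0) -> float:
    """Mono-exponential fit of the initial phase of the -200 pA response.

    The fit window runs from step onset to ``window_factor`` times a coarse
    63% estimate, which keeps a slow sag component from contaminating the
    fast membrane charging phase.  Returns tau_m in ms, NaN when degenerate.
    """
    fs = trace.sampling_rate
    onset = trace.params["onset_s"]
    offset = trace.params.get("offset_s", trace.duration)
    i0, i1 = int(onset * fs), int(offset * fs)
    base = _baseline(trace)
    seg = trace.signal[i0:i1]
    n_q = max((i1 - i0) // 4, 1)
    v_ss = seg[-n_q:].mean()
    dv = v_ss - base
    if abs(dv) < 1.0:
        return np.nan
    crossed = np.nonzero(np.sign(dv) * (seg - base) >= 0.632 * abs(dv))[0]
    if crossed.size == 0:
        return np.nan
    tau_coarse = crossed[0] / fs * 1000.0
    n_fit = max(int(window_factor * tau_coarse / 1000.0 * fs), 10)
    t_ms = np.arange(min(n_fit, seg.size)) / fs * 1000.0
    y = seg[: t_ms.size]

    def model(t, v_inf, v0, tau):
        return v_inf + (v0 - v_inf) * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t_ms, y, p0=(v_ss, base, max(tau_coarse, 0.05)), maxfev=5000
        )
    except RuntimeError:
        return np.nan
    tau = popt[2]
    return float(tau) if 0 < tau < 1000 else np.nan


def measure_rin_rs(trace: Trace, peak_window_ms: float = 2.0) -> tuple[float, float]:
    """Series and input resistance from the -5 mV voltage-clamp step.

    R_s = dV / I_peak using the capacitive transient peak; R_in = dV / I_ss
    - R_s with I_ss the mean over the last quartile of the step.  Returns
    (r_in, r_s) in MOhm; (NaN, NaN) when the steady-state current has the
    wrong sign or the transient is absent.
    """
    if trace.units != "pA":
        raise TypeError("R_s/R_in require a current trace")
    fs = trace.sampling_rate
    dv = trace.params["delta_mv"]
    i0 = int(trace.params["onset_s"] * fs)
    i1 = int(trace.params["offset_s"] * fs)
    base = _baseline(trace)
    seg = trace.signal[i0:i1] - base
    n_peak = max(int(peak_window_ms / 1000.0 * fs), 2)
    i_peak = seg[:n_peak].min() if dv < 0 else seg[:n_peak].max()
    n_q = max(seg.size // 4, 1)
    i_ss = seg[-n_q:].mean()
    if i_ss * dv <= 0 or i_peak * dv <= 0:
        return np.nan, np.nan
    r_s = dv / i_peak * 1000.0  # mV/pA -> GOhm -> MOhm
    r_total = dv / i_ss * 1000.0
    r_in = r_total - r_s
    if r_in <= 0:
        return np.nan, float(r_s)
    return float(r_in), float(r_s)


def derive_cm(tau_m: float, r_in: float) -> float:
    """Membrane capacitance C_m = tau_m / R_in (ms / MOhm -> nF), in pF."""
    if not np.isfinite(tau_m) or not np.isfinite(r_in) or tau_m <= 0 or r_in <= 0:
        return np.nan
    return tau_m / r_in * 1000.0


# ---------------------------------------------------------------------------
# action potentials


def detect_aps(
    trace: Trace,
    peak_threshold_mv: float = -10.0,
    dvdt_threshold_v_per_s: float = 10.0,
    refractory_ms: float = 1.0,
    smooth_ms: float = 0.5,
    run_ms: float = 0.2,
) -> list[APRecord]:
    """Detect APs as peaks above an absolute voltage with a refractory gap.

    AP threshold is the voltage where the (smoothed) dV/dt last rises
    through the criterion before the peak and stays above it; a crossing
    only counts after a sustained (``run_ms``) sub-criterion stretch, which
    keeps single noisy dV/dt dips near the peak from masquerading as the
    spike foot.  Amplitude is referenced to the pre-stimulus baseline;
    halfwidth is the width at baseline + half amplitude.
    """
    if trace.units != "mV":
        raise TypeError("AP detection requires a voltage trace")
    v = trace.signal
    fs = trace.sampling_rate
    dist = max(int(refractory_ms / 1000.0 * fs), 1)
    peaks, _ = find_peaks(v, height=peak_threshold_mv, distance=dist)
    if peaks.size == 0:
        return []
    base = _baseline(trace)
    onset_ms = trace.params.get("onset_s", 0.0) * 1000.0

    win = max(int(smooth_ms / 1000.0 * fs) | 1, 5)
    dvdt = savgol_filter(v, win, polyorder=3, deriv=1, delta=1.0 / fs) * 1e-3  # V/s

    n_run = max(int(run_ms / 1000.0 * fs), 1)
    records = []
    for pk in peaks:
        amp = v[pk] - base
        if amp <= 0:
            continue
        lo = max(pk - int(0.005 * fs), 0)
        below = dvdt[lo:pk] < dvdt_threshold_v_per_s
        run, end = 0, None
        for i, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= n_run:
                end = i
        thr_idx = lo + end + 1 if end is not None else lo
        thr_v = float(v[min(thr_idx, pk)])
        half_level = base + 0.5 * amp
        hw = _width_at_level(v, pk, half_level, fs)
        t_pk = pk / fs * 1000.0
        records.append(
            APRecord(
                peak_time=t_pk, peak_v=float(v[pk]), threshold_v=thr_v,
                amplitude=float(amp), halfwidth=hw, latency=t_pk - onset_ms,
            )
        )
    return records


def _width_at_level(v: np.ndarray, peak: int, level: float, fs: float) -> float:
    """Linear-interpolated width (ms) of the spike around ``peak`` at ``level``."""
    left = peak
    while left > 0 and v[left] > level:
        left -= 1
    right = peak
    while right < v.size - 1 and v[right] > level:
        right += 1
    if v[left] > level or v[right] > level:
        return np.nan
    t_l = left + (level - v[left]) / (v[left + 1] - v[left]) if v[left + 1] != v[left] else left
    t_r = right - 1 + (level - v[right - 1]) / (v[right] - v[right - 1]) \
        if v[right] != v[right - 1] else right
    return float((t_r - t_l) / fs * 1000.0)


def approximate_rheobase(step_traces: list[Trace], **detect_kwargs) -> float:
    """Smallest step amplitude whose response holds >= 1 AP (pA; NaN if none).

    The family must be ordered by increasing amplitude.
    """
    amps = [t.params["amplitude_pa"] for t in step_traces]
    if any(b <= a for a, b in zip(amps, amps[1:])):
        raise ValueError("step family must be ordered by increasing amplitude")
    for tr in step_traces:
        if tr.params["amplitude_pa"] <= 0:
            continue
        if detect_aps(tr, **detect_kwargs):
            return float(tr.params["amplitude_pa"])
    return np.nan


def classify_firing_pattern(
    step_traces: list[Trace],
    rheobase: float,
    latency_threshold_ms: float = 15.0,
    onset_max_aps: int = 5,
    test_increment_pa: float = 150.0,
    **detect_kwargs,
) -> tuple[str | None, float]:
    """Firing class from the step family given the rheobase.

    First-AP latency is measured at rheobase.  Delayed if latency >= 15 ms;
    otherwise Onset if the AP count at rheobase + 150 pA is <= 5, else
    Sustained.  Returns (class, first_ap_latency_ms); (None, NaN) when
    rheobase is undefined.
    """
    if not np.isfinite(rheobase):
        return None, np.nan
    by_amp = {t.params["amplitude_pa"]: t for t in step_traces}
    aps_rheo = detect_aps(by_amp[rheobase], **detect_kwargs)
    if not aps_rheo:
        return None, np.nan
    latency = aps_rheo[0].latency
    if latency >= latency_threshold_ms:
        return "Delayed", latency
    target = rheobase + test_increment_pa
    amps = np.array(sorted(by_amp))
    nearest = float(amps[np.argmin(np.abs(amps - target))])
    n_aps = len(detect_aps(by_amp[nearest], **detect_kwargs))
    return ("Onset" if n_aps <= onset_max_aps else "Sustained"), latency


def measure_sag(
    trace: Trace,
    peak_search_ms: float = 50.0,
    smooth_ms: float = 1.0,
    rebound_min_ms: float = 5.0,
) -> tuple[float, bool]:
    """Sag amplitude and rebound flag from the -200 pA step response.

    sag = |peak hyperpolarization (first 50 ms, smoothed)| - |steady state|
    with steady state the mean of the last quartile of the step.  Rebound is
    true when the post-offset voltage exceeds baseline by >= 2x the noise SD
    (floored at 0.1 mV) for at least 5 contiguous ms.
    """
    fs = trace.sampling_rate
    i0 = int(trace.params["onset_s"] * fs)
    i1 = int(trace.params["offset_s"] * fs)
    base = _baseline(trace)
    noise_sd = float(trace.signal[: i0 or trace.signal.size // 10].std())

    from scipy.ndimage import uniform_filter1d

    k = max(int(smooth_ms / 1000.0 * fs), 1)
    seg = uniform_filter1d(trace.signal[i0:i1], k, mode="nearest")
    n_peak = min(int(peak_search_ms / 1000.0 * fs), seg.size)
    v_peak = seg[:n_peak].min()
    n_q = max(seg.size // 4, 1)
    v_ss = seg[-n_q:].mean()
    sag = max(v_ss - v_peak, 0.0)

    post = uniform_filter1d(trace.signal[i1:], k, mode="nearest")
    thresh = base + max(2.0 * noise_sd, 0.1)
    above = post > thresh
    need = int(rebound_min_ms / 1000.0 * fs)
    rebound = _longest_run(above) >= need
    return float(sag), bool(rebound)


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return int((ends - starts).max())


# ---------------------------------------------------------------------------
# spontaneous postsynaptic currents


def detect_pscs(
    trace: Trace,
    threshold_k: float = 4.0,
    max_events: int = 100,
    min_separation_ms: float = 10.0,
    min_above_ms: float = 0.2,
    window_post_ms: float = 40.0,
    window_pre_ms: float = 5.0,
) -> tuple[list[PSCEvent], dict[str, PSCSummary]]:
    """Threshold-crossing PSC detection and averaged-waveform kinetics.

    Events are detected per polarity at ``threshold_k`` x the robust noise
    SD (1.4826 x MAD) and must stay above threshold for ``min_above_ms``
    (single-sample noise excursions are not events); the first
    ``max_events`` per polarity are aligned on their peak and averaged.  Amplitude, 10-90% rise time and
    100-37% decay time are measured on the averaged waveform.  Polarities
    with fewer than 10 events are flagged low-confidence.
    """
    if trace.units != "pA":
        raise TypeError("PSC detection requires a current trace")
    sig = trace.signal
    fs = trace.sampling_rate
    med = np.median(sig)
    sd = 1.4826 * np.median(np.abs(sig - med))
    if sd == 0:
        sd = sig.std() or 1.0

    events: list[PSCEvent] = []
    summaries: dict[str, PSCSummary] = {}
    n_pre = int(window_pre_ms / 1000.0 * fs)
    n_post = int(window_post_ms / 1000.0 * fs)
    for polarity, sign in (("inward", -1.0), ("outward", 1.0)):
        x = sign * (sig - med)
        crossings = np.nonzero((x[1:] >= threshold_k * sd) & (x[:-1] < threshold_k * sd))[0] + 1
        onsets = []
        last = -np.inf
        min_gap = min_separation_ms / 1000.0 * fs
        n_above = max(int(min_above_ms / 1000.0 * fs), 1)
        level = threshold_k * sd
        n_back0, n_back1 = int(0.001 * fs), max(int(0.00025 * fs), 1)
        for c in crossings:
            if c - last < min_gap:
                last = c
                continue
            last = c
            # sustained excursion, tolerant of isolated noise dips
            if np.count_nonzero(x[c:c + 3 * n_above] >= level) >= n_above:
                # reject re-crossings inside a previous event's tail: a real
                # onset rises from near baseline, not from half threshold
                pre = x[max(c - n_back0, 0):c - n_back1]
                if pre.size == 0 or np.median(pre) < 0.5 * level:
                    onsets.append(c)
        pol_events = []
        segs = []
        n_search = int(0.005 * fs)  # event peak lies within 5 ms of the crossing
        k_amp = max(int(0.00025 * fs) | 1, 3)  # light smoothing for peak reads
        xs = np.convolve(x, np.ones(k_amp) / k_amp, mode="same")
        for c in onsets:
            if c - n_pre < 0 or c + n_post > x.size:
                continue
            pv = xs[c:c + n_search].max()
            pol_events.append(PSCEvent(onset_time=c / fs, polarity=polarity, amplitude=float(pv)))
            # align on the steep 50%-of-peak rising crossing: peak-aligned
            # averages smear the rise because the biexponential peak is flat
            lo = max(c - n_search, 0)
            half = np.nonzero(xs[lo:c + n_search] >= 0.5 * pv)[0]
            if half.size == 0:
                continue
            a = lo + half[0]
            if len(segs) < max_events and a - n_pre >= 0 and a + n_post <= x.size:
                segs.append(x[a - n_pre:a + n_post])
        events.extend(pol_events)
        summary = PSCSummary(polarity=polarity, n_events=len(pol_events))
        if segs:
            avg = np.mean(segs, axis=0)
            base = avg[: max(n_pre - int(0.002 * fs), 1)].mean()
            pk = n_pre + int(np.argmax(avg[n_pre:n_pre + n_search]))
            amp = avg[pk] - base
            if amp > 0:
                summary.amplitude = float(amp)
                summary.rise_10_90 = _rise_time(avg, base, pk, fs)
                summary.decay_100_37 = _decay_time(avg, base, pk, fs)
                summary.waveform = sign * avg + med
        summary.low_confidence = summary.n_events < 10
        summaries[polarity] = summary
    return events, summaries


def _crossing(seg: np.ndarray, level: float, rising: bool) -> float:
    """Fractional index of the first crossing of ``level`` in ``seg``."""
    if rising:
        idx = np.nonzero(seg >= level)[0]
    else:
        idx = np.nonzero(seg <= level)[0]
    if idx.size == 0:
        return np.nan
    i = idx[0]
    if i == 0 or seg[i] == seg[i - 1]:
        return float(i)
    return float(i - 1 + (level - seg[i - 1]) / (seg[i] - seg[i - 1]))


def _rise_time(avg: np.ndarray, base: float, pk: int, fs: float) -> float:
    amp = avg[pk] - base
    seg = avg[: pk + 1]
    t10 = _crossing(seg, base + 0.1 * amp, rising=True)
    t90 = _crossing(seg, base + 0.9 * amp, rising=True)
    if np.isnan(t10) or np.isnan(t90):
        return np.nan
    return float((t90 - t10) / fs * 1000.0)


def _decay_time(avg: np.ndarray, base: float, pk: int, fs: float) -> float:
    amp = avg[pk] - base
    t37 = _crossing(avg[pk:], base + 0.37 * amp, rising=False)
    return float(t37 / fs * 1000.0) if not np.isnan(t37) else np.nan


# ---------------------------------------------------------------------------


def extract_feature_vector(ts: TraceSet, **class_kwargs) -> EphysFeatures:
    """Assemble the per-cell feature vector from all available protocols.

    Protocols that are absent simply leave their features NaN-flagged.
    """
    f = EphysFeatures(cell_id=ts.cell_id)

    if "rest" in ts:
        f.v_rest = measure_vrest(ts["rest"])

    if "vc_step" in ts:
        f.r_in, f.r_s = measure_rin_rs(ts["vc_step"])

    if "step_-200" in ts:
        f.tau_m = fit_membrane_time_constant(ts["step_-200"])
        f.sag_amp, f.rebound = measure_sag(ts["step_-200"])

    f.c_m = derive_cm(f.tau_m, f.r_in)

    steps = ts.step_traces()
    if steps:
        f.rheobase = approximate_rheobase(steps)
        f.firing_class, f.first_ap_latency = classify_firing_pattern(
            steps, f.rheobase, **class_kwargs
        )

    tris = ts.triangular_traces()
    if tris:
        amps, hws, thrs = [], [], []
        for tr in tris:
            aps = detect_aps(tr)
            if aps:
                amps.append(aps[0].amplitude)
                hws.append(aps[0].halfwidth)
                thrs.append(aps[0].threshold_v)
        if amps:
            f.ap_amplitude = float(np.mean(amps))
            f.ap_halfwidth = float(np.nanmean(hws))
            f.ap_threshold = float(np.mean(thrs))

    if "psc" in ts:
        _, summaries = detect_pscs(ts["psc"])
        sin = summaries.get("inward")
        if sin and sin.n_events:
            f.sepsc_amp, f.sepsc_rise, f.sepsc_decay = (
                sin.amplitude, sin.rise_10_90, sin.decay_100_37
            )
        sout = summaries.get("outward")
        if sout and sout.n_events:
            f.sipsc_amp, f.sipsc_rise, f.sipsc_decay = (
                sout.amplitude, sout.rise_10_90, sout.decay_100_37
            )
    return f
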