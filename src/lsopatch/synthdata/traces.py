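"""Parametric synthesis of patch-clamp recordings.

Traces are built from closed-form RC responses with stereotyped action
potentials inserted at rule-driven times (integrate-and-fire style: the
subthreshold trajectory is clipped at the AP threshold voltage), so every
generated feature is exactly recoverable.  Protocols mirror a standard
whole-cell characterization: a 30-s rest segment, a current-step family
(-200..1000 pA in 50-pA steps, 200 ms), ten brief triangular pulses for AP
waveform metrics, a -5 mV voltage-clamp step for R_s/R_in, and a 60-s
continuous recording of spontaneous postsynaptic currents at V_hold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import GroundTruth, Trace, TraceSet
from .config import EphysClassParams, GeneratorConfig

__all__ = [
    "realize_cell_ephys",
    "generate_traces",
    "generate_pscs",
    "iter_tracesets",
    "STEP_AMPLITUDES_PA",
]

STEP_AMPLITUDES_PA = np.arange(-200, 1001, 50)

STEP_PRE_S = 0.050
STEP_DUR_S = 0.200
STEP_POST_S = 0.150

TRI_PRE_S = 0.002
TRI_RISE_S = 0.0015
TRI_DECAY_S = 0.0035
TRI_POST_S = 0.010

VC_PRE_S = 0.020
VC_DUR_S = 0.200
VC_POST_S = 0.080
VC_DELTA_MV = -5.0
VC_HOLD_MV = -70.0


def _cell_rng(config: GeneratorConfig, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream, index))
    )


def realize_cell_ephys(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-cell electrophysiological parameters from the class laws.

    Negative controls get NaN parameters (no recordings exist for them).
    The stored ``ap_threshold_measured`` is the threshold the dV/dt
    criterion reads off the clean AP waveform, so recovery tests compare
    like with like.
    """
    rows = []
    for cls in config.cell_classes():
        if cls == "NegControl":
            rows.append({"cell_class": cls, "cluster": 0})
            continue
        p: EphysClassParams = config.ephys_params[cls]
        lat = _draw_latency(p, rng)
        rheo = float(np.round(rng.normal(p.rheobase_pa, p.rheobase_sd) / 10) * 10)
        rheo = max(rheo, 50.0)
        sag = 0.0
        if p.sag_amp_mv > 0:
            sag = max(float(rng.normal(p.sag_amp_mv, p.sag_amp_mv * p.sag_amp_cv)), 0.5)
        row = {
            "cell_class": cls,
            "cluster": 1 if cls in ("Onset", "Sustained") else 2,
            "v_rest": float(rng.normal(p.v_rest_mv, p.v_rest_sd)),
            "r_in": float(rng.normal(p.r_in_mohm, p.r_in_mohm * p.r_in_cv)),
            "c_m": float(rng.normal(p.c_m_pf, p.c_m_pf * p.c_m_cv)),
            "r_s": p.r_s_mohm,
            "rheobase": rheo,
            "first_ap_latency": lat,
            "sag_amp": sag,
            "sag_rise": p.sag_rise_ms,
            "sag_decay": p.sag_decay_ms,
            "rebound_amp": p.rebound_amp_mv if sag > 0 else 0.0,
            "ap_amplitude": p.ap_amplitude_mv,
            "ap_threshold": p.ap_threshold_mv,
            "ap_halfwidth": p.ap_halfwidth_ms,
            "ap_peak_latency": p.ap_peak_latency_ms,
            "epsc_rate": p.epsc.rate_hz, "epsc_amp": p.epsc.amp_pa,
            "epsc_rise": p.epsc.rise_ms, "epsc_decay": p.epsc.decay_ms,
            "ipsc_rate": p.ipsc.rate_hz, "ipsc_amp": p.ipsc.amp_pa,
            "ipsc_rise": p.ipsc.rise_ms, "ipsc_decay": p.ipsc.decay_ms,
            "noise_sd_mv": p.noise_sd_mv, "noise_sd_pa": p.noise_sd_pa,
        }
        row["tau_m"] = row["r_in"] * row["c_m"] / 1000.0
        row["ap_threshold_measured"] = _calibrate_measured_threshold(config, row)
        rows.append(row)
    return pd.DataFrame(rows)


def _draw_latency(p: EphysClassParams, rng: np.random.Generator) -> float:
    if p.latency_law == "shifted_exp":
        lat = p.latency_min_ms + rng.exponential(p.latency_sd_ms)
    else:
        lat = rng.normal(p.latency_mean_ms, p.latency_sd_ms)
    return float(np.clip(lat, p.latency_min_ms, p.latency_max_ms))


# ---------------------------------------------------------------------------
# waveform building blocks


def _ap_template(t_ms: np.ndarray, peak_ms: float, v_rest: float,
                 amplitude: float, halfwidth_ms: float) -> np.ndarray:
    """Gaussian spike whose absolute peak is v_rest + amplitude and whose
    full width at the 50%-of-amplitude level equals halfwidth."""
    sigma = halfwidth_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return v_rest + amplitude * np.exp(-0.5 * ((t_ms - peak_ms) / sigma) ** 2)


def _insert_aps(v: np.ndarray, t_ms: np.ndarray, times_ms: np.ndarray,
                v_rest: float, amplitude: float, halfwidth_ms: float) -> None:
    sigma = halfwidth_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    dt = t_ms[1] - t_ms[0]
    half = int(np.ceil(6 * sigma / dt))
    for tm in times_ms:
        i0 = int(round((tm - t_ms[0]) / dt))
        lo, hi = max(i0 - half, 0), min(i0 + half + 1, v.size)
        if lo >= hi:
            continue
        spike = _ap_template(t_ms[lo:hi], tm, v_rest, amplitude, halfwidth_ms)
        np.maximum(v[lo:hi], spike, out=v[lo:hi])


def _sag_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    # sigmoid activation (like I_h) so the initial membrane charging phase
    # remains a clean mono-exponential for the tau_m fit
    return (1.0 - np.exp(-t_ms / tau_rise)) ** 4 * np.exp(-t_ms / tau_decay)


def _ap_times_ms(p: EphysClassParams, amp_pa: float, rheo_pa: float,
                 latency_ms: float, step_ms: float) -> np.ndarray:
    """Firing rule: AP times relative to step onset, empty below rheobase."""
    if amp_pa < rheo_pa:
        return np.empty(0)
    t_max = step_ms - 5.0
    if p.firing_rule == "onset":
        n = int(min(1 + (amp_pa - rheo_pa) // 100, 4))
        times = latency_ms + 3.0 * np.arange(n)
    else:
        rate = p.rate0_hz + p.rate_slope_hz_per_pa * (amp_pa - rheo_pa)
        if rate <= 0:
            times = np.array([latency_ms])
        else:
            isi = 1000.0 / rate
            n = max(int(np.floor((t_max - latency_ms) / isi)) + 1, 1)
            times = latency_ms + isi * np.arange(n)
    return times[times <= t_max]


def _step_trace(config: GeneratorConfig, p: EphysClassParams, cell: dict,
                amp_pa: float, rng: np.random.Generator) -> Trace:
    fs = config.fs_current_clamp
    n_pre = int(STEP_PRE_S * fs)
    n_step = int(STEP_DUR_S * fs)
    n_post = int(STEP_POST_S * fs)
    vr, r_in, tau = cell["v_rest"], cell["r_in"], cell["tau_m"]
    thr = cell["ap_threshold"]

    t_step = np.arange(n_step) / fs * 1000.0  # ms from step onset
    dv_inf = amp_pa * r_in * 1e-3
    v_step = vr + dv_inf * (1.0 - np.exp(-t_step / tau))

    if amp_pa < 0 and cell["sag_amp"] > 0:
        u = _sag_kernel(t_step, cell["sag_rise"], cell["sag_decay"])
        # calibrate so (peak in first 50 ms) - (mean of last quartile) == sag
        first = u[t_step <= 50.0]
        unit = first.max() - u[t_step >= 0.75 * STEP_DUR_S * 1000.0].mean()
        scale = cell["sag_amp"] * (amp_pa / -200.0) / unit
        v_step = v_step - scale * u
    elif amp_pa > 0:
        times = _ap_times_ms(p, amp_pa, cell["rheobase"], cell["first_ap_latency"],
                             STEP_DUR_S * 1000.0)
        clip = thr if times.size else thr - 1.0
        np.minimum(v_step, clip, out=v_step)
        if times.size:
            _insert_aps(v_step, t_step, times, vr, cell["ap_amplitude"],
                        cell["ap_halfwidth"])

    v_off = v_step[-1] if amp_pa != 0 else vr
    if amp_pa > 0:
        v_off = min(v_off, thr)
    t_post = np.arange(n_post) / fs * 1000.0
    v_post = vr + (v_off - vr) * np.exp(-t_post / tau)
    if amp_pa < 0 and cell["rebound_amp"] > 0:
        w = _sag_kernel(t_post, cell["sag_rise"], cell["sag_decay"])
        v_post = v_post + cell["rebound_amp"] * (-amp_pa / 200.0) * w / w.max()

    v = np.concatenate([np.full(n_pre, vr), v_step, v_post])
    if p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, v.size)
    return Trace(
        signal=v, sampling_rate=fs, protocol="current_step", units="mV",
        params={"amplitude_pa": float(amp_pa), "onset_s": STEP_PRE_S,
                "offset_s": STEP_PRE_S + STEP_DUR_S},
    )


def _triangular_trace(config: GeneratorConfig, p: EphysClassParams, cell: dict,
                      rng: np.random.Generator | None,
                      with_ap: bool = True) -> Trace:
    fs = config.fs_current_clamp
    dt_ms = 1000.0 / fs
    n = int((TRI_PRE_S + TRI_RISE_S + TRI_DECAY_S + TRI_POST_S) * fs)
    t_ms = np.arange(n) * dt_ms
    on_ms = TRI_PRE_S * 1000.0
    peak_pa = 1.5 * cell["rheobase"]

    i_stim = np.zeros(n)
    rise = (t_ms >= on_ms) & (t_ms < on_ms + 1.5)
    decay = (t_ms >= on_ms + 1.5) & (t_ms < on_ms + 5.0)
    i_stim[rise] = peak_pa * (t_ms[rise] - on_ms) / 1.5
    i_stim[decay] = peak_pa * (1.0 - (t_ms[decay] - on_ms - 1.5) / 3.5)

    vr, r_in, tau = cell["v_rest"], cell["r_in"], cell["tau_m"]
    v = np.empty(n)
    v[0] = vr
    alpha = dt_ms / tau
    drive = vr + i_stim * r_in * 1e-3
    for i in range(1, n):  # exact enough exponential-Euler passive response
        v[i] = v[i - 1] + alpha * (drive[i - 1] - v[i - 1])
    np.minimum(v, cell["ap_threshold"] - 1.0, out=v)

    if with_ap:
        _insert_aps(v, t_ms, np.array([on_ms + cell["ap_peak_latency"]]),
                    vr, cell["ap_amplitude"], cell["ap_halfwidth"])
    if rng is not None and p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, n)
    return Trace(
        signal=v, sampling_rate=fs, protocol="triangular", units="mV",
        params={"peak_pa": peak_pa, "onset_s": TRI_PRE_S,
                "offset_s": TRI_PRE_S + TRI_RISE_S + TRI_DECAY_S},
    )


def _vc_step_trace(config: GeneratorConfig, p: EphysClassParams, cell: dict,
                   rng: np.random.Generator) -> Trace:
    fs = config.fs_voltage_clamp
    n_pre = int(VC_PRE_S * fs)
    n_step = int(VC_DUR_S * fs)
    n_post = int(VC_POST_S * fs)
    r_s, r_in, c_m = cell["r_s"], cell["r_in"], cell["c_m"]
    i_peak = VC_DELTA_MV / r_s * 1000.0  # pA
    i_ss = VC_DELTA_MV / (r_s + r_in) * 1000.0
    tau_c = (r_s * r_in / (r_s + r_in)) * c_m / 1000.0  # ms

    t_ms = np.arange(n_step) / fs * 1000.0
    i_step = i_ss + (i_peak - i_ss) * np.exp(-t_ms / tau_c)
    t_post = np.arange(n_post) / fs * 1000.0
    i_post = -i_peak * np.exp(-t_post / tau_c)
    i = np.concatenate([np.zeros(n_pre), i_step, i_post])
    if p.noise_sd_pa > 0:
        i = i + rng.normal(0.0, p.noise_sd_pa, i.size)
    return Trace(
        signal=i, sampling_rate=fs, protocol="vc_step", units="pA",
        params={"delta_mv": VC_DELTA_MV, "v_hold_mv": VC_HOLD_MV,
                "onset_s": VC_PRE_S, "offset_s": VC_PRE_S + VC_DUR_S},
    )


def _rest_trace(config: GeneratorConfig, p: EphysClassParams, cell: dict,
                rng: np.random.Generator) -> Trace:
    n = int(config.rest_duration_s * config.fs_rest)
    v = np.full(n, cell["v_rest"])
    if p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, n)
    return Trace(signal=v, sampling_rate=config.fs_rest, protocol="rest", units="mV")


def _calibrate_measured_threshold(config: GeneratorConfig, cell: dict) -> float:
    """Threshold the dV/dt rule reads from the clean triangular waveform."""
    from .. import ephys  # deferred: ephys is generator-independent

    p = config.ephys_params[cell["cell_class"]]
    trace = _triangular_trace(config, p, cell, rng=None, with_ap=True)
    aps = ephys.detect_aps(trace)
    return aps[0].threshold_v if aps else np.nan


# ---------------------------------------------------------------------------
# public generation API

CC_PROTOCOLS = ("rest", "steps", "triangular", "vc_step")


def generate_traces(
    config: GeneratorConfig,
    truth: GroundTruth,
    cells: list[str] | None = None,
    protocols: tuple[str, ...] = CC_PROTOCOLS,
) -> dict[str, TraceSet]:
    """Synthesize recordings for the requested cells (default: all neurons).

    Negative controls have no recordings and are rejected if requested.
    Randomness is drawn from per-cell streams derived from ``config.seed``,
    so any subset of cells reproduces byte-identically.
    """
    if config.fs_current_clamp < 2000.0 / min(
        p.ap_halfwidth_ms for p in config.ephys_params.values()
    ):
        raise ValueError("sampling rate below twice the AP template bandwidth")
    index = {cid: i for i, cid in enumerate(truth.cells["cell_id"])}
    if cells is None:
        cells = [
            cid for cid, cls in zip(truth.cells["cell_id"], truth.cells["cell_class"])
            if cls != "NegControl"
        ]
    out = {}
    for cid in cells:
        row = truth.cells.iloc[index[cid]]
        if row["cell_class"] == "NegControl":
            raise ValueError(f"{cid} is a negative control; no traces exist")
        out[cid] = _traceset_for_cell(config, row.to_dict(), index[cid], protocols)
    return out


def _traceset_for_cell(config: GeneratorConfig, cell: dict, cell_index: int,
                       protocols: tuple[str, ...]) -> TraceSet:
    p: EphysClassParams = config.ephys_params[cell["cell_class"]]
    rng = _cell_rng(config, stream=1, index=cell_index)
    ts = TraceSet(cell_id=cell["cell_id"])
    # draw in fixed protocol order so subsets stay deterministic
    rest = _rest_trace(config, p, cell, rng)
    steps = [_step_trace(config, p, cell, a, rng) for a in STEP_AMPLITUDES_PA]
    tris = [_triangular_trace(config, p, cell, rng) for _ in range(10)]
    vc = _vc_step_trace(config, p, cell, rng)
    if "rest" in protocols:
        ts.traces["rest"] = rest
    if "steps" in protocols:
        for amp, tr in zip(STEP_AMPLITUDES_PA, steps):
            ts.traces[f"step_{int(amp)}"] = tr
    if "triangular" in protocols:
        for i, tr in enumerate(tris):
            ts.traces[f"triangular_{i}"] = tr
    if "vc_step" in protocols:
        ts.traces["vc_step"] = vc
    return ts


def generate_pscs(
    config: GeneratorConfig,
    truth: GroundTruth,
    cells: list[str] | None = None,
) -> dict[str, Trace]:
    """Synthesize the 60-s spontaneous-PSC recording per neuron.

    Events are Poisson-timed biexponential currents: EPSCs inward
    (negative), IPSCs outward (positive).  Planted event times and
    amplitudes are recorded in ``truth.psc_events`` for recall tests.
    """
    index = {cid: i for i, cid in enumerate(truth.cells["cell_id"])}
    if cells is None:
        cells = [
            cid for cid, cls in zip(truth.cells["cell_id"], truth.cells["cell_class"])
            if cls != "NegControl"
        ]
    fs = config.fs_psc
    n = int(config.psc_duration_s * fs)
    out = {}
    for cid in cells:
        cell = truth.cells.iloc[index[cid]].to_dict()
        if cell["cell_class"] == "NegControl":
            raise ValueError(f"{cid} is a negative control; no traces exist")
        p: EphysClassParams = config.ephys_params[cell["cell_class"]]
        rng = _cell_rng(config, stream=2, index=index[cid])
        sig = np.zeros(n)
        events = []
        for polarity, kin, sign in (("inward", p.epsc, -1.0), ("outward", p.ipsc, 1.0)):
            if kin.rate_hz <= 0:
                continue
            n_ev = rng.poisson(kin.rate_hz * config.psc_duration_s)
            t_ev = np.sort(rng.uniform(0.0, config.psc_duration_s - 0.1, n_ev))
            amps = kin.amp_pa * np.clip(1.0 + kin.amp_cv * rng.normal(size=n_ev), 0.2, None)
            _add_psc_events(sig, fs, t_ev, amps, kin.rise_ms, kin.decay_ms, sign)
            events.append(pd.DataFrame(
                {"polarity": polarity, "time_s": t_ev, "amplitude_pa": amps}
            ))
        if p.noise_sd_pa > 0:
            sig = sig + rng.normal(0.0, p.noise_sd_pa, n)
        truth.psc_events[cid] = (
            pd.concat(events, ignore_index=True) if events
            else pd.DataFrame(columns=["polarity", "time_s", "amplitude_pa"])
        )
        out[cid] = Trace(
            signal=sig, sampling_rate=fs, protocol="psc", units="pA",
            params={"v_hold_mv": VC_HOLD_MV},
        )
    return out


def _add_psc_events(sig: np.ndarray, fs: float, times_s: np.ndarray,
                    amps: np.ndarray, rise_ms: float, decay_ms: float,
                    sign: float) -> None:
    tau_r, tau_d = rise_ms / 1000.0, decay_ms / 1000.0
    t_peak = np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    n_win = int(8 * tau_d * fs) + 1
    t_win = np.arange(n_win) / fs
    kernel = (np.exp(-t_win / tau_d) - np.exp(-t_win / tau_r)) / peak
    for t0, a in zip(times_s, amps):
        i0 = int(round(t0 * fs))
        hi = min(i0 + n_win, sig.size)
        sig[i0:hi] += sign * a * kernel[: hi - i0]


def iter_tracesets(config: GeneratorConfig, truth: GroundTruth,
                   include_psc: bool = True,
                   protocols: tuple[str, ...] = CC_PROTOCOLS):
    """Yield (cell_id, TraceSet) per neuron without holding all in memory."""
    neurons = [
        cid for cid, cls in zip(truth.cells["cell_id"], truth.cells["cell_class"])
        if cls != "NegControl"
    ]
    for cid in neurons:
        ts = generate_traces(config, truth, cells=[cid], protocols=protocols)[cid]
        if include_psc:
            ts.traces["psc"] = generate_pscs(config, truth, cells=[cid])[cid]
        yield cid, ts
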