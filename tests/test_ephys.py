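"""Feature extraction: closed-form checks, recovery from generated traces,
and determinism."""

import numpy as np
import pytest

from lsopatch.datatypes import Trace
from lsopatch import ephys
from lsopatch.synthdata.traces import _add_psc_events


def _trace(signal, fs=50_000.0, units="mV", protocol="rest", **params):
    return Trace(signal=np.asarray(signal, dtype=float), sampling_rate=fs,
                 protocol=protocol, units=units, params=params)


class TestVrest:
    def test_constant_segment(self):
        tr = _trace(np.full(10_000, -64.0), fs=5000.0)
        assert ephys.measure_vrest(tr) == -64.0

    def test_noisy_segment_within_standard_error(self):
        rng = np.random.default_rng(0)
        n = 150_000  # 30 s at 5 kHz
        tr = _trace(-64.0 + rng.normal(0, 0.5, n), fs=5000.0)
        se = 0.5 / np.sqrt(n)
        assert abs(ephys.measure_vrest(tr) + 64.0) < 3 * se

    def test_current_trace_rejected(self):
        tr = _trace(np.zeros(10_000), units="pA", fs=5000.0)
        with pytest.raises(TypeError):
            ephys.measure_vrest(tr)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            ephys.measure_vrest(_trace(np.zeros(100), fs=5000.0))


class TestTauFit:
    def test_pure_rc_recovered_to_one_percent(self):
        fs, tau = 50_000.0, 1.06
        t_ms = np.arange(int(0.2 * fs)) / fs * 1000.0
        step = -64.0 - 19.2 * (1 - np.exp(-t_ms / tau))
        sig = np.concatenate([np.full(int(0.05 * fs), -64.0), step])
        tr = _trace(sig, protocol="current_step", onset_s=0.05, offset_s=0.25,
                    amplitude_pa=-200.0)
        assert ephys.fit_membrane_time_constant(tr) == pytest.approx(tau, rel=0.01)

    def test_sag_contaminated_fit_within_ten_percent(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        for _, row in truth.cells[truth.cells["sag_amp"] > 0].iterrows():
            tau = ephys.fit_membrane_time_constant(traces[row["cell_id"]]["step_-200"])
            assert tau == pytest.approx(row["tau_m"], rel=0.10)

    def test_flat_trace_flagged_missing(self):
        tr = _trace(np.full(20_000, -64.0), protocol="current_step",
                    onset_s=0.05, offset_s=0.25, amplitude_pa=0.0)
        assert np.isnan(ephys.fit_membrane_time_constant(tr))


class TestRinRs:
    def test_ohms_law_with_negligible_transient(self):
        fs = 20_000.0
        n_pre, n_step = int(0.02 * fs), int(0.2 * fs)
        sig = np.concatenate([np.zeros(n_pre), np.full(n_step, -50.0)])
        sig[n_pre] = -2500.0  # single-sample transient (R_s = 2 MOhm)
        tr = _trace(sig, fs=fs, units="pA", protocol="vc_step",
                    delta_mv=-5.0, onset_s=0.02, offset_s=0.22)
        r_in, r_s = ephys.measure_rin_rs(tr)
        assert r_s == pytest.approx(2.0, rel=1e-6)
        assert r_in == pytest.approx(5.0 / 50.0 * 1000.0 - 2.0, rel=1e-3)

    def test_generated_vc_step_recovery(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        for _, row in truth.cells.iterrows():
            r_in, r_s = ephys.measure_rin_rs(traces[row["cell_id"]]["vc_step"])
            assert r_in == pytest.approx(row["r_in"], rel=0.01)
            assert r_s == pytest.approx(row["r_s"], rel=0.02)

    def test_no_transient_flagged(self):
        fs = 20_000.0
        sig = np.concatenate([np.zeros(int(0.02 * fs)), np.full(int(0.2 * fs), -50.0)])
        tr = _trace(sig, fs=fs, units="pA", protocol="vc_step",
                    delta_mv=-5.0, onset_s=0.02, offset_s=0.22)
        r_in, r_s = ephys.measure_rin_rs(tr)
        assert np.isnan(r_in)  # R_s absorbed the whole resistance


class TestDeriveCm:
    @pytest.mark.parametrize(
        "tau,r_in,expected",
        [(1.06, 96.0, 11.04), (1.0, 1000.0, 1.0)],
    )
    def test_values(self, tau, r_in, expected):
        assert ephys.derive_cm(tau, r_in) == pytest.approx(expected, rel=0.01)

    def test_missing_propagates(self):
        assert np.isnan(ephys.derive_cm(np.nan, 96.0))
        assert np.isnan(ephys.derive_cm(1.0, np.nan))


class TestDetectAps:
    def test_subthreshold_trace_empty(self):
        tr = _trace(np.full(5000, -64.0), onset_s=0.01)
        assert ephys.detect_aps(tr) == []

    def test_triangular_spike_halfwidth_is_half_base(self):
        """An isoceles-triangle spike of base b has width b/2 at 50% of the
        peak amplitude measured from baseline."""
        fs = 50_000.0
        base_ms = 2.0
        n = int(0.02 * fs)
        sig = np.full(n, -64.0)
        t_ms = np.arange(n) / fs * 1000.0
        apex = 10.0
        rise = (t_ms >= apex - base_ms / 2) & (t_ms <= apex)
        fall = (t_ms > apex) & (t_ms <= apex + base_ms / 2)
        amp = 70.0
        sig[rise] = -64.0 + amp * (t_ms[rise] - (apex - base_ms / 2)) / (base_ms / 2)
        sig[fall] = -64.0 + amp * ((apex + base_ms / 2) - t_ms[fall]) / (base_ms / 2)
        aps = ephys.detect_aps(_trace(sig, onset_s=0.002))
        assert len(aps) == 1
        assert aps[0].halfwidth == pytest.approx(base_ms / 2, rel=0.02)
        assert aps[0].amplitude == pytest.approx(amp, rel=0.01)

    def test_template_recovery(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        for _, row in truth.cells.iterrows():
            tr = traces[row["cell_id"]]["triangular_0"]
            aps = ephys.detect_aps(tr)
            assert len(aps) == 1
            assert aps[0].amplitude == pytest.approx(row["ap_amplitude"], rel=0.01)
            assert aps[0].halfwidth == pytest.approx(row["ap_halfwidth"], rel=0.05)
            assert aps[0].threshold_v == pytest.approx(
                row["ap_threshold_measured"], abs=1.0
            )


class TestRheobaseAndClassification:
    def test_rheobase_examples(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        for _, row in truth.cells.iterrows():
            steps = traces[row["cell_id"]].step_traces()
            rheo = ephys.approximate_rheobase(steps)
            assert 0 <= rheo - row["rheobase"] < 50

    def test_no_aps_gives_missing(self):
        steps = [
            _trace(np.full(5000, -64.0), protocol="current_step",
                   amplitude_pa=a, onset_s=0.01, offset_s=0.05)
            for a in (-50.0, 50.0, 100.0)
        ]
        assert np.isnan(ephys.approximate_rheobase(steps))
        cls, lat = ephys.classify_firing_pattern(steps, np.nan)
        assert cls is None and np.isnan(lat)

    def test_unordered_family_rejected(self):
        steps = [
            _trace(np.zeros(100), protocol="current_step", amplitude_pa=a,
                   onset_s=0.0005, offset_s=0.001)
            for a in (100.0, 50.0)
        ]
        with pytest.raises(ValueError):
            ephys.approximate_rheobase(steps)

    def test_noiseless_classification_perfect(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        for _, row in truth.cells.iterrows():
            steps = traces[row["cell_id"]].step_traces()
            rheo = ephys.approximate_rheobase(steps)
            cls, lat = ephys.classify_firing_pattern(steps, rheo)
            assert cls == row["cell_class"]
            assert lat == pytest.approx(row["first_ap_latency"], abs=0.2)


class TestSag:
    def test_peak_minus_steady_state(self):
        fs = 50_000.0
        n_pre, n_step, n_post = int(0.05 * fs), int(0.2 * fs), int(0.05 * fs)
        step = np.full(n_step, -80.0)
        step[: int(0.01 * fs)] = -90.0  # early hyperpolarized peak
        sig = np.concatenate([np.full(n_pre, -64.0), step, np.full(n_post, -64.0)])
        sag, _ = ephys.measure_sag(_trace(sig, onset_s=0.05, offset_s=0.25,
                                          protocol="current_step", amplitude_pa=-200.0))
        assert sag == pytest.approx(10.0, rel=0.02)

    def test_pure_rc_has_zero_sag_and_no_rebound(self):
        fs, tau = 50_000.0, 1.5
        t_ms = np.arange(int(0.2 * fs)) / fs * 1000.0
        step = -64.0 - 20.0 * (1 - np.exp(-t_ms / tau))
        t_post = np.arange(int(0.1 * fs)) / fs * 1000.0
        post = -64.0 + (step[-1] + 64.0) * np.exp(-t_post / tau)
        sig = np.concatenate([np.full(int(0.05 * fs), -64.0), step, post])
        sag, rebound = ephys.measure_sag(
            _trace(sig, onset_s=0.05, offset_s=0.25, protocol="current_step",
                   amplitude_pa=-200.0))
        assert sag == pytest.approx(0.0, abs=0.01)
        assert not rebound

    def test_generator_sag_recovered(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        plso = truth.cells[truth.cells["sag_amp"] > 0]
        for _, row in plso.iterrows():
            sag, rebound = ephys.measure_sag(traces[row["cell_id"]]["step_-200"])
            assert sag == pytest.approx(row["sag_amp"], rel=0.05)
            assert rebound


class TestDetectPscs:
    def test_monoexponential_tail_decay(self):
        """decay_100_37 of an event with negligible rise equals tau_decay."""
        fs = 20_000.0
        n = int(20 * fs)
        rng = np.random.default_rng(1)
        times = np.arange(0.5, 19.5, 0.5)
        sig = np.zeros(n)
        _add_psc_events(sig, fs, times, np.full(times.size, 60.0), 0.01, 5.0, 1.0)
        sig += rng.normal(0, 1.0, n)
        _, summ = ephys.detect_pscs(_trace(sig, fs=fs, units="pA", protocol="psc"))
        assert summ["outward"].decay_100_37 == pytest.approx(5.0, rel=0.02)

    def test_outward_only_train(self):
        fs = 20_000.0
        sig = np.zeros(int(30 * fs))
        times = np.arange(0.5, 29.5, 0.4)
        _add_psc_events(sig, fs, times, np.full(times.size, 50.0), 0.3, 3.0, 1.0)
        sig += np.random.default_rng(2).normal(0, 3.0, sig.size)
        events, summ = ephys.detect_pscs(_trace(sig, fs=fs, units="pA", protocol="psc"))
        assert summ["inward"].n_events == 0
        assert summ["outward"].n_events > 0
        assert all(e.polarity == "outward" for e in events)

    def test_planted_event_recall_and_amplitude(self):
        fs = 20_000.0
        n = int(60 * fs)
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 59.9, 120))  # 2 Hz
        sig = np.zeros(n)
        _add_psc_events(sig, fs, times, np.full(times.size, 50.0), 0.3, 5.0, -1.0)
        sig += rng.normal(0, 3.0, n)
        events, summ = ephys.detect_pscs(_trace(sig, fs=fs, units="pA", protocol="psc"))
        det = np.array([e.onset_time for e in events if e.polarity == "inward"])
        recall = np.mean([np.abs(det - t).min() < 0.005 for t in times])
        assert recall >= 0.95
        mean_amp = np.mean([e.amplitude for e in events if e.polarity == "inward"])
        assert mean_amp == pytest.approx(50.0, rel=0.10)

    def test_sparse_polarity_flagged_low_confidence(self):
        fs = 20_000.0
        sig = np.zeros(int(10 * fs))
        _add_psc_events(sig, fs, np.array([2.0, 5.0]), np.array([80.0, 80.0]),
                        0.3, 5.0, 1.0)
        sig += np.random.default_rng(3).normal(0, 3.0, sig.size)
        _, summ = ephys.detect_pscs(_trace(sig, fs=fs, units="pA", protocol="psc"))
        assert summ["outward"].low_confidence


class TestFeatureVector:
    def test_complete_traceset_populates_all_fields(self, noiseless_cells):
        from lsopatch.synthdata import generate_pscs

        cfg, truth, traces = noiseless_cells
        cid = truth.cells["cell_id"].iloc[0]
        ts = traces[cid]
        # noiseless PSC traces break MAD-based thresholds; use noisy ones
        ts.traces["psc"] = _noisy_psc(cfg, truth, cid)
        f = ephys.extract_feature_vector(ts)
        for name in ephys.FEATURES_16:
            assert np.isfinite(getattr(f, name)), name
        assert f.firing_class == "Onset"

    def test_missing_psc_protocol_flags_psc_features(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        cid = truth.cells["cell_id"].iloc[1]
        f = ephys.extract_feature_vector(traces[cid])
        for name in ("sepsc_amp", "sepsc_rise", "sepsc_decay",
                     "sipsc_amp", "sipsc_rise", "sipsc_decay"):
            assert np.isnan(getattr(f, name))

    def test_extraction_is_deterministic(self, noiseless_cells):
        cfg, truth, traces = noiseless_cells
        cid = truth.cells["cell_id"].iloc[0]
        f1 = ephys.extract_feature_vector(traces[cid])
        f2 = ephys.extract_feature_vector(traces[cid])
        assert f1 == f2


def _noisy_psc(cfg, truth, cid):
    from dataclasses import replace as dc_replace

    from lsopatch.synthdata import generate_pscs

    noisy = dc_replace(
        cfg,
        ephys_params={
            k: dc_replace(v, noise_sd_pa=3.0) for k, v in cfg.ephys_params.items()
        },
    )
    return generate_pscs(noisy, truth, cells=[cid])[cid]
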