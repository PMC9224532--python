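"""Patch-clamp feature extraction on constructed and generated traces."""

import numpy as np
import pytest

from csdskit.ephys import (
    EPSCSeries,
    Sweep,
    SweepSet,
    analyze_ltd,
    build_curves,
    detect_spikes,
    measure_passive,
    measure_spike_properties,
)

FS = 20_000.0
DT_MS = 1000.0 / FS


def stamp_ap(trace, t_onset_s, threshold=-40.0, peak=30.0,
             rise_ms=1.5, decay_ms=3.0, foot=False):
    """Write a triangular action potential into a trace, in place.

    With ``foot`` a slow (15 mV/ms, below the detection criterion) ramp
    from the baseline up to threshold precedes the fast upstroke, so the
    dV/dt criterion crossing falls exactly on the threshold sample.
    """
    i0 = int(round(t_onset_s * FS))
    if foot:
        base = trace[i0 - 1]
        n_foot = int(np.ceil((threshold - base) / (15.0 * DT_MS)))
        trace[i0 - n_foot:i0] = np.linspace(base, threshold, n_foot,
                                            endpoint=False)
    n_rise = int(round(rise_ms / DT_MS))
    n_decay = int(round(decay_ms / DT_MS))
    ap = np.concatenate([
        np.linspace(threshold, peak, n_rise + 1),
        np.linspace(peak, threshold, n_decay + 1)[1:],
    ])
    end = min(i0 + ap.size, trace.size)
    trace[i0:end] = ap[: end - i0]
    return trace


def rc_sweep(current_pA, rmp=-80.0, rin=150.0, tau_ms=15.0,
             pre_s=0.1, step_s=0.5, post_s=0.1):
    """Analytic RC (no-spike) response to a current step."""
    n = int(round((pre_s + step_s + post_s) * FS))
    t = np.arange(n) / FS
    v = np.full(n, rmp)
    v_inf = rmp + rin * current_pA * 1e-3
    on, off = pre_s, pre_s + step_s
    during = (t >= on) & (t < off)
    v[during] = v_inf + (rmp - v_inf) * np.exp(-(t[during] - on) / (tau_ms / 1000))
    v_off = v_inf + (rmp - v_inf) * np.exp(-step_s / (tau_ms / 1000))
    after = t >= off
    v[after] = rmp + (v_off - rmp) * np.exp(-(t[after] - off) / (tau_ms / 1000))
    return Sweep(current_pA=current_pA, step_onset_s=on, step_offset_s=off,
                 voltage_mV=v)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        v = np.full(int(FS), -80.0)
        assert detect_spikes(v, FS).size == 0

    def test_five_stamped_aps_found_at_stamp_times(self):
        v = np.full(int(FS), -80.0)
        times = [0.1, 0.25, 0.4, 0.55, 0.7]
        for t0 in times:
            stamp_ap(v, t0)
        onsets = detect_spikes(v, FS) / FS
        assert onsets.size == 5
        assert np.allclose(onsets, times, atol=0.25e-3)

    def test_refractory_merges_aps_one_ms_apart(self):
        v = np.full(int(FS), -80.0)
        stamp_ap(v, 0.100, rise_ms=0.3, decay_ms=0.5)
        stamp_ap(v, 0.101, rise_ms=0.3, decay_ms=0.5)
        assert detect_spikes(v, FS).size == 1

    def test_subthreshold_blip_is_rejected_by_overshoot_check(self):
        v = np.full(int(FS), -80.0)
        stamp_ap(v, 0.2, threshold=-70.0, peak=-30.0)  # never above 0 mV
        assert detect_spikes(v, FS).size == 0

    def test_bad_sampling_rate(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(100), 0.0)


class TestMeasurePassive:
    def _sweepset(self, rin=150.0, tau_ms=15.0):
        currents = [-100.0, -60.0, -20.0, 0.0, 20.0]
        return SweepSet(
            neuron_id="rc1",
            sampling_rate=FS,
            sweeps=[rc_sweep(i, rin=rin, tau_ms=tau_ms) for i in currents],
        )

    def test_capacitance_identity_on_noiseless_rc(self):
        p = measure_passive(self._sweepset(rin=150.0, tau_ms=15.0))
        assert p.capacitance_pF == pytest.approx(100.0, rel=0.02)
        assert p.input_resistance_MOhm == pytest.approx(150.0, rel=0.01)
        assert p.membrane_tau_ms == pytest.approx(15.0, rel=0.01)

    def test_rmp_read_from_zero_current_sweep(self):
        p = measure_passive(self._sweepset())
        assert p.rmp_mV == pytest.approx(-80.0, abs=1e-9)

    def test_no_spiking_sweep_flags_absent_rheobase(self):
        p = measure_passive(self._sweepset())
        assert p.rheobase_pA is None

    def test_junction_correction_shifts_rmp(self):
        plain = measure_passive(self._sweepset())
        corr = measure_passive(self._sweepset(), junction_correction=True)
        assert corr.rmp_mV == pytest.approx(plain.rmp_mV - 15.4)


class TestSpikeProperties:
    def _spiking_set(self, **ap_kw):
        sub = rc_sweep(-50.0)
        sup = rc_sweep(0.0)
        sup.current_pA = 120.0  # labelled suprathreshold step
        stamp_ap(sup.voltage_mV, 0.35, foot=True, **ap_kw)
        return SweepSet(neuron_id="s1", sampling_rate=FS, sweeps=[sub, sup])

    def test_amplitude_is_peak_minus_threshold(self):
        props = measure_spike_properties(
            self._spiking_set(threshold=-40.0, peak=30.0)
        )
        assert props.ap_amplitude_mV == pytest.approx(70.0, abs=0.5)
        assert props.ap_threshold_mV == pytest.approx(-40.0, abs=0.5)

    def test_symmetric_ap_has_equal_rise_and_decay(self):
        props = measure_spike_properties(
            self._spiking_set(rise_ms=2.0, decay_ms=2.0)
        )
        assert props.rise_kinetics_mV_per_ms == pytest.approx(
            props.decay_kinetics_mV_per_ms, rel=0.01
        )

    def test_delay_measured_from_step_onset(self):
        props = measure_spike_properties(self._spiking_set())
        assert props.delay_to_first_spike_ms == pytest.approx(250.0, abs=0.3)

    def test_no_spikes_anywhere_is_an_error(self):
        ss = SweepSet(neuron_id="q", sampling_rate=FS,
                      sweeps=[rc_sweep(-50.0), rc_sweep(0.0)])
        with pytest.raises(ValueError, match="no spikes"):
            measure_spike_properties(ss)


class TestCurves:
    def test_iv_slope_recovers_input_resistance(self):
        ss = SweepSet(
            neuron_id="rc2", sampling_rate=FS,
            sweeps=[rc_sweep(i, rin=180.0) for i in
                    (-100.0, -50.0, 0.0, 50.0)],
        )
        curves = build_curves(ss)
        slope = np.polyfit(curves.iv["current_pA"],
                           curves.iv["steady_state_mV"], 1)[0]
        assert slope * 1000 == pytest.approx(180.0, rel=0.01)
        assert curves.if_curve.empty

    def test_iv_excludes_every_spiking_sweep(self):
        sweeps = [rc_sweep(i) for i in (-50.0, 0.0, 50.0, 100.0)]
        stamp_ap(sweeps[3].voltage_mV, 0.3)
        ss = SweepSet(neuron_id="mix", sampling_rate=FS, sweeps=sweeps)
        curves = build_curves(ss)
        assert 100.0 not in curves.iv["current_pA"].to_numpy()
        assert curves.if_curve["current_pA"].tolist() == [100.0]

    def test_if_curve_reproduces_constructed_spike_counts(self):
        # counts follow floor((I - rheobase)/20) + 1 by construction
        rheo, sweeps = 100.0, []
        for current in (80.0, 100.0, 120.0, 140.0, 160.0):
            s = rc_sweep(0.0)
            s.current_pA = current
            if current >= rheo:
                n = int((current - rheo) // 20) + 1
                for k in range(n):
                    stamp_ap(s.voltage_mV, 0.15 + 0.02 * k,
                             rise_ms=0.5, decay_ms=1.0)
            sweeps.append(s)
        curves = build_curves(
            SweepSet(neuron_id="f", sampling_rate=FS, sweeps=sweeps),
            relative_to_rheobase=True,
        )
        got = dict(zip(curves.if_curve["current_pA"],
                       curves.if_curve["n_spikes"]))
        assert got == {100.0: 1, 120.0: 2, 140.0: 3, 160.0: 4}
        assert curves.if_curve["current_rel_pA"].tolist() == [0, 20, 40, 60]


class TestLTD:
    def _series(self, factor=0.7, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.concatenate([np.arange(0, 600, 10.0),
                            np.arange(1200, 3600, 10.0)])
        mean = np.where(t < 600, 200.0, 200.0 * factor)
        amp = mean * (1 + rng.normal(0, noise, t.size))
        return EPSCSeries(neuron_id="n1", times_s=t, amplitudes_pA=amp,
                          protocol_onset_s=600.0, protocol_end_s=1200.0)

    def test_normalized_baseline_mean_is_one(self):
        res = analyze_ltd(self._series(noise=0.1, seed=3))
        base = res.normalized.query("phase == 'baseline'")["amplitude_norm"]
        assert base.mean() == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_depression_recovered_exactly(self):
        res = analyze_ltd(self._series(factor=0.7))
        assert res.late_mean == pytest.approx(0.7, abs=1e-9)
        assert res.early_mean == pytest.approx(0.7, abs=1e-9)

    def test_no_depression_keeps_post_at_baseline(self):
        res = analyze_ltd(self._series(factor=1.0))
        assert res.late_mean == pytest.approx(1.0, abs=1e-9)

    def test_noisy_late_mean_within_clt_bound(self):
        res = analyze_ltd(self._series(factor=0.7, noise=0.1, seed=5))
        assert abs(res.late_mean - 0.7) <= 3 * (0.1 * 0.7) / np.sqrt(60)

    def test_short_baseline_is_an_error(self):
        s = self._series()
        s.times_s = s.times_s[55:]
        s.amplitudes_pA = s.amplitudes_pA[55:]
        with pytest.raises(ValueError, match="baseline"):
            analyze_ltd(s)
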