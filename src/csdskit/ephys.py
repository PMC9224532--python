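"""Whole-cell patch-clamp feature extraction.

Works on current-clamp step families (one :class:`SweepSet` per neuron,
default protocol -100 to +300 pA in 10 pA increments, 500 ms steps,
sampled at 20 kHz) and on evoked-EPSC amplitude series recorded at 0.1 Hz
around a 10 Hz / 10 min low-frequency stimulation protocol that induces
long-term depression (LTD).

Extracted per neuron: passive membrane properties (resting membrane
potential, input resistance, membrane time constant, capacitance,
rheobase), action-potential shape properties measured on the first spike
of the rheobase sweep, I/V and I-F curves, and baseline-normalized LTD
magnitudes.  All extraction is deterministic given a trace.

Conventions that are choices rather than physics: spike onset is the
first sample where dV/dt reaches 20 mV/ms and the voltage overshoots
0 mV within 2 ms (with a 2 ms refractory lockout); AP duration is the
base width at the threshold voltage level; capacitance is tau/Rin.  The
+15.4 mV liquid-junction potential is not subtracted unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Sweep",
    "SweepSet",
    "PassiveProperties",
    "SpikeProperties",
    "EphysCurves",
    "EPSCSeries",
    "LTDResult",
    "detect_spikes",
    "measure_passive",
    "measure_spike_properties",
    "build_curves",
    "analyze_ltd",
    "JUNCTION_POTENTIAL_MV",
]

JUNCTION_POTENTIAL_MV = 15.4

# spike-detection defaults; the confirmation window is sized for the
# slow AP upstrokes recorded in these cells (rise kinetics ~27-35 mV/ms)
DVDT_THRESHOLD_MV_PER_MS = 20.0
OVERSHOOT_MV = 0.0
CONFIRM_WINDOW_MS = 4.0
REFRACTORY_MS = 2.0


@dataclass
class Sweep:
    """One current-clamp step: injected current and the voltage response."""

    current_pA: float
    step_onset_s: float
    step_offset_s: float
    voltage_mV: np.ndarray


@dataclass
class SweepSet:
    """A neuron's family of current steps, shared timing and sampling."""

    neuron_id: str
    sampling_rate: float = 20_000.0
    sweeps: list[Sweep] = field(default_factory=list)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        currents = [s.current_pA for s in self.sweeps]
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise ValueError("sweep currents must be strictly increasing")


@dataclass
class PassiveProperties:
    rmp_mV: float
    input_resistance_MOhm: float
    membrane_tau_ms: float
    capacitance_pF: float
    rheobase_pA: float | None  # None when no sweep spiked


@dataclass
class SpikeProperties:
    ap_threshold_mV: float
    ap_amplitude_mV: float
    ap_duration_ms: float
    delay_to_first_spike_ms: float
    rise_kinetics_mV_per_ms: float
    decay_kinetics_mV_per_ms: float


@dataclass
class EphysCurves:
    """I/V over spike-free sweeps and I-F over spiking sweeps."""

    iv: pd.DataFrame  # current_pA, steady_state_mV
    if_curve: pd.DataFrame  # current_pA, n_spikes (+ current_rel_pA if asked)


def detect_spikes(
    trace_mV,
    sampling_rate: float,
    dvdt_threshold: float = DVDT_THRESHOLD_MV_PER_MS,
    overshoot_mV: float = OVERSHOOT_MV,
    confirm_window_ms: float = CONFIRM_WINDOW_MS,
    refractory_ms: float = REFRACTORY_MS,
) -> np.ndarray:
    """Return spike-onset sample indices of a voltage trace.

    Onset = first sample where the forward-difference dV/dt reaches
    ``dvdt_threshold`` (mV/ms) and the voltage subsequently exceeds
    ``overshoot_mV`` within ``confirm_window_ms``; detections within
    ``refractory_ms`` of the previous onset are suppressed.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    v = np.asarray(trace_mV, dtype=float)
    dt_ms = 1000.0 / sampling_rate
    if v.size < int(2 * refractory_ms / dt_ms) + 2:
        raise ValueError("trace shorter than two refractory periods")
    dvdt = np.diff(v) / dt_ms
    candidates = np.flatnonzero(dvdt >= dvdt_threshold)
    confirm = max(1, int(round(confirm_window_ms / dt_ms)))
    lockout = max(1, int(round(refractory_ms / dt_ms)))
    onsets: list[int] = []
    last = -lockout - 1
    for i in candidates:
        if i - last <= lockout:
            continue
        if v[i + 1 : i + 1 + confirm].max(initial=-np.inf) > overshoot_mV:
            onsets.append(int(i))
            last = i
    return np.asarray(onsets, dtype=int)


def _step_slices(sweep: Sweep, fs: float) -> tuple[slice, slice, slice]:
    on = int(round(sweep.step_onset_s * fs))
    off = int(round(sweep.step_offset_s * fs))
    return slice(0, on), slice(on, off), slice(off, None)


def _spike_free(ss: SweepSet, **detect_kw) -> list[tuple[Sweep, bool]]:
    return [
        (s, detect_spikes(s.voltage_mV, ss.sampling_rate, **detect_kw).size > 0)
        for s in ss.sweeps
    ]


def measure_passive(
    ss: SweepSet,
    steady_state_window_ms: float = 100.0,
    tau_fit_window_ms: float = 150.0,
    junction_correction: bool = False,
) -> PassiveProperties:
    """Extract passive membrane properties from a sweep family.

    RMP is the mean pre-step voltage of the 0 pA sweep(s); input
    resistance is the least-squares slope of steady-state voltage
    deflection vs injected current over the spike-free sweeps; the
    membrane time constant comes from a mono-exponential fit to the
    charging phase of the largest spike-free hyperpolarizing step; and
    capacitance is tau/Rin (ms/MOhm -> nF, reported in pF).  Rheobase is
    the smallest current with at least one detected spike, ``None`` if
    no sweep spikes.
    """
    fs = ss.sampling_rate
    flags = _spike_free(ss)
    zero = [s for s in ss.sweeps if s.current_pA == 0.0]
    if not zero:
        raise ValueError("need a 0 pA sweep to measure RMP")
    pre, _, _ = _step_slices(zero[0], fs)
    rmp = float(np.mean([s.voltage_mV[pre].mean() for s in zero]))

    nss = max(1, int(round(steady_state_window_ms / 1000.0 * fs)))
    sub = [(s.current_pA, s) for s, spiked in flags if not spiked]
    hyper = [s for i, s in sub if i < 0]
    if len(sub) < 2 or not hyper:
        raise ValueError("need >= 2 subthreshold sweeps incl. hyperpolarizing")
    dI = np.array([i for i, _ in sub])  # pA
    dV = np.array(
        [s.voltage_mV[_step_slices(s, fs)[1]][-nss:].mean()
         - s.voltage_mV[_step_slices(s, fs)[0]].mean()
         for _, s in sub]
    )  # mV
    # slope of mV over pA is GOhm; scale to MOhm
    slope = float(np.polyfit(dI, dV, 1)[0])
    rin = slope * 1000.0
    if rin <= 0:
        raise ValueError("non-positive fitted input resistance")

    fit_sweep = min(hyper, key=lambda s: s.current_pA)
    _, step, _ = _step_slices(fit_sweep, fs)
    nfit = min(int(round(tau_fit_window_ms / 1000.0 * fs)),
               step.stop - step.start)
    seg = fit_sweep.voltage_mV[step.start : step.start + nfit]
    t_ms = np.arange(nfit) / fs * 1000.0
    v0, vss = seg[0], seg[-1]

    def charging(t, v_inf, dv, tau):
        return v_inf + dv * np.exp(-t / tau)

    popt, _ = curve_fit(
        charging, t_ms, seg, p0=(vss, v0 - vss, 15.0),
        maxfev=10_000,
    )
    tau_ms = float(abs(popt[2]))
    cap_pF = tau_ms / rin * 1000.0

    spiking = [s.current_pA for s, spiked in flags if spiked]
    rheobase = min(spiking) if spiking else None

    if junction_correction:
        rmp -= JUNCTION_POTENTIAL_MV
    return PassiveProperties(rmp, rin, tau_ms, cap_pF, rheobase)


def measure_spike_properties(
    ss: SweepSet, junction_correction: bool = False, **detect_kw
) -> SpikeProperties:
    """AP shape properties measured on the first spike at rheobase.

    Threshold is the voltage at the dV/dt-criterion crossing; amplitude
    is peak minus threshold; duration is the width at the threshold
    level (base width); delay is spike onset minus step onset; rise and
    decay kinetics are amplitude over time-to-peak and over
    peak-to-threshold return time respectively.
    """
    fs = ss.sampling_rate
    for sweep in ss.sweeps:
        onsets = detect_spikes(sweep.voltage_mV, fs, **detect_kw)
        if onsets.size:
            break
    else:
        raise ValueError(f"no spikes in any sweep of neuron {ss.neuron_id!r}")
    v = sweep.voltage_mV
    i0 = int(onsets[0])
    thr = float(v[i0])
    horizon = i0 + int(round(0.020 * fs))  # peak must fall within 20 ms
    seg = v[i0 : min(horizon, v.size)]
    ipk = i0 + int(np.argmax(seg))
    peak = float(v[ipk])
    amp = peak - thr
    if amp <= 0:
        raise ValueError("non-positive AP amplitude")
    after = v[ipk:]
    below = np.flatnonzero(after <= thr)
    iret = ipk + (int(below[0]) if below.size else after.size - 1)
    dt_ms = 1000.0 / fs
    t_rise = max(ipk - i0, 1) * dt_ms
    t_decay = max(iret - ipk, 1) * dt_ms
    delay = (i0 / fs - sweep.step_onset_s) * 1000.0
    if junction_correction:
        thr -= JUNCTION_POTENTIAL_MV
    return SpikeProperties(
        ap_threshold_mV=thr,
        ap_amplitude_mV=amp,
        ap_duration_ms=(iret - i0) * dt_ms,
        delay_to_first_spike_ms=delay,
        rise_kinetics_mV_per_ms=amp / t_rise,
        decay_kinetics_mV_per_ms=amp / t_decay,
    )


def build_curves(
    ss: SweepSet,
    steady_state_window_ms: float = 100.0,
    relative_to_rheobase: bool = False,
    **detect_kw,
) -> EphysCurves:
    """I/V (spike-free sweeps) and I-F (spiking sweeps) curves.

    Steady-state voltage is the mean of the last ``steady_state_window_ms``
    of the step.  With ``relative_to_rheobase`` the I-F currents are also
    reported relative to the smallest spiking current.
    """
    fs = ss.sampling_rate
    nss = max(1, int(round(steady_state_window_ms / 1000.0 * fs)))
    iv_rows, if_rows = [], []
    for sweep in ss.sweeps:
        n = detect_spikes(sweep.voltage_mV, fs, **detect_kw).size
        if n == 0:
            vss = sweep.voltage_mV[_step_slices(sweep, fs)[1]][-nss:].mean()
            iv_rows.append((sweep.current_pA, float(vss)))
        else:
            if_rows.append((sweep.current_pA, n))
    iv = pd.DataFrame(iv_rows, columns=["current_pA", "steady_state_mV"])
    if_curve = pd.DataFrame(if_rows, columns=["current_pA", "n_spikes"])
    if relative_to_rheobase and len(if_curve):
        if_curve["current_rel_pA"] = (
            if_curve["current_pA"] - if_curve["current_pA"].min()
        )
    return EphysCurves(iv=iv, if_curve=if_curve)


@dataclass
class EPSCSeries:
    """Evoked-EPSC amplitudes (magnitudes, pA) sampled at 0.1 Hz."""

    neuron_id: str
    times_s: np.ndarray
    amplitudes_pA: np.ndarray
    protocol_onset_s: float
    protocol_end_s: float
    stimulation_intensity: float = 1.0


@dataclass
class LTDResult:
    neuron_id: str
    baseline_mean_pA: float
    normalized: pd.DataFrame  # t_s, amplitude_norm, phase
    early_mean: float
    late_mean: float
    early_window_s: tuple[float, float]
    late_window_s: tuple[float, float]


def analyze_ltd(
    series: EPSCSeries,
    baseline_window_s: float = 600.0,
    early_window_s: tuple[float, float] = (0.0, 600.0),
    late_window_s: tuple[float, float] = (1800.0, 2400.0),
    min_baseline_events: int = 10,
) -> LTDResult:
    """Per-neuron LTD normalization of an evoked-EPSC series.

    Every amplitude is divided by the neuron's own baseline mean (the
    ``baseline_window_s`` preceding protocol onset, 10 min / 60 events
    by default), so the normalized baseline averages exactly 1.  Early
    and late LTD magnitudes are means of the normalized amplitudes over
    windows expressed relative to the end of the induction protocol
    (defaults: 0-10 min and 30-40 min after protocol end).
    """
    t = np.asarray(series.times_s, dtype=float)
    a = np.asarray(series.amplitudes_pA, dtype=float)
    pre = (t < series.protocol_onset_s) & (
        t >= series.protocol_onset_s - baseline_window_s
    )
    if pre.sum() < min_baseline_events:
        raise ValueError(
            f"neuron {series.neuron_id!r}: only {int(pre.sum())} baseline "
            f"events, need >= {min_baseline_events}"
        )
    base = float(a[pre].mean())
    norm = a / base
    rel = t - series.protocol_end_s
    phase = np.where(
        t < series.protocol_onset_s, "baseline",
        np.where(t < series.protocol_end_s, "protocol", "post"),
    )

    def window_mean(win):
        sel = (rel >= win[0]) & (rel < win[1]) & (phase == "post")
        return float(norm[sel].mean()) if sel.any() else float("nan")

    table = pd.DataFrame(
        {"t_s": t, "amplitude_norm": norm, "phase": phase}
    )
    return LTDResult(
        neuron_id=series.neuron_id,
        baseline_mean_pA=base,
        normalized=table,
        early_mean=window_mean(early_window_s),
        late_mean=window_mean(late_window_s),
        early_window_s=tuple(early_window_s),
        late_window_s=tuple(late_window_s),
    )
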