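"""Synthetic diet x stress cohort generator.

Generates every input the analysis pipeline consumes — behavioral test
tables, social-interaction times, current-clamp sweep families, evoked
EPSC series, an 89-gene expression panel and GO-style gene families —
with the statistical structure the analyses assume (group-level effects,
noise, batch structure) and with ground-truth labels so parameter
recovery can be tested end to end.

The design is the 2x2 cohort of the reference experiment: diet in
{control, n3_suppl} x stress in {none, csds}, 7-10 animals per cell.
Per-cell action-potential defaults track the published group means
(e.g. AP amplitude 61 mV control vs 72 mV supplemented); behavioral
defaults are qualitative — stress shrinks exploration, n-3
supplementation enlarges it — because per-group behavioral means are
not published.  Times and distances use Gaussian draws truncated at the
physical bounds of each apparatus; entry and head-dip counts are
Poisson.

Membrane voltage traces come from a leaky integrate-and-fire cell with
exact exponential subthreshold integration and a stylized triangular
action-potential waveform stamped at threshold crossings; the spike
threshold is derived per neuron from (RMP, Rin, tau, rheobase, delay to
first spike) so that the first spiking sweep is exactly the rheobase
step and the first spike at rheobase occurs at the requested delay.

Randomness: one independent RNG stream per data domain (behavior,
ephys, expression, families), each seeded from the master seed by a
fixed offset, so regenerating one domain does not shift the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import EPSCSeries, Sweep, SweepSet
from .expression import ExpressionMatrix
from .enrichment import DEFAULT_GENOME_SIZE, GeneSetCollection

__all__ = [
    "CELLS",
    "GroupDesign",
    "EphysCellParams",
    "ExprSpec",
    "EffectSpec",
    "TruthBundle",
    "default_effects",
    "generate_behavior_cohort",
    "generate_ephys_recordings",
    "generate_expression_dataset",
    "generate_gene_families",
]

DIET_LEVELS = ("control", "n3_suppl")
STRESS_LEVELS = ("none", "csds")
CELLS = tuple((d, s) for d in DIET_LEVELS for s in STRESS_LEVELS)

# fixed per-domain offsets applied to the master seed
_DOMAIN_OFFSETS = {"behavior": 0, "ephys": 1, "expression": 2, "families": 3}

# apparatus durations, seconds
OF_DURATION_S = 600.0
LD_DURATION_S = 480.0
EPM_DURATION_S = 300.0
SI_PHASE_S = 300.0

# the 25 genes reported upregulated on the lipid panel; used as the
# default true-positive set so downstream gene lists look like the assay
UPREGULATED_GENES = (
    "Abhd4", "Abhd6", "Acadl", "Acadvl", "Hadh", "Elovl1", "Elovl5",
    "Ptgs1", "Fasn", "Acat1", "Pcyt1a", "Pcyt1b", "Pcyt2", "Adipor2",
    "Ppard", "Ppargc1a", "Ptger4", "Rxra", "Apoe", "Fads2", "Scd1",
    "Slc25a20", "Slc27a1", "Slc27a3", "Slc27a4",
)


def domain_rng(seed: int, domain: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one data domain."""
    return np.random.default_rng(
        np.random.SeedSequence((seed, _DOMAIN_OFFSETS[domain]))
    )


@dataclass(frozen=True)
class GroupDesign:
    """The 2x2 diet x stress cohort layout."""

    n_per_group: int = 8
    diet_levels: tuple[str, str] = DIET_LEVELS
    stress_levels: tuple[str, str] = STRESS_LEVELS

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.diet_levels) != 2 or len(self.stress_levels) != 2:
            raise ValueError("design must have exactly four cells (2x2)")

    @property
    def cells(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (d, s) for d in self.diet_levels for s in self.stress_levels
        )


@dataclass
class EphysCellParams:
    """Mean and SD of each electrophysiological parameter in one cell.

    Units: RMP mV, Rin MOhm, tau ms, rheobase pA, delay ms, AP amplitude
    mV, AP rise/decay kinetics mV/ms, EPSC baseline pA; the LTD factor is
    the fraction of baseline amplitude retained after induction (1 = no
    depression).
    """

    rmp_mV: tuple[float, float]
    rin_MOhm: tuple[float, float]
    tau_ms: tuple[float, float]
    rheobase_pA: tuple[float, float]
    delay_ms: tuple[float, float]
    ap_amplitude_mV: tuple[float, float]
    ap_rise_mV_per_ms: tuple[float, float]
    ap_decay_mV_per_ms: tuple[float, float]
    epsc_baseline_pA: tuple[float, float]
    ltd_factor: tuple[float, float]

    def __post_init__(self):
        for name in ("rin_MOhm", "tau_ms"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} mean must be positive")
        if not (0.0 < self.ltd_factor[0] <= 1.0):
            raise ValueError("LTD factor must lie in (0, 1]")
        for name, (mean, sd) in asdict(self).items():
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")


@dataclass
class ExprSpec:
    """Structure of the synthetic expression panel."""

    n_genes: int = 89
    n_true_up: int = 25
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    n_batches: int = 2
    batch_offset: float = 1.0  # log2 shift of batch 2 vs batch 1
    baseline_log2_range: tuple[float, float] = (6.0, 12.0)
    housekeeping: str = "Gapdh"
    true_up_genes: tuple[str, ...] = UPREGULATED_GENES

    def __post_init__(self):
        if self.n_true_up > self.n_genes:
            raise ValueError("n_true_up cannot exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class EffectSpec:
    """Per-cell generative targets for every data domain."""

    behavior: dict[tuple[str, str], dict[str, tuple[float, float]]]
    si_ratio: dict[tuple[str, str], tuple[float, float]]
    ephys: dict[tuple[str, str], EphysCellParams]
    expr: ExprSpec = field(default_factory=ExprSpec)
    si_no_target: tuple[float, float] = (60.0, 15.0)  # mean, sd seconds

    def require_cells(self, design: GroupDesign, domain: str) -> None:
        spec = getattr(self, domain)
        missing = [c for c in design.cells if c not in spec]
        if missing:
            raise ValueError(f"{domain} effects missing cells: {missing}")


@dataclass
class TruthBundle:
    """Ground truth of one generated dataset, for recovery tests."""

    animal_cells: dict[str, tuple[str, str]] = field(default_factory=dict)
    gene_flags: dict[str, bool] = field(default_factory=dict)
    neuron_params: dict[str, dict[str, float]] = field(default_factory=dict)
    si_targets: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "animal_cells": {k: list(v) for k, v in self.animal_cells.items()},
            "gene_flags": self.gene_flags,
            "neuron_params": self.neuron_params,
            "si_targets": {
                f"{d}:{s}": list(v) for (d, s), v in self.si_targets.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# -- defaults -----------------------------------------------------------

# behavioral means are qualitative: stress shrinks exploration, n-3
# enlarges it; count parameters (entries, head dips) are Poisson and
# carry only a mean
_BEHAVIOR_PARAMS = {
    # param: (base mean, sd, csds shift, n3 shift)
    "of_time_center_s": (90.0, 20.0, -25.0, 20.0),
    "of_time_periphery_s": (470.0, 30.0, 15.0, -10.0),
    "of_distance_cm": (2500.0, 300.0, -300.0, 300.0),
    "ld_time_light_s": (140.0, 30.0, -35.0, 30.0),
    "ld_time_dark_s": (310.0, 30.0, 30.0, -25.0),
    "ld_entries_light": (12.0, 3.5, -2.0, 2.0),
    "epm_time_open_s": (55.0, 15.0, -10.0, 15.0),
    "epm_time_center_s": (45.0, 10.0, -5.0, 5.0),
    "epm_distance_cm": (1000.0, 120.0, -100.0, 100.0),
    "epm_entries_open": (7.0, 2.6, -1.0, 2.0),
    "epm_head_dips": (10.0, 3.2, -2.0, 3.0),
}

COUNT_PARAMS = ("ld_entries_light", "epm_entries_open", "epm_head_dips")


def _default_behavior() -> dict:
    out = {}
    for diet, stress in CELLS:
        cell = {}
        for param, (mean, sd, d_csds, d_n3) in _BEHAVIOR_PARAMS.items():
            mu = mean
            if stress == "csds":
                mu += d_csds
            if diet == "n3_suppl":
                mu += d_n3
            cell[param] = (mu, sd)
        out[(diet, stress)] = cell
    return out


def _default_si() -> dict:
    return {
        ("control", "none"): (1.02, 0.18),
        ("control", "csds"): (0.85, 0.25),
        ("n3_suppl", "none"): (1.08, 0.18),
        ("n3_suppl", "csds"): (1.19, 0.10),
    }


def _default_ephys() -> dict:
    # diet raises RMP, capacitance (through tau), AP amplitude/duration,
    # and lowers baseline EPSC amplitude and delay to first spike; CSDS
    # effects on intrinsic properties are minor
    table = {
        ("control", "none"): dict(rmp=-82.0, tau=15.0, delay=387.5,
                                  amp=61.0, rise=34.8, decay=18.3,
                                  epsc=220.0),
        ("control", "csds"): dict(rmp=-81.5, tau=15.0, delay=427.8,
                                  amp=62.3, rise=35.0, decay=21.2,
                                  epsc=225.0),
        ("n3_suppl", "none"): dict(rmp=-78.0, tau=19.5, delay=352.4,
                                   amp=72.0, rise=31.5, decay=19.4,
                                   epsc=160.0),
        ("n3_suppl", "csds"): dict(rmp=-78.5, tau=19.5, delay=253.2,
                                   amp=69.9, rise=27.0, decay=15.5,
                                   epsc=165.0),
    }
    out = {}
    for cell, p in table.items():
        out[cell] = EphysCellParams(
            rmp_mV=(p["rmp"], 1.5),
            rin_MOhm=(165.0, 15.0),
            tau_ms=(p["tau"], 1.5),
            rheobase_pA=(240.0, 25.0),
            delay_ms=(p["delay"], 50.0),
            ap_amplitude_mV=(p["amp"], 6.0),
            ap_rise_mV_per_ms=(p["rise"], 4.0),
            ap_decay_mV_per_ms=(p["decay"], 3.0),
            epsc_baseline_pA=(p["epsc"], 35.0),
            ltd_factor=(0.70, 0.05),
        )
    return out


def default_effects() -> EffectSpec:
    """Default per-cell generative targets for all domains."""
    return EffectSpec(
        behavior=_default_behavior(),
        si_ratio=_default_si(),
        ephys=_default_ephys(),
        expr=ExprSpec(),
    )


# -- behavior -----------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Gaussian draw clipped to the physical bounds of the apparatus."""
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_behavior_cohort(
    design: GroupDesign,
    effects: EffectSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Generate per-animal behavioral and social-interaction tables.

    Returns (behavior table, social-interaction table, truth).  All
    times respect test durations (OF 600 s, LD 480 s, EPM 300 s, SI
    phases 300 s each), zone times within a test never exceed its
    duration jointly, and counts are non-negative integers.
    """
    effects.require_cells(design, "behavior")
    effects.require_cells(design, "si_ratio")
    rng = domain_rng(seed, "behavior")
    truth = TruthBundle(si_targets=dict(effects.si_ratio))
    beh_rows, si_rows = [], []
    i = 0
    for diet, stress in design.cells:
        cell = effects.behavior[(diet, stress)]
        si_mean, si_sd = effects.si_ratio[(diet, stress)]
        for _ in range(design.n_per_group):
            i += 1
            aid = f"M{i:03d}"
            truth.animal_cells[aid] = (diet, stress)
            row = {"animal_id": aid, "diet": diet, "stress": stress}
            for param, (mu, sd) in cell.items():
                if param in COUNT_PARAMS:
                    # Poisson counts (the stated sd only selects the
                    # degenerate sd=0 deterministic case)
                    row[param] = (int(rng.poisson(max(mu, 0.0)))
                                  if sd > 0 else int(round(mu)))
                else:
                    row[param] = float(_truncnorm(rng, mu, sd, 0.0, np.inf))
            # joint bounds within each apparatus
            row["of_time_center_s"] = min(row["of_time_center_s"], OF_DURATION_S)
            row["of_time_periphery_s"] = min(
                row["of_time_periphery_s"],
                OF_DURATION_S - row["of_time_center_s"],
            )
            row["ld_time_light_s"] = min(row["ld_time_light_s"], LD_DURATION_S)
            row["ld_time_dark_s"] = min(
                row["ld_time_dark_s"], LD_DURATION_S - row["ld_time_light_s"]
            )
            row["epm_time_open_s"] = min(row["epm_time_open_s"], EPM_DURATION_S)
            row["epm_time_center_s"] = min(
                row["epm_time_center_s"],
                EPM_DURATION_S - row["epm_time_open_s"],
            )
            beh_rows.append(row)

            ratio = float(_truncnorm(rng, si_mean, si_sd, 0.0, np.inf))
            no_target = float(_truncnorm(
                rng, *effects.si_no_target, 1.0, SI_PHASE_S
            ))
            target = min(ratio * no_target, SI_PHASE_S)
            si_rows.append({
                "animal_id": aid, "diet": diet, "stress": stress,
                "time_zone_no_target_s": no_target,
                "time_zone_target_s": target,
            })
    return pd.DataFrame(beh_rows), pd.DataFrame(si_rows), truth


# -- electrophysiology --------------------------------------------------

def _derive_threshold(rmp, rin, tau, rheobase, delay_ms):
    """Spike threshold putting the first rheobase spike at ``delay_ms``.

    With exact exponential charging toward V_inf = RMP + Rin*I, the
    membrane crosses thr = RMP + dV*(1 - exp(-delay/tau)) at exactly
    ``delay`` when I is the rheobase (dV = Rin*rheobase).
    """
    dv = rin * rheobase * 1e-3  # MOhm * pA -> mV
    return rmp + dv * (1.0 - np.exp(-delay_ms / tau))


def _simulate_sweep(
    params: dict[str, float],
    current_pA: float,
    sampling_rate: float,
    pre_s: float,
    step_s: float,
    post_s: float,
) -> np.ndarray:
    """Leaky integrate-and-fire response to one current step.

    Subthreshold voltage follows the exact exponential solution of
    tau dV/dt = -(V - RMP) + Rin*I; at threshold crossings a triangular
    AP (linear rise at the rise rate to threshold + amplitude, linear
    decay back to threshold) is stamped and the membrane restarts from a
    fixed post-spike reset 25 mV below threshold.
    """
    fs = sampling_rate
    rmp, rin, tau = params["rmp_mV"], params["rin_MOhm"], params["tau_ms"]
    thr = params["threshold_mV"]
    amp = params["ap_amplitude_mV"]
    rise, decay = params["ap_rise_mV_per_ms"], params["ap_decay_mV_per_ms"]
    v_reset = thr - 25.0
    tau_s = tau / 1000.0

    n = int(round((pre_s + step_s + post_s) * fs))
    t = np.arange(n) / fs
    v = np.full(n, rmp)
    onset, offset = pre_s, pre_s + step_s

    def fill_exp(t0, t1, v0, v_inf):
        """Exponential relaxation v0 -> v_inf over samples in [t0, t1)."""
        i0, i1 = int(np.ceil(t0 * fs - 1e-9)), min(int(np.ceil(t1 * fs - 1e-9)), n)
        if i1 > i0:
            v[i0:i1] = v_inf + (v0 - v_inf) * np.exp(-(t[i0:i1] - t0) / tau_s)

    def stamp_ap(t_cross):
        """Triangular AP starting at ``t_cross``; returns its end time."""
        t_rise_s = amp / rise / 1000.0
        t_decay_s = amp / decay / 1000.0
        t_peak = t_cross + t_rise_s
        t_end = t_peak + t_decay_s
        i0 = int(np.ceil(t_cross * fs - 1e-9))
        i1 = min(int(np.ceil(t_end * fs - 1e-9)), n)
        for i in range(i0, i1):
            ti = t[i]
            if ti < t_peak:
                v[i] = thr + rise * (ti - t_cross) * 1000.0
            else:
                v[i] = thr + amp - decay * (ti - t_peak) * 1000.0
        return t_end

    v_inf_step = rmp + rin * current_pA * 1e-3
    t0, v0 = onset, rmp
    while True:
        if v0 < thr and v_inf_step > thr + 1e-12:
            frac = (thr - v_inf_step) / (v0 - v_inf_step)
            t_cross = t0 + tau_s * (-np.log(frac))
        else:
            t_cross = np.inf
        fill_exp(t0, min(t_cross, offset), v0, v_inf_step)
        if t_cross >= offset:
            v_off = v_inf_step + (v0 - v_inf_step) * np.exp(
                -(offset - t0) / tau_s
            )
            t_post0, v_post0 = offset, v_off
            break
        t_end = stamp_ap(t_cross)
        if t_end >= offset:
            t_post0, v_post0 = t_end, v_reset
            break
        t0, v0 = t_end, v_reset
    fill_exp(t_post0, pre_s + step_s + post_s, v_post0, rmp)
    return v


def generate_ephys_recordings(
    design: GroupDesign,
    effects: EffectSpec,
    seed: int = 0,
    neurons_per_cell: int | None = None,
    sampling_rate: float = 20_000.0,
    step_start_pA: float = -100.0,
    step_stop_pA: float = 300.0,
    step_increment_pA: float = 10.0,
    pre_s: float = 0.1,
    step_s: float = 0.5,
    post_s: float = 0.1,
    trace_noise_mV: float = 0.0,
    epsc_noise_frac: float = 0.10,
    epsc_baseline_s: float = 600.0,
    epsc_protocol_s: float = 600.0,
    epsc_post_s: float = 2400.0,
    ltd_tau_s: float = 90.0,
) -> tuple[list[SweepSet], list[EPSCSeries], TruthBundle]:
    """Generate current-clamp sweep families and evoked-EPSC series.

    One neuron yields a family of current steps (default -100 to +300 pA
    by 10 pA, 500 ms steps at 20 kHz) and one EPSC amplitude series at
    0.1 Hz: a 10 min baseline, a 10 min induction gap (no test pulses
    during the 10 Hz protocol), and 40 min of follow-up in which the
    mean amplitude relaxes smoothly to ``ltd_factor`` times baseline.
    Per-neuron true parameters are drawn around the cell means and
    recorded in the truth bundle; the drawn rheobase is quantized to the
    step increment so it is exactly attainable.
    """
    effects.require_cells(design, "ephys")
    if step_increment_pA <= 0:
        raise ValueError("step increment must be positive")
    rng = domain_rng(seed, "ephys")
    if neurons_per_cell is None:
        neurons_per_cell = design.n_per_group
    currents = np.arange(
        step_start_pA, step_stop_pA + step_increment_pA / 2, step_increment_pA
    )
    truth = TruthBundle()
    sweep_sets: list[SweepSet] = []
    epsc_series: list[EPSCSeries] = []
    k = 0
    for diet, stress in design.cells:
        cp = effects.ephys[(diet, stress)]
        for _ in range(neurons_per_cell):
            k += 1
            nid = f"N{k:03d}"
            p = {
                "rmp_mV": rng.normal(*cp.rmp_mV),
                "rin_MOhm": max(rng.normal(*cp.rin_MOhm), 20.0),
                "tau_ms": max(rng.normal(*cp.tau_ms), 2.0),
                "ap_amplitude_mV": max(rng.normal(*cp.ap_amplitude_mV), 40.0),
                "ap_rise_mV_per_ms": max(rng.normal(*cp.ap_rise_mV_per_ms), 22.0),
                "ap_decay_mV_per_ms": max(rng.normal(*cp.ap_decay_mV_per_ms), 8.0),
                "epsc_baseline_pA": max(rng.normal(*cp.epsc_baseline_pA), 30.0),
                "ltd_factor": float(
                    np.clip(rng.normal(*cp.ltd_factor), 0.05, 1.0)
                ),
            }
            rheo = rng.normal(*cp.rheobase_pA)
            rheo = float(np.clip(
                np.round(rheo / step_increment_pA) * step_increment_pA,
                step_increment_pA, step_stop_pA,
            ))
            p["rheobase_pA"] = rheo
            # lower bound keeps the sub-rheobase sweep clearly
            # subthreshold; the upper bound keeps the rheobase-delay
            # tuning of the threshold well above float cancellation
            # noise (exp(-delay/tau) >= 1e-8)
            min_delay = p["tau_ms"] * np.log(4.0 * rheo / step_increment_pA)
            max_delay = min(step_s * 1000.0 - 20.0,
                            p["tau_ms"] * np.log(1e8))
            p["delay_ms"] = float(
                np.clip(rng.normal(*cp.delay_ms), min_delay, max_delay)
            )
            p["threshold_mV"] = float(_derive_threshold(
                p["rmp_mV"], p["rin_MOhm"], p["tau_ms"],
                p["rheobase_pA"], p["delay_ms"],
            ))
            # APs overshoot 0 mV regardless of threshold; keep the
            # stamped peak at least +5 mV
            p["ap_amplitude_mV"] = max(
                p["ap_amplitude_mV"], 5.0 - p["threshold_mV"]
            )
            p["diet"], p["stress"] = diet, stress
            truth.neuron_params[nid] = p

            sweeps = []
            for current in currents:
                v = _simulate_sweep(p, float(current), sampling_rate,
                                    pre_s, step_s, post_s)
                if trace_noise_mV > 0:
                    v = v + rng.normal(0.0, trace_noise_mV, size=v.size)
                sweeps.append(Sweep(
                    current_pA=float(current),
                    step_onset_s=pre_s,
                    step_offset_s=pre_s + step_s,
                    voltage_mV=v,
                ))
            sweep_sets.append(SweepSet(
                neuron_id=nid, sampling_rate=sampling_rate, sweeps=sweeps,
            ))

            onset = epsc_baseline_s
            end = onset + epsc_protocol_s
            t_base = np.arange(0.0, onset, 10.0)
            t_post = np.arange(end, end + epsc_post_s, 10.0)
            times = np.concatenate([t_base, t_post])
            f = p["ltd_factor"]
            mean = np.where(
                times < onset,
                p["epsc_baseline_pA"],
                p["epsc_baseline_pA"]
                * (f + (1.0 - f) * np.exp(-(times - onset) / ltd_tau_s)),
            )
            amps = mean
            if epsc_noise_frac > 0:
                amps = mean * (1.0 + rng.normal(0.0, epsc_noise_frac,
                                                size=times.size))
            amps = np.maximum(amps, 1.0)
            epsc_series.append(EPSCSeries(
                neuron_id=nid, times_s=times, amplitudes_pA=amps,
                protocol_onset_s=onset, protocol_end_s=end,
                stimulation_intensity=float(rng.normal(50.0, 5.0)),
            ))
    return sweep_sets, epsc_series, truth


# -- expression ---------------------------------------------------------

def generate_expression_dataset(
    spec: ExprSpec,
    design: GroupDesign,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthBundle]:
    """Generate a linear-scale gene x sample intensity panel.

    Samples are the two diet groups of unstressed animals
    (``design.n_per_group`` per diet), split over ``n_batches`` labeling
    batches balanced within each group.  Linear intensities are
    2 ** (gene baseline + effect * flag [supplemented samples only]
    + batch offset + Gaussian noise).  The housekeeping gene (Gapdh)
    carries no group effect; flagged genes default to the 25 panel genes
    reported upregulated.
    """
    rng = domain_rng(seed, "expression")
    filler = [f"Lp{i:02d}" for i in range(1, spec.n_genes + 1)]
    flagged = list(spec.true_up_genes[: spec.n_true_up])
    if len(flagged) < spec.n_true_up:
        flagged += filler[: spec.n_true_up - len(flagged)]
    genes = list(flagged)
    if spec.housekeeping not in genes:
        genes.append(spec.housekeeping)
    for g in filler:
        if len(genes) >= spec.n_genes:
            break
        if g not in genes:
            genes.append(g)
    if len(genes) != spec.n_genes:
        raise ValueError("could not assemble the requested gene panel")
    flags = {g: g in set(flagged) for g in genes}
    if flags[spec.housekeeping]:
        raise ValueError("housekeeping gene cannot carry a group effect")

    samples, groups, batches = [], [], []
    for diet in design.diet_levels:
        tag = "ctrl" if diet == design.diet_levels[0] else "suppl"
        for j in range(design.n_per_group):
            samples.append(f"{tag}_{j + 1:02d}")
            groups.append(diet)
            batches.append(f"B{j % spec.n_batches + 1}")
    meta = pd.DataFrame({"group": groups, "batch": batches}, index=samples)

    base = rng.uniform(*spec.baseline_log2_range, size=spec.n_genes)
    log2 = np.empty((spec.n_genes, len(samples)))
    batch_idx = np.array([int(b[1:]) - 1 for b in batches], dtype=float)
    for gi, g in enumerate(genes):
        effect = spec.log2_effect if flags[g] else 0.0
        is_suppl = np.array(
            [grp == design.diet_levels[1] for grp in groups], dtype=float
        )
        log2[gi] = (
            base[gi]
            + effect * is_suppl
            + spec.batch_offset * batch_idx
            + (rng.normal(0.0, spec.noise_sd, size=len(samples))
               if spec.noise_sd > 0 else 0.0)
        )
    values = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    values.index.name = "gene"
    meta.index.name = "sample"
    matrix = ExpressionMatrix(values=values, sample_meta=meta, scale="linear")
    truth = TruthBundle(gene_flags=flags)
    return matrix, truth


# -- gene families ------------------------------------------------------

def generate_gene_families(
    n_families: int = 50,
    genome_size: int = DEFAULT_GENOME_SIZE,
    size_range: tuple[int, int] = (5, 200),
    nest_prob: float = 0.25,
    anchor_genes=UPREGULATED_GENES,
    seed: int = 0,
) -> GeneSetCollection:
    """Generate GO-style families over a synthetic genome.

    Families draw members from a synthetic genome of ``genome_size``
    genes that includes the ``anchor_genes`` (by default the panel's 25
    upregulated genes).  Each anchor gene carries a Beta(0.5, 4)
    inclusion propensity, so a few genes recur across many families
    while others map to none — mirroring the redundancy of nested
    ontology terms.  With probability ``nest_prob`` a family is built as
    a strict subset of an earlier one, creating inclusive relationships.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    if genome_size < hi:
        raise ValueError("genome_size must cover the largest family")
    rng = domain_rng(seed, "families")
    anchors = list(anchor_genes)
    pool = [f"SynG{i:05d}" for i in range(genome_size - len(anchors))]
    propensity = rng.beta(0.5, 4.0, size=len(anchors))

    families: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    ids = []
    for i in range(n_families):
        fam = f"GO:{7000000 + i:07d}"
        target = int(rng.integers(lo, hi + 1))
        parent = None
        if ids and rng.random() < nest_prob:
            parent = ids[int(rng.integers(len(ids)))]
            members = list(families[parent])
            if len(members) > lo:
                take = int(rng.integers(lo, len(members)))
                sel = rng.choice(len(members), size=take, replace=False)
                members = [members[j] for j in sel]
        else:
            hit = rng.random(len(anchors)) < propensity
            members = [a for a, h in zip(anchors, hit) if h]
            n_fill = max(target - len(members), 1)
            sel = rng.choice(len(pool), size=min(n_fill, len(pool)),
                             replace=False)
            members += [pool[j] for j in sel]
        families[fam] = frozenset(members)
        names[fam] = (f"synthetic lipid process family {i + 1}"
                      + (f" (subset of {parent})" if parent else ""))
        ids.append(fam)
    return GeneSetCollection(
        families=families, names=names, genome_size=genome_size
    )
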