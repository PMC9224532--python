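"""End-to-end orchestration: synthesize -> score -> classify/bootstrap ->
ephys -> expression -> ORA -> report.

Stages communicate only through files in the output directory, so every
intermediate is re-runnable and inspectable; a machine-readable
``report.json`` (plus a human ``report.md``) collects the headline
numbers, the per-stage output paths with SHA-256 checksums, the seeds
and any warnings.  With a fixed master seed two runs produce identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from . import stats
from .enrichment import redundancy_map, run_ora
from .ephys import analyze_ltd, build_curves, measure_passive, \
    measure_spike_properties
from .expression import batch_correct, differential_tests, log2_transform, \
    quantile_normalize, relative_expression, zscore_matrix
from .resilience import bootstrap_group, bootstrap_null_control, \
    compare_proportions, label_cohort
from .scoring import compute_anxiety_scores
from .synthetic import ExprSpec, GroupDesign, default_effects, \
    generate_behavior_cohort, generate_ephys_recordings, \
    generate_expression_dataset, generate_gene_families

__all__ = ["default_config", "run_full_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1"


def default_config() -> dict:
    """Pipeline defaults mirroring the reference experiment's settings:
    7-10 animals per cell (8 here), r = 100 bootstrap replicates,
    alpha = 0.05, 25-of-89 expression structure, genome universe 18,985.
    """
    return {
        "design": {"n_per_group": 8},
        "arms": {"behavior": True, "ephys": True, "expression": True},
        "bootstrap": {"r": 100, "null_control_rounds": 200},
        "ephys": {"neurons_per_cell": 4},
        "expression": {},
        "ora": {"genome_size": 18_985, "top_k": 20, "n_families": 50},
        "alpha": 0.05,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_full_pipeline(config=None, out_dir="results", seed: int = 17) -> dict:
    """Run every enabled analysis arm and write ``report.json``/``.md``.

    ``config`` may be a mapping, a path to a YAML file, or None for the
    defaults; unknown keys raise before any stage runs.  A disabled arm
    is marked "skipped" in the report with a recorded warning.
    """
    if config is None:
        config = {}
    elif isinstance(config, (str, Path)):
        with open(config) as f:
            config = yaml.safe_load(f) or {}
    if not isinstance(config, dict):
        raise TypeError("config must be a mapping or a YAML file path")
    base = default_config()
    unknown = set(config) - set(base)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(base, config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    log_lines: list[str] = []
    t_start = time.perf_counter()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.perf_counter() - t_start:8.2f}s] {msg}")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": cfg,
        "seed": seed,
        "outputs": {},
        "warnings": [],
    }
    caught: list[str] = []

    def register(name: str, path: Path) -> None:
        report["outputs"][name] = {
            "path": path.name, "sha256": _sha256(path),
        }

    design = GroupDesign(n_per_group=cfg["design"]["n_per_group"])
    effects = default_effects()
    if cfg["expression"]:
        effects.expr = ExprSpec(**cfg["expression"])
    alpha = cfg["alpha"]

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # -- behavior arm ------------------------------------------------
        if cfg["arms"]["behavior"]:
            log("behavior: synthesizing cohort")
            beh, si, truth_b = generate_behavior_cohort(design, effects, seed)
            kio.write_behavior(beh, out / "behavior.csv")
            kio.write_social(si, out / "social_interaction.csv")
            truth_b.to_json(out / "truth_behavior.json")
            register("behavior", out / "behavior.csv")
            register("social_interaction", out / "social_interaction.csv")

            scores = compute_anxiety_scores(beh)
            scored = beh[["animal_id", "diet", "stress"]].merge(
                scores, on="animal_id"
            )
            kio.write_behavior(scored, out / "anxiety_scores.csv")
            register("anxiety_scores", out / "anxiety_scores.csv")
            aov = stats.anova_factorial(
                scored["anxiety_score"],
                {"stress": scored["stress"], "diet": scored["diet"]},
            )
            report["anxiety"] = {
                "per_cell_mean": _round({
                    f"{d}:{s}": float(g["anxiety_score"].mean())
                    for (d, s), g in scored.groupby(["diet", "stress"])
                }),
                "anova": _round({
                    term: {"F": t.F, "df1": t.df1, "df2": t.df2, "p": t.p}
                    for term, t in aov.terms.items()
                }),
            }

            log("behavior: resilience classification and bootstrap")
            labeled = label_cohort(si)
            kio.write_social(
                labeled[["animal_id", "diet", "stress", "ratio", "label"]],
                out / "resilience.csv",
            )
            register("resilience", out / "resilience.csv")
            defeated = labeled[labeled["stress"] == "csds"]
            r = cfg["bootstrap"]["r"]
            boot_report = {}
            group_ratios = {}
            for diet, g in defeated.groupby("diet"):
                summ = bootstrap_group(
                    g["ratio"].to_numpy(), r=r, seed=seed, group=str(diet)
                )
                group_ratios[str(diet)] = g
                boot_report[str(diet)] = _round({
                    "n": int(len(g)),
                    "r": r,
                    "observed_mean": summ.observed_mean,
                    "ci95": [summ.ci_low, summ.ci_high],
                    "prop_resilient": float((g["ratio"] > 1).mean()),
                    "mean_replicate_prop_resilient":
                        float(summ.replicate_prop_resilient.mean()),
                })
            diets = sorted(group_ratios)
            if len(diets) == 2:
                fisher = compare_proportions(
                    group_ratios[diets[0]]["label"],
                    group_ratios[diets[1]]["label"],
                )
                boot_report["fisher"] = _round({
                    "odds_ratio": fisher.odds_ratio, "p": fisher.p,
                })
                rounds = cfg["bootstrap"]["null_control_rounds"]
                if rounds:
                    null = bootstrap_null_control(
                        group_ratios[diets[0]]["ratio"].to_numpy(),
                        group_ratios[diets[1]]["ratio"].to_numpy(),
                        r=r, seed=seed, n_rounds=rounds,
                    )
                    boot_report["null_control"] = _round({
                        "n_rounds": rounds,
                        "non_overlap_rate": null.non_overlap_rate,
                    })
            report["resilience"] = boot_report
            (out / "bootstrap.json").write_text(
                json.dumps(boot_report, indent=1, sort_keys=True)
            )
            register("bootstrap", out / "bootstrap.json")
        else:
            report["anxiety"] = "skipped"
            report["resilience"] = "skipped"
            caught.append("behavior arm disabled; anxiety and resilience skipped")

        # -- ephys arm ---------------------------------------------------
        if cfg["arms"]["ephys"]:
            log("ephys: synthesizing recordings")
            sweep_sets, epsc_series, truth_e = generate_ephys_recordings(
                design, effects, seed,
                neurons_per_cell=cfg["ephys"]["neurons_per_cell"],
            )
            kio.write_sweeps_h5(sweep_sets, out / "sweeps.h5")
            kio.write_epsc(epsc_series, out / "epsc.csv")
            register("epsc", out / "epsc.csv")

            log("ephys: extracting features")
            feat_rows, curve_rows, ltd_rows = [], [], []
            for ss, es in zip(sweep_sets, epsc_series):
                meta = truth_e.neuron_params[ss.neuron_id]
                passive = measure_passive(ss)
                spikes = measure_spike_properties(ss)
                feat_rows.append({
                    "neuron_id": ss.neuron_id,
                    "diet": meta["diet"], "stress": meta["stress"],
                    "rmp_mV": passive.rmp_mV,
                    "input_resistance_MOhm": passive.input_resistance_MOhm,
                    "membrane_tau_ms": passive.membrane_tau_ms,
                    "capacitance_pF": passive.capacitance_pF,
                    "rheobase_pA": passive.rheobase_pA,
                    "ap_threshold_mV": spikes.ap_threshold_mV,
                    "ap_amplitude_mV": spikes.ap_amplitude_mV,
                    "ap_duration_ms": spikes.ap_duration_ms,
                    "delay_to_first_spike_ms": spikes.delay_to_first_spike_ms,
                    "rise_kinetics_mV_per_ms": spikes.rise_kinetics_mV_per_ms,
                    "decay_kinetics_mV_per_ms": spikes.decay_kinetics_mV_per_ms,
                })
                curves = build_curves(ss, relative_to_rheobase=True)
                for _, row in curves.iv.iterrows():
                    curve_rows.append({
                        "neuron_id": ss.neuron_id, "curve": "iv",
                        "current_pA": row["current_pA"],
                        "value": row["steady_state_mV"],
                    })
                for _, row in curves.if_curve.iterrows():
                    curve_rows.append({
                        "neuron_id": ss.neuron_id, "curve": "if",
                        "current_pA": row["current_pA"],
                        "value": row["n_spikes"],
                    })
                ltd = analyze_ltd(es)
                ltd_rows.append({
                    "neuron_id": ss.neuron_id,
                    "diet": meta["diet"], "stress": meta["stress"],
                    "baseline_mean_pA": ltd.baseline_mean_pA,
                    "early_mean": ltd.early_mean,
                    "late_mean": ltd.late_mean,
                })
            features = pd.DataFrame(feat_rows)
            features.to_csv(out / "ephys_features.csv", index=False,
                            float_format="%.6f")
            pd.DataFrame(curve_rows).to_csv(
                out / "curves.csv", index=False, float_format="%.6f"
            )
            ltd_table = pd.DataFrame(ltd_rows)
            ltd_table.to_csv(out / "ltd.csv", index=False,
                             float_format="%.6f")
            for name in ("ephys_features", "curves", "ltd"):
                register(name, out / f"{name}.csv")
            register("sweeps", out / "sweeps.h5")

            ephys_anova = {}
            for feature in ("rmp_mV", "capacitance_pF",
                            "input_resistance_MOhm", "rheobase_pA",
                            "ap_amplitude_mV"):
                aov = stats.anova_factorial(
                    features[feature],
                    {"stress": features["stress"], "diet": features["diet"]},
                )
                ephys_anova[feature] = _round({
                    term: {"F": t.F, "p": t.p}
                    for term, t in aov.terms.items()
                })
            report["ephys"] = {
                "n_neurons": int(len(features)),
                "anova": ephys_anova,
                "ltd_late_mean_per_cell": _round({
                    f"{d}:{s}": float(g["late_mean"].mean())
                    for (d, s), g in ltd_table.groupby(["diet", "stress"])
                }),
            }
        else:
            report["ephys"] = "skipped"
            caught.append("ephys arm disabled")

        # -- expression arm ----------------------------------------------
        if cfg["arms"]["expression"]:
            log("expression: synthesizing panel")
            matrix, truth_x = generate_expression_dataset(
                effects.expr, design, seed
            )
            kio.write_expression(matrix, out / "expression.tsv",
                                 out / "samples.tsv")
            register("expression", out / "expression.tsv")
            register("samples", out / "samples.tsv")

            log("expression: preprocessing and differential tests")
            m = log2_transform(matrix)
            m = batch_correct(m)
            m = quantile_normalize(m)
            rel = relative_expression(
                m, housekeeping=effects.expr.housekeeping,
                control_group=design.diet_levels[0],
            )
            kio.write_expression(rel, out / "normalized.tsv",
                                 out / "samples_normalized.tsv")
            register("normalized", out / "normalized.tsv")
            diff = differential_tests(
                rel, design.diet_levels[0], design.diet_levels[1],
                alpha=alpha,
            )
            diff.table.to_csv(out / "differential.csv",
                              float_format="%.6g")
            register("differential", out / "differential.csv")
            zscore_matrix(rel).to_csv(out / "zscores.tsv", sep="\t",
                                      float_format="%.6f")
            register("zscores", out / "zscores.tsv")
            up = diff.table[(diff.table["significant"])
                            & (diff.table["log2_fc"] > 0)]
            report["expression"] = {
                "n_genes": int(len(diff.table)),
                "n_significant": int(diff.n_significant),
                "n_significant_up": int(len(up)),
                "alpha": alpha,
            }

            log("ora: gene families and over-representation")
            collection = generate_gene_families(
                n_families=cfg["ora"]["n_families"],
                genome_size=cfg["ora"]["genome_size"],
                seed=seed,
            )
            collection.to_gmt(out / "families.gmt")
            register("families", out / "families.gmt")
            sig_genes = list(up.index)
            if sig_genes:
                ora = run_ora(sig_genes, collection, alpha=alpha)
                ora.to_csv(out / "ora.csv", float_format="%.6g")
                register("ora", out / "ora.csv")
                top_k = min(cfg["ora"]["top_k"], len(ora))
                red = redundancy_map(ora, collection, sig_genes, top_k=top_k)
                red.membership.astype(int).to_csv(out / "redundancy.csv")
                register("redundancy", out / "redundancy.csv")
                report["ora"] = {
                    "universe_N": cfg["ora"]["genome_size"],
                    "top_families": ora.head(5).index.tolist(),
                    "max_ER": _round(float(ora["ER"].max())),
                    "unmapped_genes": ora.attrs["unmapped"],
                    "redundancy_max_gene": (
                        str(red.gene_counts.idxmax()) if len(red.gene_counts)
                        else None
                    ),
                }
            else:
                report["ora"] = "skipped"
                caught.append("no significant genes; ORA skipped")
        else:
            report["expression"] = "skipped"
            report["ora"] = "skipped"
            caught.append("expression arm disabled; ORA skipped")

        caught.extend(str(w.message) for w in wrec)

    report["warnings"] = caught
    (out / "report.json").write_text(
        json.dumps(_round(report), indent=1, sort_keys=True) + "\n"
    )
    (out / "report.md").write_text(_render_md(report))
    log("done")
    log_path.write_text("\n".join(log_lines) + "\n")
    return report


def _render_md(report: dict) -> str:
    lines = [
        "# Pipeline report",
        "",
        f"- schema version: {report['schema_version']}",
        f"- master seed: {report['seed']}",
        "",
        "## Headline numbers",
        "",
    ]
    if isinstance(report.get("anxiety"), dict):
        for cell, mean in sorted(
            report["anxiety"]["per_cell_mean"].items()
        ):
            lines.append(f"- anxiety score mean [{cell}]: {mean}")
    if isinstance(report.get("resilience"), dict):
        for grp, d in sorted(report["resilience"].items()):
            if isinstance(d, dict) and "ci95" in d:
                lines.append(
                    f"- SI ratio [{grp}]: mean {d['observed_mean']}, "
                    f"95% CI {d['ci95']}, resilient {d['prop_resilient']}"
                )
    if isinstance(report.get("expression"), dict):
        e = report["expression"]
        lines.append(
            f"- differential genes: {e['n_significant']} of {e['n_genes']} "
            f"at alpha={e['alpha']} ({e['n_significant_up']} up)"
        )
    if isinstance(report.get("ora"), dict):
        lines.append(
            f"- top enriched families: "
            f"{', '.join(report['ora']['top_families'][:3])}"
        )
    lines += ["", "## Outputs", ""]
    for name, d in sorted(report["outputs"].items()):
        lines.append(f"- {name}: `{d['path']}` (sha256 {d['sha256'][:12]})")
    if report["warnings"]:
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in report["warnings"]]
    return "\n".join(lines) + "\n"
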