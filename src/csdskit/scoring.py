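"""Composite anxiety score on a 0-3 scale.

Six exploration parameters from three tests — open-field (OF) center time;
light-dark (LD) box light time and light entries; elevated-plus-maze (EPM)
open-arm time, open-arm entries and head dips — are min-max normalized over
the whole cohort, oriented so that 1 marks the anxiogenic extreme (all six
are exploration measures, so orientation is 1 - normalized), and aggregated
so each behavioral test contributes exactly one point: OF with weight 1,
the two LD parameters with weight 1/2 each, the three EPM parameters with
weight 1/3 each.  The total therefore lies in [0, 3], with 3 the most
anxious animal a cohort can contain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["SCORE_WEIGHTS", "normalize_minmax", "compute_anxiety_scores"]

# parameter -> (test, weight); weights within a test sum to 1
SCORE_WEIGHTS: dict[str, tuple[str, float]] = {
    "of_time_center_s": ("OF", 1.0),
    "ld_time_light_s": ("LD", 0.5),
    "ld_entries_light": ("LD", 0.5),
    "epm_time_open_s": ("EPM", 1.0 / 3.0),
    "epm_entries_open": ("EPM", 1.0 / 3.0),
    "epm_head_dips": ("EPM", 1.0 / 3.0),
}


def normalize_minmax(values) -> np.ndarray:
    """Min-max normalize a cohort's parameter: (x - min)/(max - min).

    The cohort minimum maps to 0 and the maximum to 1.  A zero-range
    parameter (all animals identical) maps every animal to the neutral
    0.5 with a warning, so the composite stays defined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(
            "zero range in min-max normalization; all values set to 0.5"
        )
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def compute_anxiety_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Compute per-animal composite anxiety scores for a cohort.

    Parameters
    ----------
    cohort : one row per animal with at least ``animal_id`` and the six
        score parameters (see :data:`SCORE_WEIGHTS`).  Normalization
        extremes are taken over all animals passed in (all experimental
        groups pooled).

    Returns
    -------
    DataFrame with the oriented per-parameter values (``oriented_*``,
    1 = anxiogenic extreme), the per-test scores (``score_of``,
    ``score_ld``, ``score_epm``, each in [0, 1]) and the composite
    ``anxiety_score`` in [0, 3].
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 animals to compute scores")
    missing = [p for p in SCORE_WEIGHTS if p not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks score parameters: {missing}")
    for p in SCORE_WEIGHTS:
        bad = cohort.loc[cohort[p].isna(), "animal_id"].tolist()
        if bad:
            raise ValueError(f"missing value for parameter {p!r} in animals {bad}")

    out = pd.DataFrame({"animal_id": cohort["animal_id"].to_numpy()})
    per_test = {"OF": 0.0, "LD": 0.0, "EPM": 0.0}
    for param, (test, weight) in SCORE_WEIGHTS.items():
        oriented = 1.0 - normalize_minmax(cohort[param])
        out[f"oriented_{param}"] = oriented
        per_test[test] = per_test[test] + weight * oriented
    for test, score in per_test.items():
        out[f"score_{test.lower()}"] = score
    out["anxiety_score"] = (
        out["score_of"] + out["score_ld"] + out["score_epm"]
    )
    return out
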