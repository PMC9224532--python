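"""Composite anxiety scoring of a synthetic diet x stress cohort.

Generates behavioral test tables for a 2x2 cohort (diet: control vs
n-3 supplemented; stress: none vs chronic social defeat), computes the
six-parameter composite anxiety score on the 0-3 scale, and compares
group means: defeated mice should score higher (more anxious), n-3
supplemented mice lower.
"""

from csdskit import compute_anxiety_scores, generate_behavior_cohort
from csdskit.synthetic import GroupDesign, default_effects

design = GroupDesign(n_per_group=8)
behavior, _, _ = generate_behavior_cohort(design, default_effects(), seed=17)

scores = behavior[["animal_id", "diet", "stress"]].merge(
    compute_anxiety_scores(behavior), on="animal_id"
)

print("mean composite anxiety score (0 = exploratory, 3 = most anxious):")
for (diet, stress), group in scores.groupby(["diet", "stress"]):
    print(f"  {diet:9s} x {stress:5s}: "
          f"{group['anxiety_score'].mean():.2f} "
          f"(n={len(group)})")
print()
print("Each behavioral test (open field, light-dark box, elevated plus")
print("maze) contributes one point; a higher score means the animal sat")
print("nearer the cohort's anxiogenic extreme on that test's parameters.")
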