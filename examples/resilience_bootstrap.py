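"""Resilience classification and bootstrap CIs for defeated mice.

Social-interaction (SI) ratios above 1 mark stress-resilient animals.
With 7-10 animals per group, single proportions are noisy, so each
defeated group's mean ratio gets a percentile bootstrap CI (r = 100),
plus a permuted-label negative control showing that resampling alone
does not separate the groups.
"""

from csdskit import (
    bootstrap_group,
    bootstrap_null_control,
    compare_proportions,
    generate_behavior_cohort,
    label_cohort,
)
from csdskit.synthetic import GroupDesign, default_effects

design = GroupDesign(n_per_group=10)
_, si, _ = generate_behavior_cohort(design, default_effects(), seed=17)
labeled = label_cohort(si)
defeated = labeled[labeled["stress"] == "csds"]

groups = {}
for diet, g in defeated.groupby("diet"):
    s = bootstrap_group(g["ratio"].to_numpy(), r=100, seed=17,
                        group=str(diet))
    groups[str(diet)] = g
    n_res = (g["label"] == "resilient").sum()
    print(f"{diet:9s}: mean SI ratio {s.observed_mean:.2f}, "
          f"95% bootstrap CI [{s.ci_low:.2f}, {s.ci_high:.2f}], "
          f"resilient {n_res}/{len(g)}")

fisher = compare_proportions(groups["control"]["label"],
                             groups["n3_suppl"]["label"])
print(f"Fisher's exact test on resilient/susceptible counts: "
      f"p = {fisher.p:.2f}")

null = bootstrap_null_control(
    groups["control"]["ratio"].to_numpy(),
    groups["n3_suppl"]["ratio"].to_numpy(),
    r=100, seed=17, n_rounds=300,
)
print(f"negative control (labels permuted, {null.n_rounds} rounds): "
      f"CI non-overlap rate {null.non_overlap_rate:.3f}")
print()
print("A supplemented-group CI strictly above 1 indicates resilience at")
print("the group level; the near-zero null rate shows the bootstrap is")
print("not manufacturing that separation.")
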