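# Methods

This note documents the models behind each component, the defaults and
why they were chosen, the numerical decisions, and the limits of what
the synthetic cohort can demonstrate.

## Study design emulated

A 2×2 factorial mouse cohort: diet ∈ {control, n3_suppl} × stress ∈
{none, csds}, default 8 animals per cell (the experiment this mirrors
used 7–10). Group comparisons use two-way factorial ANOVA with stress
and diet as factors; per-gene comparisons use unpaired t-tests; label
proportions use Fisher's exact test.

## Composite anxiety score

Each of the six exploration parameters is min–max normalized over the
*pooled* cohort (all four cells). Per-group normalization was rejected
because it would erase exactly the group effects the score is meant to
expose; whether the original analysis normalized within-experiment or
against historical extremes is not documented, so the pooled-cohort
convention is this package's own documented choice, not recovered
intent.

Orientation: all six parameters are exploration measures (more time in
the open/light zones = less anxious), so each contributes
weight × (1 − x_n); this is the only orientation consistent with a 0–3
scale on which 3 is maximal anxiety. Weights are fixed by parameter
count per test (1; ½,½; ⅓,⅓,⅓) so each test contributes one point; they
are deliberately not configurable.

Degenerate input: a parameter with zero cohort range would make x_n
undefined; it is mapped to the neutral 0.5 for every animal, with a
warning, so the composite stays defined rather than failing the run.

Guaranteed properties (all tested): totals in [0, 3] with the extremes
attained exactly at the cohort extremes; invariance under positive
affine rescaling of any raw parameter; monotonicity — reducing an
animal's exploration (within fixed cohort extremes) never lowers its
score.

## Resilience bootstrap

The resampling unit is the animal, with replacement, preserving group
size; the replicate statistic is the **group mean ratio** (the original
report does not state its statistic; the mean matches the displayed CI
of ratios). The CI is the percentile interval (2.5th/97.5th of r
replicate means) — the simplest method consistent with "95% CI" at
r = 100; BCa was not used. The tie ratio = 1 classifies as susceptible
because resilience is defined strictly by ratio > 1.

Percentile bootstrap CIs *undercover* at these group sizes: for
N(μ, σ) samples with n = 10 and r = 2000, measured coverage of the 95%
interval is roughly 88–98% over 1000 Monte-Carlo rounds (asserted in
the test suite). Users comparing two groups by CI overlap should treat
the comparison as descriptive, which is why the permuted-label negative
control (`bootstrap_null_control`) is part of the module: it reruns the
whole procedure on label-permuted pseudo-groups and reports how often
the two 95% CIs fail to overlap — at or below the nominal level within
Monte-Carlo error when there is nothing to find.

## Expression pipeline

Stage order is enforced by a scale tag on the matrix (linear → log2 →
batch-corrected → quantile-normalized → relative); out-of-order calls
raise. Batch correction is one-way per-gene mean centering (subtract
batch mean, add back grand mean), ignoring group structure: the
confounders in the emulated experiment are technical (washing bath,
labeling serial) and the centering contract is the minimal testable
model; the original estimator is unreported. Centering is idempotent.
Quantile normalization is the standard sort/average/rank-map procedure;
ties receive the mean of their tied ranks' reference values.

Relative expression subtracts the housekeeping gene's (Gapdh) log2
value per sample, then the control-group mean per gene, so control fold
change is 1; results are reported both as log2 differences and linear
fold changes. Differential calls are pooled-variance t-tests at
α = 0.05 with **no multiplicity correction by default** — the emulated
analysis reports uncorrected "p < 0.05, unpaired t-tests" counts
(25 of 89) — with Benjamini–Hochberg available behind a flag.

## Over-representation analysis

ER = m·N/(M·n) is the observed family overlap over its expectation
under random draws; ER of the expected overlap is 1, and ER for m = 0
is defined as 0 (the source formula leaves it undefined). Significance
is the upper-tail hypergeometric probability P(X ≥ m), computed
locally (no web service). The default universe is the whole mouse
genome (N = 18,985) because that is the published formula's convention;
for an 89-gene assay panel this is statistically anticonservative, so
the universe is configurable and the default is logged loudly on every
run. The redundancy map counts each significant gene's membership
across the top-K (default 50) enriched families and flags member-set
inclusions among them — nested ontology terms make hits in a subset
imply hits in its supersets.

## Electrophysiology

**Generator model.** Leaky integrate-and-fire with exact exponential
subthreshold integration of τ·dV/dt = −(V − RMP) + R·I, sampled at
20 kHz; a conductance-based model is unnecessary because every
downstream feature is defined on the trace. Action potentials are
stylized triangular waveforms (linear rise at the cell's rise
kinetics to threshold + amplitude, linear decay back to threshold),
stamped at threshold crossings with a post-spike reset 25 mV below
threshold. The spike threshold is *derived* per neuron from (RMP, Rin,
τ, rheobase, delay-to-first-spike) such that the first spiking sweep is
exactly the rheobase step and the first spike occurs at the requested
delay; drawn rheobases are quantized to the step increment to keep this
exact. Two numerical guards: the requested delay is capped at
τ·ln(1e8) so the threshold-to-asymptote gap stays far above float
cancellation noise, and the AP peak is floored at +5 mV so every spike
overshoots 0 mV as real APs do. Traces are noiseless by default (an
optional additive noise term exists); EPSC amplitudes carry 10%
multiplicative noise by default.

**Feature extraction.** Spike onset = first sample with dV/dt ≥
20 mV/ms whose voltage exceeds 0 mV within 4 ms, with a 2 ms refractory
lockout. The dV/dt rule is a conventional choice (the emulated study
reports spike properties without a detection rule); the 4 ms
confirmation window is sized for these cells' slow upstrokes (rise
kinetics ~27–35 mV/ms on amplitudes of 55–75 mV). AP duration is the
base width at the threshold level, not the half-width: the reference
durations (5–8 ms) are far larger than typical half-widths, making base
width the consistent reading. Capacitance is τ/R (ms/MΩ → nF, reported
in pF) — the only trace-derivable definition. RMP comes from the
pre-step baseline at 0 pA; Rin from the least-squares slope of
steady-state ΔV vs ΔI over spike-free sweeps (steady state = mean of
the last 100 ms of the step); τ from a mono-exponential fit to the
charging phase of the largest spike-free hyperpolarizing step. The
+15.4 mV liquid-junction potential is **not** subtracted by default
(the emulated values are reported without stating a correction); a flag
applies it.

**LTD.** Baseline = the 10 min (60 events at 0.1 Hz) before protocol
onset; every amplitude is divided by the neuron's own baseline mean, so
the normalized baseline averages exactly 1. Early/late windows default
to 0–10 and 30–40 min after protocol end; the source windows are
unreported, so these are configurable and recorded in the output.

## Synthetic cohort: what it does and does not emulate

Emulated: the 2×2 group structure with per-cell means and noise;
truncated-Gaussian times/distances respecting apparatus durations
(OF 600 s, LD 480 s, EPM 300 s, SI phases 300 s) and Poisson counts;
SI-ratio distributions per cell (defaults put defeated controls near
0.85 and defeated supplemented animals near 1.19); an 89-gene panel
with 25 truly upregulated genes (+2.0 log2 by default, sd 0.5, two
labeling batches with a +1.0 log2 offset) and a zero-effect Gapdh;
per-cell AP parameters tracking the published group means (e.g.
amplitude 61 mV control vs 72 mV supplemented, rise 35 vs 31.5 mV/ms);
GO-style families over an 18,985-gene synthetic genome with
Beta-distributed gene recurrence (a few hub genes appear in many
families, some in none) and probabilistic nesting.

Not emulated, by design: video tracking, within-session behavioral
dynamics, the 10-day CSDS time course, probe-level microarray
artifacts, conductance-based membrane dynamics, series-resistance
effects, and any correlation structure between an animal's behavior and
its neurons' properties (domains are generated independently). Passing
tests therefore demonstrate that the *procedures* recover planted
structure under the stated noise models — not that they would be robust
to artifacts these simplifications exclude. Per-group behavioral means
are not published for the emulated study; the behavior defaults encode
only the qualitative ordering (CSDS more anxious, n-3 supplementation
less) and should not be read as quantitative claims.

One RNG stream per domain (behavior/ephys/expression/families), each
seeded from the master seed by a fixed offset, so regenerating one
domain never shifts another; all outputs are text-serialized at fixed
precision and byte-identical under a fixed seed.

## Shared statistics

The t statistic, Type II factorial sums of squares (via nested
least-squares model comparisons with sum-to-zero coding), and the
two-sided Fisher p (sum of hypergeometric point probabilities ≤ the
observed table's, with a 1 + 1e-7 tie guard) are computed in-package;
only the t/F/hypergeometric distribution functions come from scipy.
Type II was chosen for the unbalanced 2×2 cells (7–10/cell): it tests
each main effect adjusted for the other mains, the standard default
absent a stated choice. Pooled-variance (not Welch) matches the
classical "unpaired t-test". Post hoc tests are not implemented — the
emulated analyses report only omnibus F values. The test suite checks
the ANOVA against statsmodels' `anova_lm(typ=2)` to 1e-8, Fisher
against exhaustive enumeration of all tables with margins ≤ 12, and
the null calibration of the 2×2 ANOVA terms by simulation.

## Problem sizes in the test and acceptance runs

The distributed checks use: 1000 Monte-Carlo rounds at r = 2000 for
bootstrap coverage; 400 permutation rounds at r = 100 for the null
control; 52 randomized neurons (full −100…+300 pA families at 20 kHz)
for parameter recovery; 200 simulated 89 × 12 panels for differential
recall; and two full pipeline runs (n = 8/cell, 4 neurons/cell) for
end-to-end determinism. These sizes give Monte-Carlo error comfortably
inside every stated tolerance while keeping the whole suite around
twenty seconds on one core.

## Known limitations

- The leaky integrate-and-fire cell produces a discontinuous I–F curve
  near rheobase (one spike at rheobase, several one increment above),
  unlike real MSN f–I curves; the I–F contract is only that counts are
  nonzero above rheobase and reproduce stamped spikes exactly.
- Long first-spike delays (≫ τ) require exponentially fine threshold
  tuning in this model; the τ·ln(1e8) cap trades fidelity to the
  longest reported delays (~430 ms) for numerical robustness.
- Bootstrap CI comparisons are descriptive, not a calibrated test (see
  the undercoverage note above).
- The genome-wide ORA universe overstates enrichment for small assay
  panels; pass the panel size as the universe for conservative results.
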