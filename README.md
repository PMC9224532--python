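# csdskit

Analysis toolkit for **diet × chronic-social-defeat-stress (CSDS) mouse
cohorts**: the bespoke quantitative procedures of a 2×2 behavioral /
electrophysiological / transcriptional phenotyping experiment (diet:
control vs long-chain n-3 PUFA supplemented; stress: none vs 10-day
CSDS; 7–10 animals per cell), packaged as tested, reusable components
driven by a synthetic-cohort generator — so the full pipeline runs and
is verifiable without any animal data.

It is intended for behavioral neuroscientists and biostatisticians who
want these small-cohort procedures as an auditable library rather than
one-off analysis scripts.

## What it computes

**Composite anxiety score (0–3).** Six exploration parameters — open
field center time; light–dark box light time and light entries;
elevated-plus-maze open-arm time, open-arm entries and head dips — are
min–max normalized over the cohort, `x_n = (x − min)/(max − min)`,
oriented so 1 is the anxiogenic extreme (`1 − x_n`, since all six are
exploration measures), and summed with each behavioral *test* weighted
equally: OF ×1, the two LD parameters ×½, the three EPM parameters ×⅓.
An animal at the cohort's anxiogenic extreme on all six scores exactly
3; the all-exploratory extreme scores 0.

**Resilience classification and bootstrap.** The social-interaction
ratio (zone time with target / zone time with empty cage) labels
defeated mice resilient (ratio > 1) or susceptible (ratio < 1).
Group-level inference uses a percentile bootstrap of the group mean
ratio (default r = 100 replicates, 95% CI from the 2.5th/97.5th
replicate percentiles), Fisher's exact test on the label counts, and a
permuted-label negative control verifying that resampling alone does
not separate groups.

**Expression pipeline + ORA.** A gene × sample intensity panel
(89 genes including Gapdh in the reference design) is log2-transformed,
batch-corrected by per-gene batch-mean centering, quantile-normalized,
expressed relative to Gapdh and to control levels, and tested per gene
with unpaired pooled-variance t-tests (α = 0.05, uncorrected by
default). Significant genes feed an over-representation analysis with
enrichment ratio `ER = m·N / (M·n)` (m mapped significant genes, M
family size, n significant-list size = 25 by default, N genome size =
18,985 by default) and an upper-tail hypergeometric p, plus a
redundancy map of genes across the top-K enriched families.

**Patch-clamp features.** From current-clamp step families (−100 to
+300 pA by 10 pA, 500 ms, 20 kHz): resting membrane potential, input
resistance (ΔV/ΔI least squares on spike-free sweeps), membrane time
constant (mono-exponential fit), capacitance (τ/R), rheobase, AP shape
properties on the first rheobase spike, I/V and I–F curves. Evoked-EPSC
series (0.1 Hz) around a 10 Hz/10 min induction protocol are normalized
per neuron by the baseline mean to quantify long-term depression (LTD).

**Shared statistics.** Unpaired pooled-variance t-test, two-/three-way
factorial ANOVA with Type II sums of squares (reported as F(df1, df2)
with p), and two-sided Fisher's exact test — all implemented against
closed-form / brute-force / reference-implementation oracles in the
test suite.

## Worked example

```bash
python examples/resilience_bootstrap.py
```

```
control  : mean SI ratio 0.95, 95% bootstrap CI [0.82, 1.07], resilient 4/10
n3_suppl : mean SI ratio 1.16, 95% bootstrap CI [1.07, 1.24], resilient 9/10
Fisher's exact test on resilient/susceptible counts: p = 0.06
negative control (labels permuted, 300 rounds): CI non-overlap rate 0.023
```

The supplemented defeated group's CI lies strictly above 1 — group-level
resilience — while the control defeated group straddles 1; the Fisher p
shows the raw 9/10-vs-4/10 split alone is not conclusive at these group
sizes, and the permutation control shows the bootstrap CI separation is
not an artifact of resampling. Other examples: `anxiety_scoring.py`,
`ephys_features.py`, `expression_ora.py`, `full_pipeline.py`, one per
capability.

A thin CLI wraps the same functions:

```bash
csdskit run --out results/ --seed 17        # full pipeline + report
csdskit synth --out data/ --seed 17         # synthetic inputs only
csdskit score --in data/behavior.csv --out scores.csv
csdskit ora --gmt data/families.gmt --genes sig.txt --n 18985
```

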