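# azfcnv

Read-depth calling of Y-chromosome **AZFc gr/gr deletions** from whole-genome
sequencing, with a truth-labeled simulator for validating the caller across
coverage levels and the case-control statistics (Firth bias-reduced logistic
regression, inverse-variance meta-analysis) needed to test the deletion's
association with disease.

## The problem

The AZFc region of the human Y chromosome is built from families of long,
near-identical repeats ("amplicon classes", conventionally named for colors)
plus inverted-repeat (IR) elements, each present at a fixed copy number in the
wild-type architecture. Non-allelic homologous recombination between repeats
generates copy-number variants; the most frequent, the **gr/gr deletion**,
removes one green and two red amplicon copies (taking two of the four *DAZ*
gene copies with it) and is carried hemizygously, since chrY is haploid.
Because the repeats are near-identical, conventional variant callers fail
here — but *dosage* survives: the total read depth over each class still
reflects how many copies a sample carries.

## The method

For each sample, class intervals are tiled with fixed-size bins (default
1000 bp) and mean per-base depth is computed per bin, counting all primary
alignments regardless of mapping quality (multi-mapped reads carry the dosage
signal). Per-class copy number is estimated against a single-copy control
region:

```
raw_cn[c] = reference_copies[c] * depth[c] / depth[control]
```

where `depth` is the per-class median of bin depths at ordinary coverage, or
the aggregate read-bases/length at ultra-low coverage (auto-selected below a
control depth of 2X). To remove batch effects and marker-specific
multiplicative biases, a **median-centering** adjustment rescales each class
so the cohort median lands on the wild-type copy number. Centered estimates
are rounded to integers and matched **exactly** against a catalog of
architecture signatures: the wild-type vector (gr/gr-negative), the gr/gr
vector (gr/gr-positive), or anything else (other AZFc CNV — excluded from
association testing, as are samples that cannot be normalized).

Carrier-phenotype association uses Firth's bias-reduced logistic regression
(Jeffreys-prior penalized likelihood, finite under complete separation —
the regime rare carriers and case-control imbalance produce), with profile
penalized-likelihood confidence intervals and penalized likelihood-ratio
p-values. Per-dataset log-OR estimates are combined by fixed-effect and
DerSimonian–Laird random-effects inverse-variance meta-analysis with
Cochran's Q and I² heterogeneity metrics.

## Worked example

Simulate a 300-sample cohort (12 gr/gr carriers) at 7.4X on the miniature
AZFc-style architecture, with per-class marker biases drawn log-uniformly
from [0.8, 1.25], then call and score it:

```python
from azfcnv import (miniature_azfc, make_bins, simulate_validation_cohort,
                    run_calling_pipeline, confusion, metrics)

defs, catalog = miniature_azfc()
bins = make_bins(defs, bin_size=1000)
truth, tables = simulate_validation_cohort(
    defs, bins, catalog, n_samples=300, n_carriers=12, coverage=7.4, seed=7)
calls = run_calling_pipeline(tables, defs, catalog)
m = confusion(truth, calls)
pm = metrics(m)
print(f"TP={m.tp} FP={m.fp} TN={m.tn} FN={m.fn}")
print(f"sensitivity={pm.sensitivity:.3f} specificity={pm.specificity:.3f}")
```

prints

```
TP=12 FP=0 TN=288 FN=0
sensitivity=1.000 specificity=1.000
```

i.e. at low coverage every injected carrier is recovered with no false
positives despite the marker biases. Pooling two published-style adjusted
odds ratios (given as OR with 95% CI) under the random-effects model:

```python
from azfcnv import estimate_from_ci, random_effects

studies = [estimate_from_ci(0.98, 0.54, 1.75, "ukb"),
           estimate_from_ci(1.69, 0.86, 3.33, "tecac")]
r = random_effects(studies)
print(f"combined OR={r.or_point:.2f} (95% CI {r.ci95[0]:.2f}-{r.ci95[1]:.2f}), "
      f"p={r.p:.2f}, Q={r.q_stat:.2f}, I2={r.i2_percent:.1f}%")
```

prints

```
combined OR=1.25 (95% CI 0.74-2.13), p=0.41, Q=1.42, I2=29.5%
```

— a non-significant combined estimate with mild between-study heterogeneity.

A CLI mirrors the library (`azfcnv simulate | downsample | bins | depth |
call | evaluate | assoc | meta`); every stage reads and writes documented
TSV/JSON files, so an alignment-backed depth source can replace the simulator
without touching the statistics.

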