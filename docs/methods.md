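# Methods

This note documents the models, numerical choices and assumptions behind
`azfcnv`, and what the simulation-based validation does and does not show.

## Dosage model and copy-number estimation

Each amplicon/IR class `c` has a wild-type copy number `R_c`; a sample
carrying `k_c` copies contributes read depth proportional to `k_c`. Depth is
quantified over fixed-size bins tiled left-to-right across each class
interval; a trailing partial bin is kept iff it is at least half a bin long,
so no bin ever exceeds the nominal size and short remnants do not add noisy
estimates. The default bin size is 1000 bp: at ~0.7X haploid coverage a
single-copy 1 kb bin still receives several reads in expectation
(0.7 × 1000/150 ≈ 4.7), while every class in the shipped architecture keeps
at least ~70 bins. Bin size is configurable.

Copies are estimated as `raw_cn[c] = R_c · depth[c] / depth[control]`, where
the control is a single-copy region, making the estimate invariant to overall
sequencing depth. Two per-class summaries are available:

* **MEDIAN_BIN** — median of per-bin mean depths; robust to localized
  artifacts; default at ordinary coverage.
* **AGGREGATE** — total read-bases / total tiled length; at ultra-low
  coverage the per-bin distribution is concentrated on 0–2 reads and the
  median collapses onto small integers, so the aggregate is used instead.

Mode auto-selection switches to AGGREGATE when the control aggregate depth is
below 2.0X; the active mode is recorded in every profile and overridable.
Depth extraction counts all primary alignments regardless of mapping quality:
the amplicon copies are near-identical, so multi-mapped (MAPQ 0) reads carry
the dosage signal, and filtering on MAPQ would null the method.

## Median centering

Marker-specific multiplicative biases (GC, mappability, library chemistry)
and batch effects distort `raw_cn` by a per-class factor shared across a
batch. Centering rescales each class so the cohort median equals `R_c`:

```
centered_cn[c, s] = cn[c, s] · R_c / median_s cn[c, s]
```

This assumes carriers are a minority (<50%) in every class so the cohort
median tracks the wild type; the assumption is checked, and a
`CenteringAssumptionWarning` is emitted whenever a class's cohort median
rounds away from its reference copy number (strong bias, or a
carrier-majority batch). Centering operates on the latest estimates, making
it exactly idempotent, and it is equivariant under per-class multiplicative
bias. Classes with cohort median 0 are left uncentered and flagged. Cohorts
of fewer than three samples cannot be centered; `single_sample_mode` skips
centering explicitly (flag recorded) rather than failing silently.

## Calling

Centered estimates are rounded to the nearest integer (exact halves away
from zero, floored at 0) and looked up in the signature catalog by **exact
match**. Near-misses are deliberately not force-assigned to the closest
signature: an unmatched vector becomes OTHER_AZFC_CNV, which is conservative
for association testing since those samples are excluded anyway (rarer AZFc
CNVs could confound a gr/gr–phenotype association if pooled with either
group). Normalization failures (zero control depth) surface as CALL_FAILED
statuses rather than exceptions, so one broken sample never aborts a cohort.
Catalog vectors are validated pairwise-distinct, so matching is unambiguous
and tie-breaking never arises.

The shipped AZFc definition (`data/azfc_amplicons.bed`,
`data/azfc_signatures.yaml`) encodes six amplicon classes, two IR classes and
a single-copy control; the gr/gr vector differs from wild type in green
(3→2) and red (4→2) only. The three known gr/gr breakpoint subtypes produce
this same dosage vector and are indistinguishable by copy number, so no
subtype resolution is attempted. Interval coordinates in the BED are
simplified placeholders: the file is editable configuration, transcribed
once from published architecture diagrams, and all tests requiring exactness
use synthetic catalogs so the transcription never gates correctness. IR
classes participate in the matching vector by default; a catalog restricted
to amplicon classes is equally valid configuration.

## Simulator

Per-bin read counts are Poisson:

```
count ~ Poisson(coverage · bin_length / read_length · (k_c / R_c) · bias_c)
```

with `mean_depth = count · read_length / bin_length`. Read placement,
sequence errors, GC/mappability structure and ancestry are *not* modeled;
dosage enters only through the mean, which is the signal the caller uses.
Binomial per-bin thinning emulates samtools-style read subsampling
(Poisson(λ) thinned with retention p is Poisson(pλ)), which is how the
ultra-low (~0.7X) condition is derived from the low-coverage (7.4X) one with
p = 0.1. A gamma-Poisson `dispersion` knob adds overdispersion when desired;
the default is pure Poisson, which suffices to reproduce the
coverage-dependent ordering of calling sensitivity. Consequently, passing
the titration tests shows the dosage→rounding→matching chain is correct and
correctly normalized under Poisson noise and multiplicative marker bias; it
does not certify performance on real alignments, where mappability structure
and non-Poisson noise can only degrade the margins.

Case-control cohorts draw carrier labels per arm: with control-arm carrier
frequency `q` and odds ratio `OR`, the case-arm frequency is
`p1 = OR·q / (1 − q + OR·q)`. The validation cohorts use 1194 samples with
exactly 47 carriers and cohort-wide per-class biases log-uniform in
[0.8, 1.25] — the sample size, carrier count and coverage grid
(30X / 7.4X / 0.7X) of the benchmark design the caller is meant to support.
All randomness flows through explicit integer seeds (child seeds derived via
`numpy` SeedSequence, kept below 2³¹); identical specs and seeds give
byte-identical tables, and seeds are echoed into output headers.

The miniature architecture used for simulation studies keeps the real class
structure and copy numbers but one 200 kb interval per class (200 bins at
the default bin size). At 0.7X in AGGREGATE mode this gives per-class
copy-number standard deviations of ≤ ~0.19, so the expected per-sample
misrounding rate is ~1%, concentrated in the highest-copy class — small
enough that the ultra-low-coverage sensitivity floor (0.90) is met with
margin, while cohort-scale suites stay inside a CI-friendly runtime.

## Evaluation metrics

Alongside standard sensitivity, specificity and FPR = FP/(FP+TN), the module
exposes `fpr_called_positive` = FP/(FP+TP): published benchmark tables for this class
of caller sometimes report "false positive rate" against the called-positive
denominator (1 FP among 48 positive calls → 0.021). Both conventions are
computed as distinct fields and never conflated; which one a report uses is
an explicit choice. Metrics with zero denominators are `None`, not 0 or NaN.
CALL_FAILED samples are excluded from the confusion matrix and counted
separately.

## Firth-penalized logistic regression

The fit maximizes `pl(β) = l(β) + ½·log det I(β)` (Jeffreys-prior penalty)
by Newton iteration on the Firth-modified score
`U*(β) = X′(y − π + h(½ − π))`, with `h` the hat-matrix diagonals, and
step-halving so the penalized log-likelihood never decreases across accepted
steps. Convergence: max |U*| < 1e−8 or step < 1e−8, capped at 100
iterations; rank-deficient designs are rejected with the offending column
named. Frequency-weighted (grouped) rows give identical likelihood,
information and hat values to the expanded per-individual representation, so
large cohorts with few covariate patterns are fit in microseconds; the
equivalence is verified in the tests.

Confidence intervals default to profile penalized likelihood (endpoints
where `2(pl_max − pl_profile)` crosses χ²₁(0.95), found by bracketing plus
Brent root-finding; constrained maximizations keep the penalty computed on
the full design). Wald intervals are available and the method used is always
recorded. P-values are penalized likelihood-ratio tests. The normal quantile
is carried as 1.959964 rather than 1.96 to minimize rounding drift against
printed intervals. For the unadjusted 2×2 analysis the chi-square is
Yates-corrected — the corrected statistic is what reproduces printed
p-values for this analysis style — with a Woolf log-scale CI; any zero cell
makes the OR undefined and the result redirects to the Firth fit instead of
emitting infinities. Covariates (typically principal components computed
upstream) are accepted as numeric columns; all-zero covariate columns are
dropped, as they carry no information and would only make the design
singular.

## Meta-analysis

Per-study inputs are log-ORs with SEs, reconstructed from printed ORs and
CIs where fitted SEs are unavailable (`se = (ln hi − ln lo)/(2·1.959964)`) —
reconstruction is the canonical path for reproducing published summary rows,
and its 2-d.p. input rounding is the dominant error term (±0.05 on a
combined OR near 1.25, ±0.10 on Q near 1.4). The between-study variance uses
the DerSimonian–Laird moment estimator, truncated at zero, so the
random-effects result collapses exactly onto the fixed-effect one whenever
Q ≤ k−1. I² = max(0, (Q−(k−1))/Q)·100. The I² confidence interval uses the
test-based log-H method where defined (the small-k variance branch is
undefined at k = 2 with small Q, in which case no interval is reported); I²
interval conventions differ enough across software that the interval is
labeled method-sensitive and treated as informational only. The DL pooling,
Q, τ² and I² are cross-checked against R's `metafor` in the test suite.

## Known limitations

* No GC/mappability correction and no segmentation: the caller operates on
  class-level dosage only, by design.
* Exact-match calling cannot genotype partial, mosaic or novel architectures;
  they fall into the excluded OTHER_AZFC_CNV pool.
* The simulator's Poisson noise is a lower bound on real-data noise; the
  optional dispersion knob is available but the shipped validation does not
  sweep it.
* Shipped BED coordinates are schematic; applying the caller to real
  alignments requires replacing them with build-specific intervals.
* Y-haplogroup structure, semen phenotype and family history — proposed
  modifiers of gr/gr penetrance — are outside the scope of the statistics
  implemented here.
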