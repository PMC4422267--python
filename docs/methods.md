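# Methods

## The design being modelled

A two-condition, five-stage small-RNA experiment in filling rice grains:
one sequencing library per condition (superior or inferior spikelets) per
stage (10, 15, 21, 27, 35 days after flowering, DAF), no sequencing
replicates. Each library carries a `total_clean_reads` figure that serves
as the denominator both for TPM normalization and for the exact count test
(N1, N2). Whether "total clean reads" counts redundant reads or distinct
tags is left to the caller — the package uses the supplied figure
consistently for both purposes, which is the property that actually
matters for internal coherence.

## Normalization and filtering

TPM = count × 10^6 / total_clean_reads, per library. Two post-processing
steps, in a fixed order:

1. **Zero floor (default 0.01 TPM).** Applied once, after normalization,
   to exact zeros only; a measured 0.005 TPM is data, not absence. The
   floor exists so fold-change ratios stay finite; it is deliberately far
   below any abundance of interest.
2. **Abundance filter (default 10 TPM, strict `>`).** An entity enters
   differential analysis only if it exceeds the threshold in at least one
   library. The configuration refuses `threshold <= floor`, which makes
   the kept/dropped partition provably invariant to flooring.

Read-length profiles (18–30 nt) and annotation-class composition
(rRNA/tRNA/snoRNA/snRNA/miRNA/unannotated, exact full-length matching in
that priority order) are summary utilities; alignment-based annotation is
upstream of this package.

## The exact two-library test

For counts `x` (superior, total N1) and `y` (inferior, total N2):

    p(y|x) = (N2/N1)^y (x+y)!/(x! y!) (1+N2/N1)^-(x+y+1)

This is the posterior predictive of a Poisson rate under a flat prior —
equivalently the negative-binomial pmf with `x+1` successes and success
probability `N1/(N1+N2)`. Implementation notes:

* evaluated in log space with `scipy.special.gammaln` and `logsumexp`;
  a direct factorial evaluation fails beyond a few hundred counts;
* `p_lower = Σ_{k≤y} p(k|x)`; `p_upper = Σ_{k≥y} p(k|x)` computed as the
  complement of the finite sum to `y−1`, so both tails contain the
  observed point and `p_lower + p_upper = 1 + p(y|x)`;
* `p_two_sided = min(1, 2·min(p_lower, p_upper))` — the standard
  doubled-tail convention;
* the pmf is swap-symmetric pointwise when N1 = N2 (`p(y|x) = p(x|y)`),
  but the tail sums are not (they cumulate over different variables), so
  the two-sided p is swap-symmetric only at `x = y`. Tests assert the
  true properties.

Fold change is `log2 R`, `R = floored inferior TPM / floored superior
TPM`, so negative values mean "higher in superior". The test consumes raw
counts with library totals; the fold change consumes floored TPM — each
quantity stays on the scale its definition implies. Classification:
`|log2 FC| > 1` gates everything; p in the closed interval [0.01, 0.05]
gives "differential", p < 0.01 "significant". No multiple-testing
correction is applied by default (a Benjamini–Hochberg helper exists but
is off), matching single-library deep-sequencing practice for this design.

Cross-stage consistency uses a classical two-tailed paired t-test over the
five per-stage (superior − inferior) differences, df = 4, computed on
log2 TPM (the scale profile heat maps are drawn on; raw TPM is available
via `log_scale=False`). Zero-variance differences with nonzero mean report
p = 0 with a `degenerate` flag; all-zero differences give t = 0, p = 1.
A direction ("consistently higher in …") is claimed only at p < 0.05.

## Novel-miRNA acceptance

Three independent, monotone criteria; any one suffices:

* **H** — max TPM strictly above 50 in some library;
* **F** — detected (TPM strictly above 0 by default) in **at least half**
  of the libraries;
* **S** — miRNA* passenger strand observed in at least one library.

The breadth rule is stated in prose as "more than half", but the published
13-candidate table accepts a candidate detected in exactly 5 of 10
libraries on breadth evidence alone, so the operative rule is evidently
at-least-half; the package defaults to that reading and offers
`strict_majority=True` for the literal one (under which that single
candidate fails). The packaged fixture records only *that* a star read
existed for the starred rows, not where; the loader places the flag in the
row's highest-TPM library as a labelled synthetic stand-in. Hairpin
validation and duplex geometry are upstream concerns.

## Logistic kinetics

Weight: `Y(t) = K/(1 + a·e^(−bt))` (K mg/grain; a dimensionless > 0;
b 1/day > 0). Rate: `V(t) = K·a·b·e^(−bt)/(1 + a·e^(−bt))²`, with
`t_peak = ln(a)/b`, `V_max = K·b/4`, and time to completion fraction f
`t_f = ln(a·f/(1−f))/b`.

Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`)
with a deterministic initialization — `K0 = 1.05·max(Y)`, then a linear
regression of `logit(Y/K0)` on t for `(a0, b0)` — parameter tolerance
1e-10, max 10 000 evaluations; non-convergence raises, never silently
passes. At least 4 points are required (3 parameters); inverse-variance
weighting is available when replicate SDs are supplied. The asymmetry
index (moment skewness of V over [0, t_99]) is **descriptive only**: a
pure logistic rate curve is a symmetric bell around t_peak, so the index
measures where the peak sits within the filling window, not intrinsic
curve asymmetry.

## Profiles

Clustering of log2 profiles: agglomerative, average linkage, distance
1 − Pearson r, flat cut at k clusters or a distance threshold (default
0.5). Deterministic, and invariant (as a partition) to input order. The
double normalization divides each sample's target quantity by its
reference-RNA quantity, then by the same ratio in the baseline sample
(superior, 10 DAF), which is exactly 1.0 by construction; amplification-
efficiency correction is not modelled. Correlations are computed on the
log2 scale for TPM inputs and raw scale for relative-expression inputs;
constant series return NaN, never 0.

## Synthetic data generator

Defaults are the modelled study's conditions:

| parameter | default | why |
|---|---|---|
| design | 2 conditions × 5 stages, 1 library each | the field design |
| library size | uniform 1e5–2e5 reads | the real ~1.1–1.8×10^7 clean reads scaled down for desk-scale runs; configurable to 10^7 |
| baseline TPM | log-normal, median ≈ e^3 ≈ 20, σ_log 1.5 | typical skewed miRNA abundance spectrum |
| DE fraction / effect | 0.2, |log2 FC| uniform 1–3, random sign | "configurable fraction with stated fold changes" |
| counts | negative binomial, var = μ + 0.05·μ² | small-RNA libraries are overdispersed; dispersion 0 gives the Poisson limit for calibration studies |
| length mix | 58.28% 24-nt, 18.30% 21-nt, remainder even | the published pooled percentages |
| kinetics superior | K=21, a=41, b=0.286 | V_max = 1.50 mg/grain/day at ~13 DAF, ~95% filled by ~23 DAF |
| kinetics inferior | K=16, a=27, b=0.15 | V_max = 0.60 mg/grain/day at ~22 DAF, ~95% filled by ~42 DAF |
| weight noise | Gaussian, sd 0.4 mg | a few percent of K, typical replicate scatter |
| target coupling | log-linear slope −1, log-noise sd 0.1 | strong, simple anti-correlation |

The kinetics defaults were chosen to reproduce the reported condition
contrast through the closed forms (peak rates ≈ 1.5 vs 0.6 mg/grain/day;
filling essentially complete by ~3 vs ~6 weeks). Condition effects apply
to the inferior libraries at every stage; each entity's true fold change,
baseline, coupling and kinetics parameters are recorded in `GroundTruth`.

What the generator does **not** emulate: sequencing error, adapter
artifacts, mapping ambiguity, stage-varying effect sizes, correlated
miRNA families, and biological replicate structure. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under its own sampling assumptions, not the reproduction of any particular
field dataset.

## Validation studies (`spikefill.studies`)

* **Oracle agreement** — the log-gamma statistic vs a 60-digit
  arbitrary-precision recurrence, full grid x, y ≤ 100 across all ordered
  pairs of totals {10^4, 10^6, 2×10^6} (91 809 points); observed worst
  relative error ~6×10^-13. An exact-rational (`fractions.Fraction`)
  oracle and the negative-binomial identity serve as further independent
  routes in the unit tests.
* **Tail normalization** — Σ_y p(y|x) vs 1, truncated 40 SD past the
  negative-binomial mean (remainder ≪ 1e-9).
* **Null calibration** — 2 000 entities, no effects, Poisson-limit
  dispersion, baselines near 100 TPM, library size 10^6: fraction of
  entity-stage tests with p < 0.05 ≈ 0.044–0.047 (the discrete doubled
  tail is conservative); the full classifier with its fold-change gate
  calls < 1%.
* **Spiked recovery** — 200 replicates × 10 entities at true |log2 FC| = 2
  and baselines ≥ 100 TPM: > 99% of entity-stage comparisons labelled,
  mean |FC error| ≈ 0.27.
* **Kinetics recovery** — 100 seeds at 2%-of-K noise on the 9-point grid:
  median K error ≪ 1%, median b error ~1–2%.
* **Worked numbers** — the direction percentages (94.50%, 11.88%, 6.88%)
  recomputed by `summarize_de` from the published counts (103 of 109 DE at
  15 DAF higher in superior; 19 and 11 of 160 consistently higher by the
  paired test), and the packaged candidate table (13 accepted; exactly
  miRn1 and miRn2 under the > 50 TPM criterion alone).

Problem sizes were chosen so the full battery completes in roughly ten
seconds on one core; they are the package's validation design, stated here
so the numbers are interpretable.

## Known limitations

* The exact test assumes counts proportional to library size under the
  null; with strong overdispersion (dispersion ≫ 0) it is anti-
  conservative, which is why calibration studies run at the Poisson limit
  and why the generator exposes dispersion explicitly.
* Percentages of DE direction are computed per stage from single-library
  comparisons; with no replicates, biological variance is not separable
  from sampling variance.
* The logistic family cannot represent genuinely asymmetric rate curves;
  the asymmetry index is a window statistic, not a shape test.
* Headline dataset-level counts from the original ten libraries (e.g. how
  many of 457 known miRNAs pass filters) are functions of unpublished raw
  data and are out of scope; the machinery, not the dataset, is what this
  package reproduces.
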