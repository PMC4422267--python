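# spikefill

Small-RNA expression dynamics between **superior and inferior rice
spikelets** during grain filling.

Rice grains on a panicle do not fill synchronously: superior spikelets
(apical, on primary branches) flower earlier, fill fast, and end up heavy
and plump, while inferior spikelets (proximal, on secondary branches) fill
late, slowly, and often incompletely. Small RNAs — miRNAs in particular —
are prime candidates for regulating this asymmetry. `spikefill` implements
the statistical machinery for a ten-library design (two spikelet classes ×
five grain-filling stages at 10, 15, 21, 27 and 35 days after flowering,
one deep-sequenced small-RNA library each) together with a synthetic-data
generator that emulates the design with known ground truth, so the whole
pipeline is testable without any external download.

## What it computes

**Exact two-library count test (Audic–Claverie statistic).** With `x`
counts of a miRNA among `N1` total clean reads in the superior library and
`y` counts among `N2` in the inferior library, the probability of `y`
given `x` is

```
p(y|x) = (N2/N1)^y · (x+y)! / (x! y!) · (1 + N2/N1)^-(x+y+1)
```

evaluated in log space via the log-gamma function (factorials at
`x + y ~ 10^3` overflow any float). Lower/upper tails cumulate over `y`
(the upper tail includes the observed point); the two-sided p-value
doubles the smaller tail. A miRNA is **differentially expressed** when
|log2 R| > 1 (R = inferior TPM / superior TPM, zeros floored at 0.01 TPM)
with p in [0.01, 0.05], and **significantly** so when p < 0.01.

**TPM workflow.** Counts are scaled to transcripts per million by each
library's total clean reads; exact zeros are floored to 0.01 TPM; entities
never exceeding 10 TPM in any library are excluded from differential
analysis. Read-length and annotation-class summaries are included.

**Novel-miRNA criteria.** A hairpin-validated candidate is accepted when
it is highly expressed (> 50 TPM in some library), detected in at least
half of the libraries, or supported by a miRNA* passenger-strand read. The
13-candidate published table ships as a packaged fixture.

**Logistic grain-filling kinetics.** Grain dry weight follows
`Y(t) = K / (1 + a·e^(-bt))`; the filling rate is its derivative
`V(t) = K·a·b·e^(-bt) / (1 + a·e^(-bt))²`, peaking at `t = ln(a)/b` with
`V_max = K·b/4`. Fitting is deterministic nonlinear least squares.

**Profiles.** log2 heat-map matrices, average-linkage hierarchical
clustering on correlation distance, qRT-PCR-style double normalization
(reference RNA, then the superior 10-DAF sample set to 1.0), and
miRNA–target anti-correlation.

## Worked example

```
$ spikefill simulate --seed 17 --out demo --n-mirnas 200
$ spikefill detest --counts demo/counts.tsv --meta demo/meta.tsv --out demo/de.tsv
106 differential calls across 910 entity-stage tests
$ spikefill kinetics --series demo/weights.tsv
superior: K=21.05 mg, a=28.63, b=0.2580/day, V_max=1.358 mg/day at 13.0 DAF
inferior: K=15.65 mg, a=25.71, b=0.1548/day, V_max=0.605 mg/day at 21.0 DAF
$ spikefill novel
...
13 of 13 candidates accepted
```

The simulated experiment seeded 20% of 200 miRNAs with true fold changes;
after the > 10 TPM filter, 910 entity-stage comparisons yield 106
differential calls (`demo/de.tsv` holds per-test TPM, R, log2 FC, both
tails and the label). The kinetics fits recover the generator's
grain-filling contrast: the superior curve peaks at ~1.4 mg/grain/day
around 13 DAF, the inferior curve at ~0.6 mg/grain/day around 21 DAF. The
packaged candidate table is accepted in full, two candidates by the
> 50 TPM criterion alone.

`spikefill run --seed 17 --out run/` executes the whole pipeline
(simulate → normalize → test → novel → kinetics → profiles) and writes
per-stage TSVs plus a single `summary.json`; identical config and seed
reproduce it byte for byte.

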