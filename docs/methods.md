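# Methods

`mireqtl` screens genetic variants for effects on miRNA array
expression in a cancer-case cohort. This note records the statistical
model, the package's tunable parameters, what the synthetic-data
generator does and does not emulate, the numerical choices, and known
limitations.

## The screening model

For each SNP *s* and miRNA *j*, the analyzed samples are the cases with
a non-missing genotype call for *s* (per-SNP complete-case deletion;
per-SNP sample counts therefore vary). The genotype is collapsed to a
binary indicator `g` under the SNP's pre-specified inheritance model:

- **dominant** — carriers of the variant allele (1 or 2 copies) versus
  reference homozygotes;
- **recessive** — variant homozygotes versus all other genotypes.

A SNP whose indicator is constant in the analyzed samples is
untestable; it is skipped with a logged reason, never aborting a scan.

The response for measured tissue is `y = log2(normalized signal + 1)`;
for the paired differential mode it is the raw carcinoma − normal
difference of normalized signal (see below). The two nested
least-squares fits are

    null:  y ~ 1 + age + sex + race
    full:  y ~ 1 + age + sex + race + g

with age centered and sex/race treatment-coded against the largest
observed level (a level that vanishes after subsetting simply
contributes no column; any residual rank deficiency is resolved by
QR-pivoting column pruning with a logged note). Evidence for the
genotype term is the 1-df nested F statistic

    F = (RSS_null − RSS_full) / (RSS_full / (n − p_full)).

### Residual-bootstrap p-values

The F statistic is referred to a null distribution built by resampling
residuals under the no-association null: fit the covariate-only model,
center its residuals, and for b = 1..B draw `e*_b` i.i.d. with
replacement and score `y*_b = X_null β̂_null + e*_b`. Because F is
invariant to anything in the column space of the null design, the
implementation scores the resampled residual vectors directly — an
exact algebraic shortcut, not an approximation. The p-value is

    p = (1 + #{F*_b ≥ F_obs}) / (B + 1),

so p never reaches zero, its resolution is 1/(B+1), and ties count as
exceedances (the conservative convention). `B` defaults to 10,000.
Raw residuals are resampled by default; leverage-adjusted resampling
(`e_i / sqrt(1 − h_ii)`) is available via
`BootstrapConfig(residual_scheme="leverage")`. For balanced designs of
this size the two schemes are practically indistinguishable (a unit
test checks the leverage scheme's calibration too).

Each (SNP, miRNA, stratum, tissue) task derives its bootstrap seed from
the master seed and a hash of the task key, so results are independent
of execution order.

### Normalization and probe filtering

Arrays are put on a common scale by multiplying every sample by
`m / Q75_i`, where `Q75_i` is that sample's 75th percentile of total
gene signal (linear interpolation between order statistics — the common
statistical default; the equal-Q75 invariant holds under any one fixed
convention) and `m` is the median of the per-sample 75th percentiles.
Scaling factors are computed from **all** probes, before filtering.
When normal and carcinoma arrays are processed together, `m` is the
median of the **pooled** per-sample Q75s of both matrices, so the two
tissues land on one shared scale — required before forming paired
differences.

Probes are retained when "expressed" in at least 20% of the analyzed
samples (`min_expressed_proportion`, configurable). "Expressed"
defaults to the platform's detection flag when a flag matrix is
supplied and to signal > 0 otherwise; a fixed signal threshold rule is
also available. Retention is recomputed per stratum on that stratum's
own samples, so the combined, colon-only and rectal-only analyses can
keep different probe sets.

### Paired differential mode

For cases with both arrays, the differential matrix is the per-sample
carcinoma − normal difference of normalized (unlogged) signal, paired
by identical sample id. Differences are analyzed untransformed and
group means are reported on the difference scale, which is why
differential results can be negative. Detection flags for a difference
are the OR of the two tissues' flags.

### Multiple testing and decisions

The adjustment family is one SNP's full scan within a stratum and
tissue, i.e. m = number of retained miRNAs for that stratum.
BH step-up adjusted p-values are computed from the definition
(`adj(i) = min_{j≥i} min(1, p(j)·m/j)` over the ascending sort);
q-values are the single-λ Storey estimate `q = π̂0 · adj` with
`π̂0 = min(1, #{p > 0.5}/(m/2))` floored at 1/m — deterministic, unlike
the spline-smoother variant. An association is **important** when its
BH-adjusted p < 0.09; a secondary flag marks q < 0.05. Whether the
original screen adjusted per SNP or globally across all SNPs is not
derivable from the printed tables alone; the per-SNP family is adopted
because the printed shared adjusted values are consistent with
m ≈ the per-stratum retained probe count.

### Group means and direction

`mean_ref` / `mean_var` are arithmetic genotype-group means on the
normalized signal scale (difference scale for differential tissue),
not back-transformed log2 means. Direction is Upregulated iff
`mean_var > mean_ref`; an exact tie is labelled Downregulated and
logged, keeping the binary label deterministic.

## Synthetic cohorts

The generator (`mireqtl.simulate`) emulates the features of the study
data that the statistics interact with:

- **Cohort**: 1188 cases by default, 1141 of them with a paired
  carcinoma array; 689:499 colon:rectal split; site-specific age
  (65.3 ± 9.1 / 61.8 ± 11.1 years, truncated to 30–79), sex
  (55.6% / 59.3% male) and race/ethnicity mixes matching the cohort's
  descriptive table.
- **Genotypes**: per-SNP MAF drawn uniformly from (0.1, 0.5) by
  default; calls ~ Binomial(2, MAF) per sample (Hardy-Weinberg);
  4% missingness completely at random, matching the shortfall of
  per-SNP Ns below the cohort size. Inheritance models are assigned
  dominant/recessive with equal probability.
- **Expression**: per-probe log2 baseline ~ U(2, 10) and residual SD
  ~ U(0.8, 1.2); age/sex/race each explain ~1% of residual variance
  (small but nonzero, so covariate adjustment is exercised rather than
  vacuous); raw signal is 2^log2 multiplied by a lognormal per-sample
  array-scale factor (σ_log = 0.25) that the normalization must remove.
- **Dropout**: per-probe detection-dropout rates ~ Beta with mean 0.20
  and concentration 2, so a realistic minority of probes fall below the
  20% filter; dropped-out cells have detection false and signal 0.
- **Carcinoma**: probe-specific Gaussian tumor shift on the log2 scale
  (SD 1.0), producing both positive and negative raw-scale paired
  differences; carcinoma-only planted effects surface in the
  differential analysis, while shared effects cancel in the difference.
- **Planted effects**: a configurable fraction of miRNAs (default 10%)
  receives a signed SNP effect in residual-SD units, recorded in a
  truth registry that calibration and recovery tests consume.

Not emulated: linkage disequilibrium between SNPs, miRNA–miRNA
correlation blocks, batch effects beyond the per-sample scale factor,
and formalin-fixation artifacts. Passing tests therefore demonstrate
the statistical machinery's calibration under the model's assumptions,
not robustness to every artifact of real array data.

## Calibration experiments and problem sizes

The package's headline calibration (also recomputed by
`scripts/acceptance.py`) runs the full pipeline on 100 replicate
one-SNP families with m = 400 miRNAs, n = 300 samples, MAF 0.3, 10% of
miRNAs carrying effects of 0.5–1.5 residual SD, and B = 500 bootstrap
replicates, then averages the realized false-discovery proportion among
associations flagged at BH-adjusted p < 0.09 (families with no
discoveries contribute 0, the quantity BH controls in expectation).
Typical result: mean FDP ≈ 0.078 (SEM ≈ 0.007), consistent with the
theoretical ceiling π0 × 0.09 = 0.081.

The test suite additionally checks: type-I error and p-value uniformity
under a global null (n = 100, 500 pairs, B = 2000); agreement of the
bootstrap p with the closed-form F tail on Gaussian data (n = 60,
B = 10,000); power against a planted 1.0-SD effect versus the
noncentral-F closed form (n = 600, MAF 0.3); and full recovery of
planted effects ≥ 1.5 SD with FDP control. These sizes were chosen so
each experiment's Monte-Carlo error is small relative to the tolerance
it checks while the whole suite stays lightweight.

The recovery experiment plants effects on 2% of probes with dropout
disabled: the criterion is that every planted pair is flagged, which
presumes planted probes survive filtering, and scaling normalization
itself assumes the bulk of probes are unshifted (next section).

## Numerical choices

- log2 offset: `log2(signal + 1)`, so zero signal maps to zero; the
  offset is configurable.
- Degenerate fits: a response already explained by the covariates gives
  F = 0; a response whose *remaining* variance is absorbed by the
  genotype indicator (perfect separation) raises a degenerate-fit
  error, and the pair is skipped with a log entry. A degenerate
  bootstrap resample (constant vector) counts as an exceedance.
- A genotype indicator numerically collinear with the covariates makes
  the SNP untestable (skipped, logged).
- RSS values are computed via an orthonormal basis of the null design;
  tiny negative round-off is clamped at zero, and tolerances are
  relative to ‖y‖².
- Exchange files round-trip floats bit-exactly (shortest-repr writing,
  correctly-rounded parsing).

## Known limitations

- **Global-signal contamination of scaling normalization.** If a large
  asymmetric share of probes truly shifts with genotype (measured here:
  10% of probes at 1.5–2.5 residual SD), the per-sample Q75 — and hence
  the scaling factor — becomes genotype-correlated, leaking a small
  coordinated shift into every null probe and inflating the realized
  FDP. This is a property of any global-quantile normalization, not of
  the bootstrap test; it is negligible at the effect sizes and
  fractions of the calibration study (10% at 0.5–1.5 SD) but worth
  remembering when interpreting dense strong-signal scenarios.
- P-values are conditionally discrete with resolution 1/(B+1); at
  B = 500 the smallest attainable BH-adjusted value in a family of m
  tests is m/(501·rank), which bounds how many discoveries a small
  family can declare.
- The paired differential response is analyzed on the raw difference
  scale, so probes with very large absolute signal dominate the
  reported means (though not the test, which is per-probe).
- BH's FDR guarantee assumes independence or positive regression
  dependence across miRNAs within a family; strong negative dependence
  is outside the guarantee (and outside the generator's model).
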