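# Methods

This note records the statistical model the package implements, the
default parameter choices and their rationale, and the numerical
decisions that matter for correctness and speed.

## Causal model

The analysis targets the effect of log red-blood-cell folate (the
exposure, `a`) on per-CpG methylation (the outcome, `y`, on the
arcsine-square-root scale) using the additively coded MTHFR trans
variant count (`z ∈ {0, 1, 2}`) as an instrument, adjusting for one
measured covariate (conception planned, `c`):

```
first stage:   a = α0 + α1·z + α2·c + αc·u + εx
second stage:  y = β0 + β1·a + β2·c + βc·u + εy
```

`u` is a latent standard-normal confounder the estimators never see.
The instrument assumptions are the usual three: `z` causes `a`
(relevance, reported via the first-stage F statistic), `z` affects `y`
only through `a` (exclusion), and `z` shares no cause with `y`
(independence; plausible for genotype by random allele assortment).

Because there is exactly one instrument the model is just-identified:
2SLS equals the ratio-of-coefficients (Wald) estimator, which the test
suite exploits as an oracle.

### Additive instrument coding

The two MTHFR variants are carried on opposite haplotypes in this
model, so per-subject variant counts satisfy `g677 + g1298 ≤ 2`. The
generator enforces this by drawing two haplotypes per subject from the
three-state distribution (no variant, 677 variant, 1298 variant);
`additive_code` validates the constraint and raises rather than
silently recoding a cis configuration.

## Synthetic cohort generator

Scope: the generator reproduces the *statistical structure* the
analysis assumes — it makes no attempt at biological realism beyond
that (no linkage structure beyond the two-SNP haplotype, no batch
effects, no cell-type heterogeneity, probe positions drawn uniformly).

Defaults (`CohortSpec`): `n=50`, `maf677=0.33`, `maf1298=0.23`
(typical European-ancestry frequencies), `alpha0=6.50`, `alpha1=0.12`,
`alpha2=0.05`, `sigma_x=0.26`, `p_planned=0.5`, `alpha_c=0`. These are
calibrated so a default cohort shows log folate values spanning roughly
6.1–7.5 with median near 6.7 and a modest first-stage F (≈5 in
expectation at n=50) — i.e. a realistically weak instrument. Tests
that need a *strong* instrument say so explicitly
(`alpha1=0.6, sigma_x=0.15` gives F well above 10).

Methylation is generated on the arcsine scale,
`y = clip(β0 + β1·a + β2·c + βc·u + σy·ε, 0, π/2)`, then mapped to
β-values by `sin²(y)`. When a nonzero `β1` is planted,
`EffectProfile.with_signal(..., recenter_at=ā)` shifts the intercept so
the probe's mean stays put and the clip boundary is not saturated.
Array artifacts are injected as disjoint probe categories with exact
counts: sex-chromosome probes, cross-reactive probes, probes with one
missing value, and bimodal "distractor" probes that the normality
filter should remove. Optional fluorescence intensities are emitted at
a fixed total intensity `S=4000`, so recovered β-values are capped at
`S/(S+100)`; `β = M/(M+U+100)` round-trips exactly below the cap.

`array27k_panel_fractions()` returns artifact fractions chosen so a
large panel loses ≈14% of probes to the sex/cross-reactive
restriction and the normality filter then removes ≈27% of
complete-case probes — proportions typical of a 27K-style array
cascade.

## Preprocessing

The probe cascade applies, in order: autosome restriction,
cross-reactive removal, complete-case filtering, then a per-probe
Shapiro–Wilk test at α=0.05 on the transformed values. The
`FilterReport` records counts and removed probe ids per stage and
validates that they reconcile. Shapiro–Wilk comes from
`scipy.stats.shapiro` (valid for 3 ≤ n ≤ 5000); constant probes are
removed with a warning since the test is undefined for them. Under a
truly normal null the filter removes ≈5% of probes by construction —
a deliberate property of using a fixed-α normality screen.

## Estimation

`ols_fit` / `tsls_fit` are closed-form with classical homoskedastic
standard errors. The 2SLS second stage regresses `y` on the *fitted*
exposure, but residuals for the error variance are recomputed with the
*observed* exposure (`σ² = ‖y − X_obs·coef‖²/(n−p)`,
`cov = σ²(X̂'X̂)⁻¹`): naive OLS-on-fitted standard errors are
inconsistent. Inference uses the t distribution on n−p degrees of
freedom.

Coefficients are computed by SVD least squares (`numpy.linalg.lstsq`)
rather than by solving the normal equations: with a weak instrument the
fitted-exposure design is nearly collinear and the normal equations
square its condition number, costing ~7 digits in unlucky draws. The
normal-equations inverse is still used for the covariance, where that
precision is ample.

### Genome-wide scan

The first stage does not depend on the probe, so it is fit once; all
second-stage coefficient vectors and corrected standard errors then
come from one shared-design multi-outcome pass
(`(X'X)⁻¹X'Y` with residuals against the observed-exposure design).
This is algebraically identical to looping `tsls_fit` per probe (tested
to ~1e-13) and makes a 20,000-probe scan a few milliseconds. Results
are ranked by TSLS p-value with deterministic tie-breaking (|estimate|
descending, then probe id). Significance defaults to unadjusted
p<0.05 — the scan reports per-locus evidence, with optional Bonferroni
and Benjamini–Hochberg columns.

### Bootstrap

Effects on the untransformed β scale get pairs-bootstrap percentile
95% CIs: subjects are resampled with replacement, each resample refit
by 2SLS, and the 2.5/97.5 empirical percentiles reported. Resamples
with a constant instrument (possible at n=50 with a rare allele) are
redrawn with a warning. All replicates are solved in one einsum-batched
pass over stacked 3×3 normal-equation systems (~0.13 s per 1,000
replicates), verified against the scalar path. A minimum of 200
replicates is enforced — percentile CIs below that are noise.

## Confounding sensitivity simulation

For each significant locus the fitted first- and second-stage
coefficients are taken as population truth, and datasets are
regenerated around the *observed* anchors (genotype, conception, log
folate) with a fresh confounder `u` injected at loading `level` into
both equations.

Two generating modes exist and answer different questions:

- **Literal mode** (default, `y_from_simulated_x=False`): the outcome
  is generated from the observed folate anchor while the estimators see
  a separately simulated noisy exposure. Both estimators are then
  attenuated toward the null even at level 0 — the simulated exposure
  is a noisy proxy for what generated the outcome. This is the mode the
  acceptance check exercises: across all effect sizes the instrumented
  estimator has the smaller median bias but the wider interquartile
  range ("more accurate but less precise").
- **Conventional mode** (`y_from_simulated_x=True`): the outcome is
  generated from the simulated exposure, so at level 0 both estimators
  are unbiased, and OLS bias then grows monotonically with the loading
  while MR stays centered. Use this mode to isolate pure
  confounding bias.

Each replicate's random stream is keyed by
`(seed, crc32(locus_id), round(level·10⁴), replicate)`, so replicates
are reproducible independent of execution order and loci/levels never
share draws. The replicate fits are batched exactly as in the
bootstrap (~0.4 s per 10,000 replicates at n=50); a scalar reference
loop is retained for cross-checking.

## Enrichment

Significant probes map to their nearest gene (first listed symbol,
deduplicated in order). Each category is tested with the hypergeometric
upper tail `P(X ≥ a)` against the analyzed-gene universe and
summarized by the sample odds ratio `ad/bc` (∞ when `bc=0` with a
nonzero numerator, NaN when the table degenerates). When an explicit
universe is supplied it is used as given — genes without any category
still count toward N. The test is *unconditional*: a DAG-conditional
variant (conditioning parent terms on significant children) needs the
ontology graph and is deliberately out of scope; output headers carry
the `hypergeometric (unconditional)` label so downstream consumers
know which test was run.

## Determinism

Every public generator and simulation takes an explicit seed; derived
seeds are produced through `numpy.random.SeedSequence` and kept below
2³¹. Pipeline runs with the same configuration are byte-identical
(tested), and per-locus bootstrap seeds derive from the scan seed and
the locus rank so adding probes does not reshuffle unrelated CIs.

## Problem sizes

Default sizes are package choices balancing statistical resolution
against desk-scale runtime: cohorts of 50 (analysis) or 50,000
(consistency checks), panels of 10²–10⁴ probes, 1,000 bootstrap
replicates, 10,000 confounding replicates per locus × level, and
500-replicate coverage experiments. The full test suite runs in well
under a minute for the unit layers plus ~15 s for the statistical
acceptance layer; the acceptance script completes in ~20 s.
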