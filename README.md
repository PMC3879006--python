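# mrewas

Mendelian-randomization epigenome-wide association scanning.

`mrewas` estimates the causal effect of a continuous exposure — log
red-blood-cell folate — on per-CpG DNA methylation, using an additively
coded MTHFR genotype (C677T + A1298C trans variant count) as an
instrumental variable. It implements the full analysis stack:

- **Synthetic cohort generator** — haplotype-constrained biallelic
  genotypes (so the two variant counts can never sum past 2), a linear
  first stage for log folate with an optional latent confounder, and
  Infinium-style methylation β-values (`M/(M+U+100)`) with sex-probe,
  cross-reactive, missing-value, and non-normal "distractor" artifacts.
- **Preprocessing** — probe restriction cascade (autosomes only → drop
  cross-reactive → complete cases), arcsine-square-root variance
  stabilization `y = arcsin(√β)`, and a per-probe Shapiro–Wilk
  normality filter, with a reconciled filter report at every stage.
- **Genotype QC** — Hardy–Weinberg chi-square tests, additive
  instrument coding with explicit trans-haplotype validation, and
  nested-model F tests (instrument strength; codominant vs additive).
- **MR engine** — two-stage least squares with the observed-exposure
  residual correction for second-stage standard errors, a vectorized
  genome-wide scan (single linear-algebra pass, numerically identical
  to per-probe fits), OLS comparison, and pairs-bootstrap percentile
  CIs for effects on the untransformed β scale.
- **Confounding sensitivity simulation** — regenerates each significant
  locus from its fitted coefficients thousands of times while injecting
  a shared latent confounder into both equations, summarizing the
  median bias and spread of the MR and OLS estimators.
- **Enrichment** — nearest-gene assignment and unconditional
  hypergeometric over-representation with sample odds ratios.
- **Pipeline + CLI** — a YAML-configured end-to-end driver
  (`mrewas run`) plus per-stage subcommands, writing a run manifest
  that ties all artifacts together.

## Worked example

```python
import mrewas as m

# 50-subject cohort with a deliberately strong instrument
cohort, u = m.gen_cohort(
    m.CohortSpec(n=50, alpha1=0.5, sigma_x=0.15, alpha_c=0.1, seed=7))
cohort.log_rbc_folate.describe()        # min 6.36, median 7.05, max 7.77

# instrument QC
g = cohort.g677.to_numpy()
m.hwe_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
# chi2=0.081, p=0.776 -> no HWE violation
m.first_stage_f(cohort)                 # F=259.8, p<1e-4: strong instrument
```

Generate a 500-probe panel with 5 planted causal probes, preprocess,
and scan:

```python
import numpy as np

ann, miss = m.gen_probe_panel(500, 0.105, 0.036, 0.015, seed=7)
rng = np.random.default_rng(7)
prof = m.EffectProfile(
    beta0=rng.uniform(0.15, 1.35, 500), beta1=np.zeros(500),
    beta2=np.full(500, 0.02), beta_c=np.full(500, 0.1),
    sigma_y=np.full(500, 0.06))
clean = (~ann.chromosome.isin(["X", "Y"]) & ~ann.cross_reactive
         & ~miss).to_numpy()
idx = rng.choice(np.flatnonzero(clean), size=5, replace=False)
prof = prof.with_signal(idx, beta1=0.4,
                        recenter_at=float(cohort.log_rbc_folate.mean()))
panel = m.gen_methylation(cohort, u, prof, ann, seed=7,
                          missing_probes=miss)

matrix_y, report = m.preprocess_panel(panel)
report.counts
# {'input': 500, 'after_autosome_restriction': 448,
#  'after_cross_reactive_removal': 430, 'after_complete_case': 422,
#  'after_normality_filter': 411}

results, comp = m.genomewide_scan(
    matrix_y, cohort, betas=panel.betas.loc[matrix_y.index],
    bootstrap_reps=1000, seed=7)
int(results.significant.sum())          # 23 loci at p<0.05 (4/5 planted)
round(comp.pearson_r, 3)                # 0.973 TSLS-vs-OLS correlation
results.head(1)
#   probe_id  tsls_estimate  tsls_se  tsls_p  delta_beta  ci_low  ci_high
# cg00000417         0.3075   0.0469     0.0      0.2631  0.1612   0.3428
```

Or drive everything from the command line:

```bash
mrewas run --config run.yaml      # simulate -> preprocess -> qc -> scan
                                  #   -> confounding sim -> enrichment
mrewas simulate --out sim/ --seed 7
mrewas qc --cohort sim/cohort.csv
```

## Layout

```
src/mrewas/
  synthetic.py     cohort / panel / annotation generators
  preprocess.py    beta math, filter cascade, normality filter
  genotype_qc.py   HWE, additive coding, nested F tests
  mr.py            OLS, 2SLS, scan, bootstrap, comparison
  confounding.py   sensitivity simulation and sweep
  enrichment.py    nearest-gene mapping, hypergeometric test
  io.py            delimited-text readers/writers (CSV/TSV/BED)
  config.py        YAML run configuration with fail-fast validation
  pipeline.py      end-to-end orchestration and manifest
  cli.py           click command group
docs/methods.md    modeling and numerical decisions
scripts/acceptance.py
tests/
```

See `docs/methods.md` for the statistical model, parameter defaults,
and the reasoning behind the numerical choices.
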