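"""Pipeline orchestration: simulate -> preprocess -> qc -> scan (with
bootstrap CIs) -> confounding simulation -> enrichment, from one
validated configuration, with a run manifest tying stage outputs
together."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from mrewas import io as mio
from mrewas.config import RunConfig
from mrewas.confounding import SimulationSpec, sweep
from mrewas.enrichment import TEST_LABEL, enrich, nearest_gene_assignment
from mrewas.genotype_qc import (codominant_vs_additive_f, first_stage_f,
                                hwe_test)
from mrewas.mr import genomewide_scan, tsls_fit
from mrewas.preprocess import preprocess_panel
from mrewas.synthetic import (CohortSpec, EffectProfile, MethylationPanel,
                              gen_cohort, gen_methylation, gen_probe_panel,
                              make_gene_term_map)

__all__ = ["run_all"]

log = logging.getLogger("mrewas")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(fh)
    if not any(type(h) is logging.StreamHandler for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"stage": name, **info})
    log.info("stage %-12s %s", name, info)


def simulate_stage(cfg: RunConfig, out: Path) -> dict:
    """Generate cohort, annotations, methylation, and gene-term map."""
    s = cfg.simulate
    spec = CohortSpec(n=s.n_subjects, maf677=s.maf677, maf1298=s.maf1298,
                      alpha0=s.alpha0, alpha1=s.alpha1, alpha2=s.alpha2,
                      alpha_c=s.alpha_c, sigma_x=s.sigma_x,
                      p_planned=s.p_planned, seed=cfg.seed)
    cohort, u = gen_cohort(spec)

    ann, missing_mask = gen_probe_panel(
        s.n_probes, s.frac_sex, s.frac_cross_reactive, s.frac_missing,
        seed=cfg.seed, frac_distractor=s.frac_distractor)

    rng = np.random.default_rng([cfg.seed, 101])
    profile = EffectProfile(
        beta0=rng.uniform(0.15, 1.35, s.n_probes),
        beta1=np.zeros(s.n_probes),
        beta2=np.full(s.n_probes, s.beta2),
        beta_c=np.full(s.n_probes, s.beta_c),
        sigma_y=np.full(s.n_probes, s.sigma_y))
    # plant causal probes among clean autosomal, non-distractor probes
    clean = (~ann["chromosome"].isin(["X", "Y"])
             & ~ann["cross_reactive"] & ~ann["distractor"]
             & ~missing_mask).to_numpy()
    candidates = np.flatnonzero(clean)
    signal_idx = rng.choice(candidates,
                            size=min(s.n_signal_probes, candidates.size),
                            replace=False)
    mean_folate = s.alpha0 + s.alpha1 * (2 * (s.maf677 + s.maf1298)) \
        + s.alpha2 * s.p_planned
    profile = profile.with_signal(signal_idx, s.signal_beta1,
                                  recenter_at=mean_folate)

    panel = gen_methylation(cohort, u, profile, ann, seed=cfg.seed,
                            missing_probes=missing_mask,
                            with_intensities=s.with_intensities)

    mio.write_cohort(cohort, out / "cohort.csv")
    mio.write_annotations(ann, out / "annotations.csv")
    mio.write_betas(panel.betas, out / "betas.tsv")
    if s.with_intensities:
        mio.write_intensities(panel, out / "intensities.tsv")
    truth = ann[["probe_id"]].copy()
    truth["beta1_true"] = profile.beta1
    truth.to_csv(out / "simulated_truth.csv", index=False)

    genes = sorted({g.split(";")[0] for g in ann["gene_symbols"]})
    g2t = make_gene_term_map(genes, n_terms=cfg.enrich.n_terms,
                             seed=cfg.seed)
    g2t.to_csv(out / "gene2term.csv", index=False)
    return {"cohort": cohort, "panel": panel, "annotations": ann,
            "gene2term": g2t,
            "signal_probes": ann["probe_id"].to_numpy()[signal_idx]}


def load_stage(cfg: RunConfig) -> dict:
    cohort = mio.read_cohort(cfg.inputs.cohort)
    ann = mio.read_annotations(cfg.inputs.annotations)
    betas = mio.read_betas(cfg.inputs.betas)
    panel = MethylationPanel(annotations=ann, betas=betas)
    g2t = (pd.read_csv(cfg.inputs.gene2term)
           if cfg.inputs.gene2term else None)
    return {"cohort": cohort, "panel": panel, "annotations": ann,
            "gene2term": g2t}


def qc_stage(cohort: pd.DataFrame, out: Path) -> dict:
    """Instrument QC report: HWE per SNP, additive-vs-codominant F, and
    the first-stage instrument-strength F."""
    lines = ["# instrument QC"]
    results = {}
    for snp in ("g677", "g1298"):
        g = cohort[snp].to_numpy()
        res = hwe_test(int((g == 0).sum()), int((g == 1).sum()),
                       int((g == 2).sum()))
        results[f"hwe_{snp}"] = res
        lines.append(
            f"HWE {snp}: chi2={res.chi2:.4f} p={res.p_value:.4f} "
            f"observed=({res.n_hom_major},{res.n_het},{res.n_hom_minor})")
    f_cd, d1, d2, p_cd = codominant_vs_additive_f(cohort)
    lines.append(f"codominant vs additive: F={f_cd:.3f} "
                 f"df=({d1},{d2}) p={p_cd:.4f}")
    f_fs, d1, d2, p_fs = first_stage_f(cohort)
    lines.append(f"first-stage instrument strength: F={f_fs:.3f} "
                 f"df=({d1},{d2}) p={p_fs:.4f}")
    (out / "qc_report.txt").write_text("\n".join(lines) + "\n")
    results["codominant_vs_additive"] = (f_cd, p_cd)
    results["first_stage"] = (f_fs, p_fs)
    return results


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages run in fixed order; each stage's artifacts are written
    before the next stage reads its inputs, so any downstream stage can
    be re-run from the persisted intermediates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)

    manifest: dict = {"config": _config_echo(config), "stages": [],
                      "seed": config.seed}
    t0 = time.time()

    if config.simulate.enabled:
        data = simulate_stage(config, out)
        _stage(manifest, "simulate", n_subjects=len(data["cohort"]),
               n_probes=data["panel"].n_probes)
    else:
        data = load_stage(config)
        _stage(manifest, "load", n_subjects=len(data["cohort"]),
               n_probes=data["panel"].n_probes)
    cohort, panel = data["cohort"], data["panel"]

    matrix_y, report = preprocess_panel(panel, alpha=config.preprocess.alpha)
    mio.write_betas(matrix_y, out / "filtered_transformed.tsv")
    mio.write_filter_report(report, out / "filter_report.txt")
    _stage(manifest, "preprocess", **report.counts)

    qc = qc_stage(cohort, out)
    _stage(manifest, "qc",
           first_stage_f=round(qc["first_stage"][0], 3))

    betas_complete = panel.betas.loc[matrix_y.index]
    results, comparison = genomewide_scan(
        matrix_y, cohort, alpha=config.scan.alpha,
        betas=betas_complete, bootstrap_reps=config.scan.bootstrap_reps,
        seed=config.seed, multiplicity=config.scan.multiplicity)
    mio.write_locus_results(results, out / "locus_results.tsv")
    mio.write_bed(results, data["annotations"], out / "probes.bed")
    (out / "comparison.txt").write_text(
        f"pearson_r\t{comparison.pearson_r:.6f}\n"
        f"pearson_p\t{comparison.pearson_p:.3e}\n"
        f"r_squared\t{comparison.r_squared:.6f}\n"
        f"tsls_range\t{comparison.tsls_range[0]:.4f}\t"
        f"{comparison.tsls_range[1]:.4f}\n"
        f"ols_range\t{comparison.ols_range[0]:.4f}\t"
        f"{comparison.ols_range[1]:.4f}\n"
        f"top10_overlap\t{comparison.overlap}\n")
    sig = results[results["significant"]]
    _stage(manifest, "scan", n_loci=len(results), n_significant=len(sig))

    if config.confound_sim.enabled and len(sig):
        truth_rows = []
        z = cohort["variant_count"].to_numpy(dtype=float)
        a = cohort["log_rbc_folate"].to_numpy(dtype=float)
        c = cohort["conception_planned"].to_numpy(dtype=float)
        for pid in sig["probe_id"].head(config.confound_sim.max_loci):
            y = matrix_y.loc[pid].to_numpy(dtype=float)
            fit = tsls_fit(y, a, z, c)
            truth_rows.append({
                "locus_id": pid,
                "alpha0": fit.first_stage.coef[0],
                "alpha1": fit.first_stage.coef[1],
                "alpha2": fit.first_stage.coef[2],
                "beta0": fit.coef[0], "beta1": fit.coef[1],
                "beta2": fit.coef[2]})
        truth_table = pd.DataFrame(truth_rows)
        truth_table.to_csv(out / "confound_truth.csv", index=False)
        base = SimulationSpec(
            genotype=z, conception=c, log_folate=a,
            alpha=(0.0, 0.0, 0.0), beta=(0.0, 0.0, 0.0),
            n_reps=config.confound_sim.n_reps, seed=config.seed,
            y_from_simulated_x=config.confound_sim.y_from_simulated_x)
        table = sweep(base, truth_table, config.confound_sim.levels)
        table.to_csv(out / "confounding_sweep.tsv", sep="\t", index=False)
        _stage(manifest, "confound_sim", n_rows=len(table),
               levels=list(config.confound_sim.levels))

    if (config.enrich.enabled and len(sig)
            and data.get("gene2term") is not None):
        genes = nearest_gene_assignment(sig["probe_id"],
                                        data["annotations"])
        analyzed_ann = data["annotations"][
            data["annotations"]["probe_id"].isin(matrix_y.index)]
        universe = sorted({g.split(";")[0]
                           for g in analyzed_ann["gene_symbols"]})
        table = enrich(genes, data["gene2term"], universe_genes=universe)
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write(f"# test: {TEST_LABEL}\n")
            table.to_csv(fh, sep="\t", index=False)
        _stage(manifest, "enrich", n_terms=len(table),
               n_subset_genes=len(genes))

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_echo(config: RunConfig) -> dict:
    from dataclasses import asdict
    return asdict(config)
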