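"""Readers and writers for the pipeline's delimited-text artifacts.

Conventions: cohort and annotation tables are CSV; methylation matrices
are TSV with the probe id in the first column, one column per subject,
and "NA" for missing values; intensity TSVs carry paired ``M_<id>`` /
``U_<id>`` columns; scan results go to TSV plus a BED file (0-based
half-open) for genome-browser overlap.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mrewas.synthetic import MethylationPanel

__all__ = [
    "write_cohort", "read_cohort",
    "write_betas", "read_betas",
    "write_annotations", "read_annotations",
    "write_intensities", "read_intensities",
    "write_filter_report", "write_locus_results", "write_bed",
]

COHORT_COLUMNS = ["subject_id", "g677", "g1298", "variant_count",
                  "conception_planned", "log_rbc_folate"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file lacks columns: {sorted(missing)}")
    return df


def write_betas(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_betas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id",
                       na_values=["NA"])


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"probe_id": str, "chromosome": str,
                                  "gene_symbols": str})
    if "cross_reactive" in df.columns:
        df["cross_reactive"] = df["cross_reactive"].astype(bool)
    if "distractor" in df.columns:
        df["distractor"] = df["distractor"].astype(bool)
    return df


def write_intensities(panel: MethylationPanel, path) -> None:
    if panel.intensities_m is None or panel.intensities_u is None:
        raise ValueError("panel carries no intensity matrices")
    cols = {}
    for sid in panel.intensities_m.columns:
        cols[f"M_{sid}"] = panel.intensities_m[sid]
        cols[f"U_{sid}"] = panel.intensities_u[sid]
    df = pd.DataFrame(cols, index=panel.intensities_m.index)
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_intensities(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    m_cols = [c for c in df.columns if c.startswith("M_")]
    u_cols = [c for c in df.columns if c.startswith("U_")]
    sids = [c[2:] for c in m_cols]
    if sids != [c[2:] for c in u_cols]:
        raise ValueError("intensity file M_/U_ columns are not paired")
    m = df[m_cols].set_axis(sids, axis=1)
    u = df[u_cols].set_axis(sids, axis=1)
    return m, u


def write_filter_report(report, path, header_lines=()) -> None:
    path = Path(path)
    frame = report.to_frame()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_locus_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_bed(results: pd.DataFrame, annotations: pd.DataFrame, path) -> None:
    """BED-style track of scanned probes: chrom, start, start+2 (the CpG
    dinucleotide), probe_id, and the TSLS p-value as score."""
    ann = annotations.set_index("probe_id")
    rows = []
    for _, r in results.iterrows():
        pid = r["probe_id"]
        chrom = ann.at[pid, "chromosome"]
        start = int(ann.at[pid, "position"])
        rows.append((f"chr{chrom}", start, start + 2, pid,
                     float(r["tsls_p"])))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                      "score"])
    bed.to_csv(path, sep="\t", index=False, header=False)
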