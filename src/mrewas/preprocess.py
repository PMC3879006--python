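"""Beta-value computation, probe restriction, transformation, and the
per-probe normality filter.

The restriction cascade is order-fixed: sex-chromosome probes are
dropped first, then cross-reactive probes, then probes with any missing
beta (complete-case), then — after the variance-stabilizing arcsine
transform — probes whose transformed values fail a Shapiro-Wilk
normality test at the chosen alpha. Each stage's removals are recorded
in a :class:`FilterReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrewas.synthetic import MethylationPanel

__all__ = [
    "FilterReport",
    "beta_from_intensities",
    "transform_beta",
    "inverse_transform",
    "restrict_probes",
    "normality_filter",
    "preprocess_panel",
]

_AUTOSOMES = {str(c) for c in range(1, 23)}
_SEX = {"X", "Y"}

STAGES = ("input", "after_autosome_restriction",
          "after_cross_reactive_removal", "after_complete_case",
          "after_normality_filter")


@dataclass
class FilterReport:
    """Probe counts and removed-probe lists at each cascade stage."""

    counts: dict[str, int] = field(default_factory=dict)
    removed: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, n_after: int, removed_ids) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.counts[stage] = int(n_after)
        if stage != "input":
            self.removed[stage] = list(removed_ids)

    def validate(self) -> None:
        seen = [s for s in STAGES if s in self.counts]
        vals = [self.counts[s] for s in seen]
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage counts must be weakly decreasing")
        for prev, cur in zip(seen, seen[1:]):
            n_rm = len(self.removed.get(cur, []))
            if self.counts[prev] - self.counts[cur] != n_rm:
                raise ValueError(
                    f"count drop {prev}->{cur} inconsistent with removals")
        all_removed = [p for s in seen[1:] for p in self.removed.get(s, [])]
        if len(all_removed) != len(set(all_removed)):
            raise ValueError("removed lists must be disjoint across stages")

    def to_frame(self) -> pd.DataFrame:
        rows, prev = [], None
        for s in STAGES:
            if s not in self.counts:
                continue
            n = self.counts[s]
            rows.append({"stage": s, "count": n,
                         "n_removed": 0 if prev is None else prev - n})
            prev = n
        return pd.DataFrame(rows)


def beta_from_intensities(m, u, detected=None):
    """Methylation beta-values from methylated/unmethylated intensities.

    beta = M / (M + U + 100); the +100 offset regularizes low-intensity
    probes. Where ``detected`` is False (signal not above background)
    the value is set to NaN, the in-memory missing sentinel.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    beta = m / (m + u + 100.0)
    if detected is not None:
        beta = np.where(np.asarray(detected, dtype=bool), beta, np.nan)
    return beta


def transform_beta(beta):
    """Square-root arcsine variance-stabilizing transform.

    Maps beta in [0, 1] to y = arcsin(sqrt(beta)) in [0, pi/2]. NaN
    (missing) passes through.
    """
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (b < 0) | (b > 1)
    if np.any(bad & np.isfinite(b)):
        raise ValueError("beta values must lie in [0, 1]")
    return np.arcsin(np.sqrt(b))


def inverse_transform(y):
    """Inverse of :func:`transform_beta`: sin^2(y), clipped to [0, 1]."""
    return np.clip(np.sin(np.asarray(y, dtype=float)) ** 2, 0.0, 1.0)


def restrict_probes(panel: MethylationPanel,
                    report: FilterReport | None = None,
                    ) -> tuple[MethylationPanel, FilterReport]:
    """Apply the probe-restriction cascade (no normality filtering).

    Removes, in order: sex-chromosome probes, cross-reactive probes,
    probes with any missing beta-value (complete-case). Returns the
    restricted panel and the report with the first four stages filled.
    """
    ann = panel.annotations
    chroms = set(ann["chromosome"].astype(str))
    unknown = chroms - _AUTOSOMES - _SEX
    if unknown:
        raise ValueError(f"unknown chromosome labels: {sorted(unknown)}")

    report = report or FilterReport()
    report.record("input", panel.n_probes, [])

    is_sex = ann["chromosome"].astype(str).isin(_SEX).to_numpy()
    sex_ids = ann.loc[is_sex, "probe_id"].tolist()
    keep = ann.loc[~is_sex, "probe_id"]
    report.record("after_autosome_restriction", len(keep), sex_ids)
    panel = panel.subset(keep)

    ann = panel.annotations
    is_cross = ann["cross_reactive"].to_numpy(dtype=bool)
    cross_ids = ann.loc[is_cross, "probe_id"].tolist()
    keep = ann.loc[~is_cross, "probe_id"]
    report.record("after_cross_reactive_removal", len(keep), cross_ids)
    panel = panel.subset(keep)

    has_missing = panel.betas.isna().any(axis=1).to_numpy()
    miss_ids = panel.betas.index[has_missing].tolist()
    keep = panel.betas.index[~has_missing]
    report.record("after_complete_case", len(keep), miss_ids)
    panel = panel.subset(keep)

    if panel.n_probes == 0:
        warnings.warn("probe restriction removed every probe", stacklevel=2)
    report.validate()
    return panel, report


def normality_filter(matrix_y: pd.DataFrame, alpha: float = 0.05,
                     report: FilterReport | None = None,
                     ) -> tuple[pd.DataFrame, FilterReport]:
    """Drop probes whose transformed values are non-normal.

    Applies a per-probe Shapiro-Wilk test and removes probes with
    p < ``alpha``; no multiple-testing adjustment is applied, so ~alpha
    of genuinely normal probes are removed by construction. Constant
    probes (W undefined) are removed with a warning.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n = matrix_y.shape[1]
    if not (3 <= n <= 5000):
        raise ValueError(
            f"Shapiro-Wilk requires 3 <= n <= 5000 subjects, got {n}")
    vals = matrix_y.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("normality filter requires complete-case input")

    removed: list[str] = []
    keep_mask = np.ones(len(matrix_y), dtype=bool)
    n_constant = 0
    for i, row in enumerate(vals):
        if np.ptp(row) == 0.0:
            keep_mask[i] = False
            n_constant += 1
            continue
        if stats.shapiro(row).pvalue < alpha:
            keep_mask[i] = False
    if n_constant:
        warnings.warn(
            f"{n_constant} constant probe(s) removed (Shapiro-Wilk W "
            "undefined)", stacklevel=2)
    removed = matrix_y.index[~keep_mask].tolist()
    out = matrix_y.loc[keep_mask]

    report = report or FilterReport()
    if "input" not in report.counts:
        report.record("input", len(matrix_y), [])
    report.record("after_normality_filter", len(out), removed)
    report.validate()
    return out, report


def preprocess_panel(panel: MethylationPanel, alpha: float = 0.05,
                     ) -> tuple[pd.DataFrame, FilterReport]:
    """Full cascade: restrict -> complete-case -> transform -> normality.

    Returns the transformed, filtered probes x subjects matrix and the
    complete five-stage :class:`FilterReport`.
    """
    restricted, report = restrict_probes(panel)
    y = pd.DataFrame(transform_beta(restricted.betas.to_numpy()),
                     index=restricted.betas.index,
                     columns=restricted.betas.columns)
    filtered, report = normality_filter(y, alpha=alpha, report=report)
    return filtered, report
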