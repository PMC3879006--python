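"""Instrument validation: Hardy-Weinberg equilibrium, additive variant
coding under the trans-haplotype constraint, and nested-model F tests
(codominant vs additive coding; instrument strength)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HweResult",
    "TransViolationError",
    "hwe_test",
    "additive_code",
    "nested_f_test",
    "codominant_vs_additive_f",
    "first_stage_f",
]


class TransViolationError(ValueError):
    """A subject carries three or more variant alleles across the two
    SNPs, implying a cis haplotype — incompatible with additive trans
    coding of the instrument."""


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int
    expected: tuple[float, float, float]
    chi2: float
    p_value: float

    @property
    def allele_freq_major(self) -> float:
        n = self.n_hom_major + self.n_het + self.n_hom_minor
        return (2 * self.n_hom_major + self.n_het) / (2 * n)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """Chi-square test of Hardy-Weinberg equilibrium from genotype counts.

    Estimates the allele frequency from the counts, forms expected
    genotype counts (p^2, 2pq, q^2) * n, and computes the Pearson
    chi-square on 1 degree of freedom with no continuity correction.
    A monomorphic sample carries no information against HWE; chi2 = 0
    and p = 1 are returned with a warning.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    if p == 0.0 or q == 0.0:
        warnings.warn("monomorphic sample: HWE test uninformative",
                      stacklevel=2)
        return HweResult(n_AA, n_Aa, n_aa, expected, 0.0, 1.0)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(n_AA, n_Aa, n_aa, expected, float(chi2), pval)


def additive_code(g677, g1298):
    """Additive instrument: total trans variant count across both SNPs.

    Valid only when the variants lie on opposite haplotypes, i.e.
    g677 + g1298 <= 2 ("zero, one, or two trans variants"). A sum of 3
    or 4 implies a cis haplotype and raises
    :class:`TransViolationError` rather than silently recoding.
    Accepts scalars or arrays; symmetric in its arguments.
    """
    a = np.asarray(g677)
    b = np.asarray(g1298)
    if np.any((a < 0) | (a > 2)) or np.any((b < 0) | (b > 2)):
        raise ValueError("allele counts must be in {0, 1, 2}")
    total = a + b
    if np.any(total > 2):
        bad = np.flatnonzero(np.atleast_1d(total > 2))
        raise TransViolationError(
            f"{bad.size} subject(s) carry >2 variant alleles (implied cis "
            "haplotype); additive trans coding is invalid for them")
    return total if total.ndim else int(total)


def _as_design(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(np.linalg.matrix_rank(X))


def nested_f_test(y, X_full, X_reduced) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F test of a reduced model nested in a full one.

    Returns ``(F, df1, df2, p)`` where df1 is the number of added
    parameters and df2 the residual degrees of freedom of the full
    model. The reduced design's column space must be contained in the
    full design's.
    """
    y = np.asarray(y, dtype=float)
    Xf = _as_design(X_full)
    Xr = _as_design(X_reduced)
    n = y.shape[0]
    if Xf.shape[0] != n or Xr.shape[0] != n:
        raise ValueError("design row counts must match y")
    rank_f = np.linalg.matrix_rank(Xf)
    if np.linalg.matrix_rank(np.hstack([Xf, Xr])) > rank_f:
        raise ValueError("reduced design is not nested in the full design")
    if rank_f < Xf.shape[1]:
        raise ValueError("full design is rank deficient")
    if n <= Xf.shape[1]:
        raise ValueError("need more observations than full-model parameters")

    rss_f, _ = _rss(y, Xf)
    rss_r, rank_r = _rss(y, Xr)
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 == 0:
        return 0.0, 0, df2, 1.0
    # numerically perfect fit: residual indistinguishable from rounding
    if rss_f <= n * np.finfo(float).eps * (1.0 + float(y @ y)):
        return float("inf"), df1, df2, 0.0
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    F = max(F, 0.0)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def codominant_vs_additive_f(cohort: pd.DataFrame
                             ) -> tuple[float, int, int, float]:
    """Does codominant coding of the variant count explain more
    first-stage variation in log folate than additive coding?

    Full model: conception + indicators for one and two variants.
    Reduced model: conception + additive count. Both include an
    intercept.
    """
    z = cohort["variant_count"].to_numpy(dtype=float)
    c = cohort["conception_planned"].to_numpy(dtype=float)
    y = cohort["log_rbc_folate"].to_numpy(dtype=float)
    ones = np.ones_like(z)
    full = np.column_stack([ones, c, (z == 1).astype(float),
                            (z == 2).astype(float)])
    reduced = np.column_stack([ones, c, z])
    return nested_f_test(y, full, reduced)


def first_stage_f(cohort: pd.DataFrame) -> tuple[float, int, int, float]:
    """Instrument-strength F: additive variant count vs intercept +
    conception only, for log folate. Reported as a weak-instrument
    diagnostic; no threshold is enforced."""
    z = cohort["variant_count"].to_numpy(dtype=float)
    c = cohort["conception_planned"].to_numpy(dtype=float)
    y = cohort["log_rbc_folate"].to_numpy(dtype=float)
    ones = np.ones_like(z)
    full = np.column_stack([ones, c, z])
    reduced = np.column_stack([ones, c])
    return nested_f_test(y, full, reduced)
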