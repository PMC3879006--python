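"""Two-stage least squares and OLS estimation, genome-wide per-locus
scanning, pairs-bootstrap confidence intervals, and scan comparison.

The instrument here is a single additive genotype score, so every model
is just-identified and 2SLS reduces to the classical two-step
construction: regress the exposure on the instrument (plus measured
covariates), then regress the outcome on the fitted exposure (plus the
same covariates). Second-stage standard errors use the standard 2SLS
correction — residuals are recomputed with the *observed* exposure,
because naive OLS-on-fitted standard errors are inconsistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrewas.genotype_qc import nested_f_test

__all__ = [
    "OlsFit",
    "TslsFit",
    "ScanComparison",
    "ols_fit",
    "tsls_fit",
    "genomewide_scan",
    "bootstrap_delta_beta",
    "compare_scans",
]


@dataclass(frozen=True)
class OlsFit:
    """Closed-form least squares with classical homoskedastic SEs."""

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    rss: float
    df_resid: int

    @property
    def n(self) -> int:
        return self.residuals.shape[0]


@dataclass(frozen=True)
class TslsFit:
    """Per-locus 2SLS fit.

    ``coef``/``se``/``t``/``p`` describe the second stage with the
    observed-exposure residual correction; index 0 is the intercept,
    index 1 the exposure effect, the rest covariates. ``first_stage``
    is the OLS fit of the exposure on instrument + covariates and
    ``first_stage_f`` the instrument-strength F statistic (a
    weak-instrument diagnostic, reported but not enforced).
    """

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    first_stage: OlsFit
    first_stage_f: float
    n: int

    @property
    def beta1(self) -> float:
        return float(self.coef[1])

    @property
    def beta1_se(self) -> float:
        return float(self.se[1])

    @property
    def beta1_p(self) -> float:
        return float(self.p[1])


@dataclass
class ScanComparison:
    """TSLS-vs-OLS comparison across a scan."""

    pearson_r: float
    pearson_p: float
    r_squared: float
    tsls_range: tuple[float, float]
    ols_range: tuple[float, float]
    top_tsls: list[str] = field(default_factory=list)
    top_ols: list[str] = field(default_factory=list)
    overlap: int = 0


def ols_fit(y, design) -> OlsFit:
    """Ordinary least squares with classical SEs.

    ``design`` must include any intercept column explicitly and be full
    column rank with more rows than columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and design row counts differ")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design is rank deficient")

    xtx = X.T @ X
    # SVD-based solve: avoids squaring the design's condition number
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return OlsFit(coef=coef, se=se, t=t, p=pvals, residuals=resid,
                  rss=rss, df_resid=df)


def _second_stage_design(col: np.ndarray, covariates) -> np.ndarray:
    parts = [np.ones_like(col), col]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        parts.append(C)
    return np.column_stack(parts)


def tsls_fit(y, exposure, instrument, covariates=None) -> TslsFit:
    """Two-stage least squares with a single instrument.

    Stage 1 regresses the exposure on the instrument and covariates;
    stage 2 regresses the outcome on the fitted exposure and the same
    covariates. Standard errors use the corrected residuals
    ``y - X_obs @ coef`` (observed exposure), sigma^2 = RSS/(n-p), and
    covariance sigma^2 (Xhat' Xhat)^-1. Inference uses the t
    distribution on n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    n = y.shape[0]
    if a.shape[0] != n or z.shape[0] != n:
        raise ValueError("y, exposure, instrument lengths differ")
    if np.ptp(z) == 0.0:
        raise ValueError("instrument is constant: first stage has zero "
                         "explanatory variance")

    X1 = _second_stage_design(z, covariates)
    first = ols_fit(a, X1)
    ahat = X1 @ first.coef

    Xhat = _second_stage_design(ahat, covariates)
    Xobs = _second_stage_design(a, covariates)
    p = Xhat.shape[1]
    if n <= p:
        raise ValueError(f"need n > parameters, got n={n}, p={p}")
    xtx = Xhat.T @ Xhat
    if np.linalg.matrix_rank(Xhat) < p:
        raise ValueError("second-stage design collinear (weak or constant "
                         "fitted exposure)")
    coef, *_ = np.linalg.lstsq(Xhat, y, rcond=None)

    resid = y - Xobs @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(t), n - p)

    X1_reduced = np.delete(X1, 1, axis=1)
    fstat, _, _, _ = nested_f_test(a, X1, X1_reduced)
    return TslsFit(coef=coef, se=se, t=t, p=pvals, first_stage=first,
                   first_stage_f=fstat, n=n)


# ---------------------------------------------------------------------------
# batched least-squares cores (vectorized over probes / replicates)

def _fixed_design_ols(Y: np.ndarray, X: np.ndarray, X_resid: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of many outcomes (rows of Y) on one shared design.

    Residuals are computed against ``X_resid`` (equal to ``X`` for
    plain OLS; the observed-exposure design for 2SLS correction).
    Returns (coefs [m, p], se [m, p], sigma2 [m]).
    """
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ (X.T @ Y.T)            # p x m
    E = Y.T - X_resid @ B                # n x m
    sigma2 = (E ** 2).sum(axis=0) / (n - p)
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    return B.T, se, sigma2


def _batched_solve(Xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for a stack of small dense systems.

    Xs: (R, n, p); ys: (R, n). Returns (R, p).
    """
    G = np.einsum("rni,rnj->rij", Xs, Xs)
    b = np.einsum("rni,rn->ri", Xs, ys)
    return np.linalg.solve(G, b[..., None])[..., 0]


# ---------------------------------------------------------------------------


def genomewide_scan(matrix_y: pd.DataFrame, cohort: pd.DataFrame,
                    alpha: float = 0.05,
                    betas: pd.DataFrame | None = None,
                    bootstrap_reps: int = 0, seed: int = 0,
                    multiplicity: bool = False,
                    top_k: int = 10,
                    ) -> tuple[pd.DataFrame, ScanComparison]:
    """Per-locus 2SLS and OLS scan across a transformed methylation
    matrix.

    Both models adjust for the conception indicator only. Because the
    first stage is locus-independent it is fit once; second-stage
    coefficients and corrected SEs are then computed for all probes in
    one linear-algebra pass (exactly equal to looping
    :func:`tsls_fit` / :func:`ols_fit` per probe).

    Probes significant at the unadjusted ``alpha`` form the significant
    set; if ``betas`` (untransformed values, same probe index) and
    ``bootstrap_reps`` are supplied, those probes additionally get an
    untransformed-scale effect (``delta_beta``) with a pairs-bootstrap
    percentile 95% CI. Bonferroni/Benjamini-Hochberg columns are
    optional extensions (``multiplicity=True``).

    Returns the result table sorted by TSLS p-value (ties broken by
    |estimate| descending, then probe id) and a :class:`ScanComparison`.
    """
    subj = list(matrix_y.columns)
    if list(cohort["subject_id"]) != subj:
        raise ValueError("matrix subject columns do not match cohort "
                         "subject_id order")
    z = cohort["variant_count"].to_numpy(dtype=float)
    if np.ptp(z) == 0.0:
        raise ValueError("instrument 'variant_count' is constant across the "
                         "cohort")
    a = cohort["log_rbc_folate"].to_numpy(dtype=float)
    c = cohort["conception_planned"].to_numpy(dtype=float)

    Y = matrix_y.to_numpy(dtype=float)
    n = Y.shape[1]

    X1 = _second_stage_design(z, c)
    first = ols_fit(a, X1)
    ahat = X1 @ first.coef
    Xhat = _second_stage_design(ahat, c)
    Xobs = _second_stage_design(a, c)
    p_cols = Xhat.shape[1]
    dof = n - p_cols

    coefs_t, se_t, _ = _fixed_design_ols(Y, Xhat, Xobs)
    tsls_est = coefs_t[:, 1]
    tsls_se = se_t[:, 1]
    tsls_t = tsls_est / tsls_se
    tsls_p = 2.0 * stats.t.sf(np.abs(tsls_t), dof)

    coefs_o, se_o, _ = _fixed_design_ols(Y, Xobs, Xobs)
    ols_est = coefs_o[:, 1]
    ols_se = se_o[:, 1]
    ols_t = ols_est / ols_se
    ols_p = 2.0 * stats.t.sf(np.abs(ols_t), dof)

    results = pd.DataFrame({
        "probe_id": matrix_y.index,
        "tsls_estimate": tsls_est,
        "tsls_se": tsls_se,
        "tsls_p": tsls_p,
        "ols_estimate": ols_est,
        "ols_se": ols_se,
        "ols_p": ols_p,
        "first_stage_f": np.full(len(matrix_y), _first_stage_f(X1, a)),
        "significant": tsls_p < alpha,
    })
    if multiplicity:
        m = len(results)
        results["tsls_p_bonferroni"] = np.minimum(tsls_p * m, 1.0)
        results["tsls_p_bh"] = _bh_adjust(tsls_p)

    results["delta_beta"] = np.nan
    results["bootstrap_ci_low"] = np.nan
    results["bootstrap_ci_high"] = np.nan
    if betas is not None and bootstrap_reps > 0:
        sig_ids = results.loc[results["significant"], "probe_id"]
        for k, pid in enumerate(sig_ids):
            b_row = betas.loc[pid].to_numpy(dtype=float)
            point, lo, hi = bootstrap_delta_beta(
                b_row, a, z, c, n_reps=bootstrap_reps,
                seed=_combine_seed(seed, k))
            row = results["probe_id"] == pid
            results.loc[row, "delta_beta"] = point
            results.loc[row, "bootstrap_ci_low"] = lo
            results.loc[row, "bootstrap_ci_high"] = hi

    # deterministic ranking: p ascending, |estimate| descending, probe id
    results = results.sort_values(
        by=["tsls_p", "tsls_estimate", "probe_id"],
        key=lambda s: -s.abs() if s.name == "tsls_estimate" else s,
    ).reset_index(drop=True)

    comparison = compare_scans(
        results["tsls_estimate"].to_numpy(), results["ols_estimate"].to_numpy(),
        probe_ids=results["probe_id"].to_numpy(),
        tsls_p=results["tsls_p"].to_numpy(), ols_p=results["ols_p"].to_numpy(),
        top_k=top_k)
    return results, comparison


def _first_stage_f(X1: np.ndarray, a: np.ndarray) -> float:
    # 1-df instrument-strength F for a fitted first-stage design
    f, _, _, _ = nested_f_test(a, X1, np.delete(X1, 1, axis=1))
    return f


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.shape[0]
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _combine_seed(seed: int, k: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(k)])
    return int(ss.generate_state(1)[0] % (2**31))


def bootstrap_delta_beta(beta_untransformed, exposure, instrument,
                         covariates=None, n_reps: int = 1000,
                         seed: int = 0,
                         ) -> tuple[float, float, float]:
    """Pairs-bootstrap percentile 95% CI for the 2SLS effect on the
    untransformed beta-value scale.

    The point estimate is the 2SLS exposure coefficient with the raw
    beta-values as outcome. Subjects (rows) are resampled with
    replacement ``n_reps`` times; each resample is refit and the
    empirical 2.5 and 97.5 percentiles of the exposure coefficient are
    returned. Resamples with a constant instrument are redrawn (their
    count is warned about when nonzero).
    """
    if n_reps < 200:
        raise ValueError("n_reps must be >= 200 for percentile CIs")
    y = np.asarray(beta_untransformed, dtype=float)
    a = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    n = y.shape[0]
    if not (a.shape[0] == z.shape[0] == n):
        raise ValueError("input vectors are not aligned")
    if n < 10:
        warnings.warn(f"only {n} subjects: bootstrap CIs are unreliable",
                      stacklevel=2)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]

    point = tsls_fit(y, a, z, covariates).beta1

    rng = np.random.default_rng(seed)
    idx = rng.integers(n, size=(n_reps, n))
    n_redrawn = 0
    while True:
        degenerate = np.ptp(z[idx], axis=1) == 0.0
        if not degenerate.any():
            break
        n_redrawn += int(degenerate.sum())
        idx[degenerate] = rng.integers(n, size=(int(degenerate.sum()), n))
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate resample(s) with a "
                      "constant instrument", stacklevel=2)

    zb = z[idx]
    ab = a[idx]
    yb = y[idx]
    ones = np.ones((n_reps, n))
    if C is not None:
        Cb = C[idx]  # (R, n, k)
        X1 = np.concatenate([ones[..., None], zb[..., None], Cb], axis=2)
    else:
        X1 = np.stack([ones, zb], axis=2)
    coef1 = _batched_solve(X1, ab)
    ahat = np.einsum("rnp,rp->rn", X1, coef1)
    if C is not None:
        X2 = np.concatenate([ones[..., None], ahat[..., None], Cb], axis=2)
    else:
        X2 = np.stack([ones, ahat], axis=2)
    coef2 = _batched_solve(X2, yb)
    est = coef2[:, 1]

    lo, hi = np.percentile(est, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def compare_scans(tsls_estimates, ols_estimates, probe_ids=None,
                  tsls_p=None, ols_p=None, top_k: int = 10
                  ) -> ScanComparison:
    """Pearson correlation and ranking overlap between the two scans.

    Top-``top_k`` lists are ranked by p-value when p-values are given,
    otherwise by |estimate| descending; ties break by |estimate| then
    probe id for determinism.
    """
    t = np.asarray(tsls_estimates, dtype=float)
    o = np.asarray(ols_estimates, dtype=float)
    if t.shape != o.shape:
        raise ValueError("estimate vectors must be aligned")
    if t.shape[0] < 3:
        raise ValueError("need at least 3 loci to compare scans")
    if np.ptp(t) == 0.0 or np.ptp(o) == 0.0:
        raise ValueError("zero-variance estimate vector")
    r, p = stats.pearsonr(t, o)

    top_t: list[str] = []
    top_o: list[str] = []
    overlap = 0
    if probe_ids is not None:
        ids = np.asarray(probe_ids)

        def _rank(est, pv):
            key = pd.DataFrame({"id": ids, "absest": -np.abs(est)})
            if pv is not None:
                key["p"] = pv
                key = key.sort_values(["p", "absest", "id"])
            else:
                key = key.sort_values(["absest", "id"])
            return key["id"].head(top_k).tolist()

        top_t = _rank(t, tsls_p)
        top_o = _rank(o, ols_p)
        overlap = len(set(top_t) & set(top_o))

    return ScanComparison(
        pearson_r=float(r), pearson_p=float(p), r_squared=float(r) ** 2,
        tsls_range=(float(t.min()), float(t.max())),
        ols_range=(float(o.min()), float(o.max())),
        top_tsls=top_t, top_ols=top_o, overlap=overlap)
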