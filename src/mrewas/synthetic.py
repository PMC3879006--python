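"""Synthetic cohorts, methylation panels, and probe annotations.

The generator emulates the statistical structure of a small birth-cohort
methylation study: two biallelic SNPs (MTHFR C677T and A1298C) combined
additively into an instrument under a trans-haplotype constraint, a
linear first-stage effect of variant count on log RBC folate, per-locus
methylation driven by folate, a binary conception-intention covariate,
and a shared standard-normal latent confounder, plus Infinium-style
array artifacts (sex-chromosome probes, cross-reactive probes, missing
beta-values, non-normal loci).

Exposure and outcome models, per subject i and probe j::

    folate_i = alpha0 + alpha1 * Z_i + alpha2 * C_i + alpha_c * u_i + sigma_x * e_i
    y_ij     = beta0_j + beta1_j * folate_i + beta2_j * C_i + beta_c_j * u_i
               + sigma_y_j * e_ij

with Z the additive variant count, C the conception indicator, u, e
standard normal. ``y`` lives on the variance-stabilized arcsine scale
and is mapped back to the beta-value scale via ``sin^2`` with clipping.

One global integer seed expands into fixed per-stage substreams
(genotypes, covariates, confounder, noise, missingness) so stages are
reproducible and mutually independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "EffectProfile",
    "MethylationPanel",
    "SubjectRecord",
    "gen_genotypes",
    "gen_cohort",
    "gen_methylation",
    "gen_probe_panel",
    "make_gene_term_map",
    "array27k_panel_fractions",
]

# Substream identifiers mixed into the seed so the random streams used by
# different generation stages never overlap.
_STREAM_GENOTYPE = 11
_STREAM_COVARIATE = 13
_STREAM_CONFOUNDER = 17
_STREAM_NOISE = 19
_STREAM_METHYLATION = 23
_STREAM_MISSING = 29
_STREAM_ANNOTATION = 31


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SubjectRecord:
    """One individual's genotypes, covariate, and exposure.

    ``variant_count`` is the additive instrument: the total number of
    variant alleles across both SNPs, valid only when the two variants
    sit on opposite haplotypes (g677 + g1298 <= 2).
    """

    subject_id: str
    g677: int
    g1298: int
    variant_count: int
    conception_planned: int
    log_rbc_folate: float


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated to the observed study conditions: n = 50
    cord-blood samples, global minor-allele frequencies ~0.33 (C677T)
    and ~0.23 (A1298C), and log RBC folate centred near 6.66 log(ng/mL)
    with essentially all mass inside a typical 6.13-7.54 range. The
    per-variant first-stage effect and noise scale are chosen so the
    instrument is of realistic modest strength at n = 50 (first-stage
    F around 5).
    """

    n: int = 50
    maf677: float = 0.33
    maf1298: float = 0.23
    alpha0: float = 6.50
    alpha1: float = 0.12
    alpha2: float = 0.05
    alpha_c: float = 0.0
    sigma_x: float = 0.26
    p_planned: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"cohort size must be >= 2, got {self.n}")
        for name in ("maf677", "maf1298"):
            f = getattr(self, name)
            if not (0.0 <= f <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5], got {f}")
        if self.sigma_x <= 0:
            raise ValueError(f"sigma_x must be positive, got {self.sigma_x}")
        if not (0.0 <= self.p_planned <= 1.0):
            raise ValueError(f"p_planned must be in [0, 1], got {self.p_planned}")


@dataclass
class EffectProfile:
    """Per-probe coefficients of the methylation outcome model.

    A null probe has ``beta1 == 0``. Probes flagged ``distractor`` are
    generated from a bimodal mixture instead of the linear model; they
    exist to exercise the normality filter.
    """

    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    beta_c: np.ndarray
    sigma_y: np.ndarray
    distractor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.beta_c = np.asarray(self.beta_c, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        if self.distractor is None:
            self.distractor = np.zeros(self.beta0.shape, dtype=bool)
        self.distractor = np.asarray(self.distractor, dtype=bool)
        n = {a.shape for a in (self.beta0, self.beta1, self.beta2,
                               self.beta_c, self.sigma_y, self.distractor)}
        if len(n) != 1:
            raise ValueError("EffectProfile arrays must share one shape")
        if np.any(self.sigma_y <= 0):
            raise ValueError("sigma_y must be positive for every probe")

    @property
    def n_probes(self) -> int:
        return self.beta0.shape[0]

    @classmethod
    def null(cls, n_probes: int, beta0: float = 0.9, sigma_y: float = 0.05
             ) -> "EffectProfile":
        """All-null profile: intercept-only probes with i.i.d. noise."""
        z = np.zeros(n_probes)
        return cls(beta0=np.full(n_probes, beta0), beta1=z.copy(),
                   beta2=z.copy(), beta_c=z.copy(),
                   sigma_y=np.full(n_probes, sigma_y))

    def with_signal(self, indices, beta1: float,
                    recenter_at: float | None = None) -> "EffectProfile":
        """Return a copy with a causal folate effect at the given probes.

        When ``recenter_at`` (a typical exposure value, e.g. the cohort
        mean log folate) is given, the intercept of each signal probe is
        shifted so the probe's expected transformed value stays where it
        was — otherwise a large ``beta1`` times an exposure far from
        zero would push ``y`` past the [0, pi/2] clip and flatten the
        probe.
        """
        idx = np.asarray(indices)
        b1 = self.beta1.copy()
        b0 = self.beta0.copy()
        if recenter_at is not None:
            b0[idx] += (self.beta1[idx] - beta1) * recenter_at
        b1[idx] = beta1
        return replace(self, beta0=b0, beta1=b1)

    def with_distractors(self, indices) -> "EffectProfile":
        d = self.distractor.copy()
        d[np.asarray(indices)] = True
        return replace(self, distractor=d)


@dataclass
class MethylationPanel:
    """Probe annotations plus a beta-value matrix, optionally with raw
    methylated/unmethylated intensity pairs.

    ``betas`` is probes x subjects with ``NaN`` marking values whose
    signal was not distinguishable from background ("NA" on disk).
    """

    annotations: pd.DataFrame
    betas: pd.DataFrame
    intensities_m: pd.DataFrame | None = None
    intensities_u: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.annotations) != len(self.betas):
            raise ValueError(
                f"annotation rows ({len(self.annotations)}) != beta rows "
                f"({len(self.betas)})")
        if not np.array_equal(self.annotations["probe_id"].to_numpy(),
                              self.betas.index.to_numpy()):
            raise ValueError("annotation probe_id order must match beta index")
        vals = self.betas.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("non-missing beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.betas)

    @property
    def n_subjects(self) -> int:
        return self.betas.shape[1]

    def subset(self, probe_ids) -> "MethylationPanel":
        keep = pd.Index(probe_ids)
        ann = (self.annotations.set_index("probe_id").loc[keep]
               .reset_index())
        m = self.intensities_m.loc[keep] if self.intensities_m is not None else None
        u = self.intensities_u.loc[keep] if self.intensities_u is not None else None
        return MethylationPanel(annotations=ann, betas=self.betas.loc[keep],
                                intensities_m=m, intensities_u=u)


def gen_genotypes(n: int, maf677: float, maf1298: float,
                  seed: int = 0) -> np.ndarray:
    """Draw (g677, g1298) allele counts for ``n`` subjects.

    Simulation is at the haplotype level: each of a subject's two
    haplotypes independently carries the 677T variant with probability
    ``maf677``, the 1298C variant with probability ``maf1298``, or
    neither. Because cis haplotypes carrying both variants are very rare
    in real populations they are excluded outright, which makes the
    trans constraint g677 + g1298 <= 2 hold by construction and the
    additive variant count a valid 0/1/2 instrument.

    Returns an ``(n, 2)`` integer array of columns (g677, g1298).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    for name, f in (("maf677", maf677), ("maf1298", maf1298)):
        if not (0.0 <= f < 1.0):
            raise ValueError(f"{name} must be in [0, 1), got {f}")
    p, q = float(maf677), float(maf1298)
    if p + q > 1.0:
        warnings.warn(
            "maf677 + maf1298 > 1: renormalizing haplotype frequencies",
            stacklevel=2)
        s = p + q
        p, q = p / s, q / s
    rng = _rng(seed, _STREAM_GENOTYPE)
    # haplotype states: 0 = wild-type, 1 = 677T, 2 = 1298C
    haps = rng.choice(3, size=(n, 2), p=[1.0 - p - q, p, q])
    g677 = (haps == 1).sum(axis=1)
    g1298 = (haps == 2).sum(axis=1)
    return np.column_stack([g677, g1298]).astype(np.int64)


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a cohort table and the latent confounder values.

    Returns ``(cohort, u)`` where ``cohort`` has columns subject_id,
    g677, g1298, variant_count, conception_planned, log_rbc_folate, and
    ``u`` is the per-subject standard-normal confounder. ``u`` is
    returned explicitly so that :func:`gen_methylation` can share it;
    analyses must never see it.
    """
    spec.validate()
    geno = gen_genotypes(spec.n, spec.maf677, spec.maf1298, seed=spec.seed)
    variant_count = geno.sum(axis=1)

    conception = (_rng(spec.seed, _STREAM_COVARIATE)
                  .random(spec.n) < spec.p_planned).astype(np.int64)
    u = _rng(spec.seed, _STREAM_CONFOUNDER).standard_normal(spec.n)
    e_x = _rng(spec.seed, _STREAM_NOISE).standard_normal(spec.n)

    folate = (spec.alpha0 + spec.alpha1 * variant_count
              + spec.alpha2 * conception + spec.alpha_c * u
              + spec.sigma_x * e_x)
    if not np.all(np.isfinite(folate)):
        raise ValueError("generated log_rbc_folate contains non-finite values")

    cohort = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(spec.n)],
        "g677": geno[:, 0],
        "g1298": geno[:, 1],
        "variant_count": variant_count,
        "conception_planned": conception,
        "log_rbc_folate": folate,
    })
    return cohort, u


def gen_probe_panel(n_probes: int, frac_sex: float, frac_cross_reactive: float,
                    frac_missing: float, seed: int = 0,
                    frac_distractor: float = 0.0,
                    allow_overlap: bool = False,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate probe annotations plus a per-probe missingness mask.

    Exactly ``round(n_probes * frac)`` probes are assigned to each
    artifact category (sex-chromosome placement, cross-reactivity flag,
    missing beta-values, non-normal distractor). Categories are disjoint
    unless ``allow_overlap`` is set, so filter-cascade counts are exact
    set arithmetic. The ``cross_reactive`` flag encodes the standard
    alignment-based criterion (>= 40 matching bases, >= 90% identity,
    end-nucleotide match, gapless) as a precomputed boolean.

    Returns ``(annotations, missing_mask)``; probes with
    ``missing_mask`` True should receive at least one missing beta.
    The annotation frame carries a boolean ``distractor`` column used by
    :func:`gen_methylation`.
    """
    for name, f in (("frac_sex", frac_sex),
                    ("frac_cross_reactive", frac_cross_reactive),
                    ("frac_missing", frac_missing),
                    ("frac_distractor", frac_distractor)):
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    if n_probes < 0:
        raise ValueError("n_probes must be non-negative")

    rng = _rng(seed, _STREAM_ANNOTATION)
    n_sex = round(n_probes * frac_sex)
    n_cross = round(n_probes * frac_cross_reactive)
    n_miss = round(n_probes * frac_missing)
    n_dist = round(n_probes * frac_distractor)

    if allow_overlap:
        sex_idx = rng.choice(n_probes, n_sex, replace=False) if n_sex else np.array([], int)
        cross_idx = rng.choice(n_probes, n_cross, replace=False) if n_cross else np.array([], int)
        miss_idx = rng.choice(n_probes, n_miss, replace=False) if n_miss else np.array([], int)
        dist_idx = rng.choice(n_probes, n_dist, replace=False) if n_dist else np.array([], int)
    else:
        total = n_sex + n_cross + n_miss + n_dist
        if total > n_probes:
            raise ValueError(
                "category fractions sum past 1 with allow_overlap=False")
        perm = rng.permutation(n_probes)
        sex_idx = perm[:n_sex]
        cross_idx = perm[n_sex:n_sex + n_cross]
        miss_idx = perm[n_sex + n_cross:n_sex + n_cross + n_miss]
        dist_idx = perm[n_sex + n_cross + n_miss:total]

    chrom = rng.choice([str(c) for c in range(1, 23)], size=n_probes)
    chrom = chrom.astype(object)
    if n_sex:
        chrom[sex_idx] = rng.choice(["X", "Y"], size=n_sex, p=[0.85, 0.15])

    cross = np.zeros(n_probes, dtype=bool)
    cross[cross_idx] = True
    missing = np.zeros(n_probes, dtype=bool)
    missing[miss_idx] = True
    distractor = np.zeros(n_probes, dtype=bool)
    distractor[dist_idx] = True

    position = rng.integers(0, 250_000_000, size=n_probes)
    # most probes annotate one gene; some list a second, comma-free symbol
    genes = []
    second = rng.random(n_probes) < 0.15
    for i in range(n_probes):
        g = f"GENE{i:05d}"
        genes.append(f"{g};GENE{i:05d}B" if second[i] else g)
    island = rng.choice(["island", "shore", "none"], size=n_probes,
                        p=[0.6, 0.2, 0.2])

    ann = pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
        "chromosome": chrom,
        "position": position,
        "gene_symbols": genes,
        "island_relation": island,
        "cross_reactive": cross,
        "distractor": distractor,
    })
    return ann, missing


def array27k_panel_fractions() -> dict[str, float]:
    """Artifact fractions that make the filter cascade behave like a
    27K promoter array: ~14% of probes lost to the sex-chromosome /
    cross-reactivity restriction, ~1.8% of the remainder to missing
    data, and ~27% of the remainder to the normality filter (bimodal
    distractors plus the test's own ~5% false-positive rate)."""
    return {
        "frac_sex": 0.105,
        "frac_cross_reactive": 0.036,
        "frac_missing": 0.015,
        "frac_distractor": 0.195,
    }


def gen_methylation(cohort: pd.DataFrame, confounders: np.ndarray,
                    profile: EffectProfile, annotations: pd.DataFrame,
                    seed: int = 0,
                    missing_probes: np.ndarray | None = None,
                    missing_rate: float = 0.0,
                    with_intensities: bool = False,
                    total_intensity: float = 4000.0) -> MethylationPanel:
    """Generate a methylation panel from the outcome model.

    The arcsine-scale outcome ``y`` is generated per probe from log
    folate, the conception indicator, the shared confounder, and probe
    noise, then clipped to [0, pi/2] and mapped to beta-values via
    ``sin^2(y)``. Probes flagged ``distractor`` in ``annotations`` (or
    the profile) draw ``y`` from a tight bimodal mixture instead, which
    the downstream normality filter should remove.

    ``missing_probes`` flags probes that receive exactly one missing
    beta (one subject at random); ``missing_rate`` additionally blanks
    cells uniformly at random. When ``with_intensities`` is set,
    methylated/unmethylated intensity pairs consistent with each beta
    are synthesized at the given total intensity.
    """
    n_sub = len(cohort)
    n_probes = profile.n_probes
    confounders = np.asarray(confounders, dtype=float)
    if confounders.shape[0] != n_sub:
        raise ValueError("confounder vector length must match cohort size")
    if len(annotations) != n_probes:
        raise ValueError("annotation rows must match profile rows")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")

    folate = cohort["log_rbc_folate"].to_numpy(dtype=float)
    conception = cohort["conception_planned"].to_numpy(dtype=float)

    rng = _rng(seed, _STREAM_METHYLATION)
    noise = rng.standard_normal((n_probes, n_sub))
    y = (profile.beta0[:, None]
         + profile.beta1[:, None] * folate[None, :]
         + profile.beta2[:, None] * conception[None, :]
         + profile.beta_c[:, None] * confounders[None, :]
         + profile.sigma_y[:, None] * noise)

    distractor = profile.distractor.copy()
    if "distractor" in annotations.columns:
        distractor |= annotations["distractor"].to_numpy(dtype=bool)
    if distractor.any():
        nd = int(distractor.sum())
        comp = rng.random((nd, n_sub)) < 0.5
        lo = rng.normal(0.35, 0.04, size=(nd, n_sub))
        hi = rng.normal(1.25, 0.04, size=(nd, n_sub))
        y[distractor] = np.where(comp, lo, hi)

    y = np.clip(y, 0.0, np.pi / 2)
    betas = np.sin(y) ** 2
    betas = np.clip(betas, 0.0, 1.0)

    miss_rng = _rng(seed, _STREAM_MISSING)
    if missing_rate > 0:
        betas[miss_rng.random(betas.shape) < missing_rate] = np.nan
    if missing_probes is not None:
        missing_probes = np.asarray(missing_probes, dtype=bool)
        if missing_probes.shape[0] != n_probes:
            raise ValueError("missing_probes mask length must match probes")
        for i in np.flatnonzero(missing_probes):
            betas[i, miss_rng.integers(n_sub)] = np.nan

    probe_ids = annotations["probe_id"].to_numpy()
    subj_ids = cohort["subject_id"].to_numpy()
    beta_df = pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"),
                           columns=subj_ids)

    m_df = u_df = None
    if with_intensities:
        # beta = M / (M + U + 100) with S = M + U fixed: feasible only for
        # beta <= S/(S+100), so cap at that bound before inverting.
        cap = total_intensity / (total_intensity + 100.0)
        b = np.minimum(np.nan_to_num(betas, nan=0.0), cap)
        m = b * (total_intensity + 100.0)
        u_int = total_intensity - m
        m_df = pd.DataFrame(m, index=beta_df.index, columns=subj_ids)
        u_df = pd.DataFrame(u_int, index=beta_df.index, columns=subj_ids)

    return MethylationPanel(annotations=annotations.reset_index(drop=True),
                            betas=beta_df, intensities_m=m_df,
                            intensities_u=u_df)


def make_gene_term_map(genes, n_terms: int = 40, seed: int = 0,
                       mean_genes_per_term: float = 12.0) -> pd.DataFrame:
    """Synthetic flat gene->category map for enrichment testing.

    Each term covers a Poisson-sized random subset of the supplied
    genes. Returns a two-column frame (term, gene).
    """
    rng = _rng(seed, _STREAM_ANNOTATION + 100)
    genes = list(genes)
    rows = []
    for t in range(n_terms):
        k = min(len(genes), max(1, rng.poisson(mean_genes_per_term)))
        members = rng.choice(len(genes), size=k, replace=False)
        for g in members:
            rows.append((f"T{t:04d}", genes[g]))
    return pd.DataFrame(rows, columns=["term", "gene"])
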