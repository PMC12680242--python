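"""Synthetic cohort generation, phenotype adjustment, and stratified splits.

Genotypes are independent biallelic SNPs sampled under Hardy-Weinberg
equilibrium (HWE); the phenotype is an additive polygenic trait with
configurable heritability plus age/sex nuisance effects. Linkage
disequilibrium is deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SingularFitError

__all__ = [
    "GenotypeMatrix",
    "CovariateTable",
    "Phenotype",
    "SplitAssignment",
    "generate_base_genotypes",
    "generate_covariates",
    "generate_phenotype",
    "adjust_phenotype",
    "stratified_split",
]


@dataclass
class GenotypeMatrix:
    """Hard-call dosage matrix (samples x SNPs) with per-SNP metadata.

    ``dosages`` holds minor-allele counts in {0, 1, 2}; ``maf`` is the
    declared per-SNP minor-allele frequency in (0, 0.5].
    """

    dosages: np.ndarray
    snp_ids: list[str]
    maf: np.ndarray
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if len(self.snp_ids) != self.n_snps or len(self.maf) != self.n_snps:
            raise ValueError("SNP metadata length mismatch")
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample id length mismatch")


@dataclass
class CovariateTable:
    """Per-sample age (years) and binary sex label (0/1)."""

    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        if self.age.shape != self.sex.shape:
            raise ValueError("age and sex must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.age)


@dataclass
class Phenotype:
    """Raw phenotype and (optionally) its adjusted, z-scored residual."""

    raw: np.ndarray
    adjusted: np.ndarray | None = None
    # bookkeeping from the generator, used by tests / diagnostics
    info: dict = field(default_factory=dict)


@dataclass
class SplitAssignment:
    """Per-sample split labels: 0=train, 1=validation, 2=test."""

    labels: np.ndarray
    fractions: tuple[float, float, float]

    LABEL_NAMES = ("train", "validation", "test")

    def mask(self, split: str) -> np.ndarray:
        return self.labels == self.LABEL_NAMES.index(split)

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == i).sum()) for i, name in enumerate(self.LABEL_NAMES)}


def generate_base_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Sample independent HWE SNPs with per-SNP MAF uniform in ``maf_range``.

    Genotype probabilities for a SNP with MAF p are ((1-p)^2, 2p(1-p), p^2).
    Deterministic given ``seed``.
    """
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if n_samples < 2 or n_snps < 1:
        raise ConfigurationError("need n_samples >= 2 and n_snps >= 1")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    # two independent Bernoulli(p) alleles per sample per SNP -> HWE by construction
    alleles = rng.random(size=(2, n_samples, n_snps)) < maf
    dosages = alleles.sum(axis=0).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=[f"snp_{j}" for j in range(n_snps)],
        maf=maf,
        sample_ids=[f"s_{i}" for i in range(n_samples)],
    )


def generate_covariates(
    n_samples: int,
    seed: int = 0,
    age_range: tuple[float, float] = (40.0, 69.0),
) -> CovariateTable:
    """Uniform ages and a balanced Bernoulli(0.5) sex label."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, size=n_samples)
    sex = (rng.random(n_samples) < 0.5).astype(int)
    # both sexes must be present for the stratified split to be meaningful
    if n_samples >= 2 and len(np.unique(sex)) == 1:
        sex[0] = 1 - sex[0]
    return CovariateTable(age=age, sex=sex)


def generate_phenotype(
    G: GenotypeMatrix,
    cov: CovariateTable,
    n_background: int = 200,
    h2: float = 0.5,
    age_effect: float = 0.0,
    sex_effect: float = 0.0,
    seed: int = 0,
) -> Phenotype:
    """Additive polygenic phenotype with heritability ``h2`` plus nuisance terms.

    ``n_background`` SNPs are drawn at random and given Gaussian effect
    sizes; the standardized genetic component is scaled so it explains
    fraction ``h2`` of the genetic-plus-noise variance. Age and sex enter
    linearly with the given coefficients.
    """
    if not (0.0 <= h2 < 1.0):
        raise ConfigurationError(f"h2 must be in [0, 1), got {h2}")
    if n_background > G.n_snps:
        raise ConfigurationError("n_background exceeds number of SNPs")
    rng = np.random.default_rng(seed)
    n = G.n_samples
    noise = rng.standard_normal(n)
    if h2 > 0 and n_background > 0:
        causal = rng.choice(G.n_snps, size=n_background, replace=False)
        beta = rng.standard_normal(n_background)
        genetic = G.dosages[:, causal].astype(float) @ beta
        gsd = genetic.std()
        if gsd == 0:
            raise ConfigurationError("degenerate genetic component (all-constant SNPs)")
        genetic = (genetic - genetic.mean()) / gsd
        core = np.sqrt(h2) * genetic + np.sqrt(1.0 - h2) * noise
    else:
        causal = np.empty(0, dtype=int)
        genetic = np.zeros(n)
        core = noise
    raw = core + age_effect * cov.age + sex_effect * cov.sex
    raw = raw - raw.mean()
    return Phenotype(
        raw=raw,
        info={
            "causal_snps": causal,
            "genetic_component": genetic,
            "h2": h2,
            "seed": seed,
        },
    )


def adjust_phenotype(
    pheno: Phenotype,
    cov: CovariateTable,
    fit_mask: np.ndarray | None = None,
) -> Phenotype:
    """OLS-residualize the raw phenotype on (intercept, age, sex), then z-score.

    The regression and the z-scoring statistics are fitted on ``fit_mask``
    (typically the training split) and applied to every sample.
    """
    n = len(pheno.raw)
    if fit_mask is None:
        fit_mask = np.ones(n, dtype=bool)
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if not fit_mask.any():
        raise ConfigurationError("fit_mask is empty")
    if not (np.isfinite(cov.age).all() and np.isfinite(cov.sex).all()):
        raise ConfigurationError("covariates must be finite")
    X = np.column_stack([np.ones(n), cov.age, cov.sex])
    Xf, yf = X[fit_mask], pheno.raw[fit_mask]
    if np.linalg.matrix_rank(Xf) < X.shape[1]:
        raise SingularFitError("degenerate covariate design on fit_mask")
    coef, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    resid = pheno.raw - X @ coef
    mu = resid[fit_mask].mean()
    sd = resid[fit_mask].std()
    if sd <= 1e-10 * max(float(pheno.raw.std()), 1.0):
        raise SingularFitError("residuals are (numerically) constant; cannot z-score")
    adjusted = (resid - mu) / sd
    return Phenotype(raw=pheno.raw, adjusted=adjusted, info=dict(pheno.info, adjust_coef=coef))


def stratified_split(
    cov: CovariateTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Sex-stratified random train/validation/test partition.

    Within each sex stratum samples are shuffled and allocated by
    largest-remainder rounding of the requested fractions.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must be 3 non-negatives summing to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    labels = np.empty(cov.n_samples, dtype=np.int8)
    for s in np.unique(cov.sex):
        idx = np.flatnonzero(cov.sex == s)
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fr)
        bounds = np.cumsum(counts)
        labels[idx[: bounds[0]]] = 0
        labels[idx[bounds[0]: bounds[1]]] = 1
        labels[idx[bounds[1]:]] = 2
    return SplitAssignment(labels=labels, fractions=tuple(fr))


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by fractions, largest remainders first."""
    exact = fractions * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:short]] += 1
    return counts
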