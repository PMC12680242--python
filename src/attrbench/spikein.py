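"""Phenotype-correlated spike-in SNP simulation.

Four effect architectures are supported: additive, dominant, recessive and
epistatic. All genotype columns are produced by rank-based discretization of
a latent Gaussian so that Hardy-Weinberg class counts hold exactly up to
integer rounding. The latent is

    z = rho * y + sqrt(1 - rho^2) * e,    e ~ N(0, 1) i.i.d.,

so corr(z, y) = rho on the latent scale; hard-call correlations are
attenuated and reported as diagnostics rather than re-calibrated.

Constraints (defaults, expressed at a reference cohort of 240,000 samples):
target |rho| in [0.018, 0.070], MAF in [0.05, 0.20], recessive expected
homozygous-alternate count >= 1200, dominant carrier fraction in
[0.10, 0.14], epistatic marginal |corr(g, y)| < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, SpecError

__all__ = [
    "SpikeInSpec",
    "SpikeInSet",
    "SpikeInConstraints",
    "sample_latent",
    "discretize_hwe",
    "gen_additive",
    "gen_dominant",
    "gen_recessive",
    "gen_epistatic_pair",
    "build_spikein_set",
]

EFFECT_TYPES = ("additive", "dominant", "recessive", "epistatic")

#: reference cohort size at which the raw count constraints are stated
REFERENCE_N = 240_000


@dataclass(frozen=True)
class SpikeInSpec:
    """Declared parameters of one spike-in SNP."""

    effect_type: str
    target_rho: float  # signed
    maf: float
    partner_id: str | None = None
    seed: int = 0


@dataclass(frozen=True)
class SpikeInConstraints:
    """Feasibility constraints, scaled relative to :data:`REFERENCE_N`."""

    rho_range: tuple[float, float] = (0.018, 0.070)
    #: separate target range for the interaction correlation; defaults to rho_range
    epistatic_rho_range: tuple[float, float] | None = None
    maf_range: tuple[float, float] = (0.05, 0.20)
    min_homalt_expected: float = 1200.0  # at REFERENCE_N; scales with n
    carrier_range: tuple[float, float] = (0.10, 0.14)
    epistatic_marginal_cap: float = 0.01

    @property
    def recessive_maf_floor(self) -> float:
        # n * p^2 >= min_homalt * (n / REFERENCE_N)  <=>  p >= sqrt(min/REF_N)
        return math.sqrt(self.min_homalt_expected / REFERENCE_N)

    def recessive_maf_range(self) -> tuple[float, float]:
        lo = max(self.maf_range[0], self.recessive_maf_floor)
        hi = self.maf_range[1]
        if lo > hi:
            raise SpecError(
                f"no feasible recessive MAF: floor {lo:.4f} exceeds range {self.maf_range}"
            )
        return (lo, hi)

    def dominant_maf_range(self) -> tuple[float, float]:
        # carrier fraction p(2-p) in carrier_range  <=>  p in [1-sqrt(1-lo), 1-sqrt(1-hi)]
        lo = max(self.maf_range[0], 1.0 - math.sqrt(1.0 - self.carrier_range[0]))
        hi = min(self.maf_range[1], 1.0 - math.sqrt(1.0 - self.carrier_range[1]))
        if lo > hi:
            raise SpecError(
                f"no feasible dominant MAF for carrier range {self.carrier_range} "
                f"within MAF range {self.maf_range}"
            )
        return (lo, hi)


@dataclass
class SpikeInSet:
    """Generated spike-in columns plus per-SNP specs and diagnostics."""

    genotypes: np.ndarray  # n_samples x n_spikes, int8 in {0,1,2}
    specs: list[SpikeInSpec]
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return [d["snp_id"] for d in self.diagnostics]

    @property
    def effect_types(self) -> np.ndarray:
        return np.array([s.effect_type for s in self.specs])

    @property
    def n_spikes(self) -> int:
        return self.genotypes.shape[1]

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diagnostics)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_latent(y: np.ndarray, rho: float, seed=0) -> np.ndarray:
    """Latent z = rho*y + sqrt(1-rho^2)*e with population corr(z, y) = rho."""
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = _rng(seed)
    e = rng.standard_normal(len(y))
    return rho * y + math.sqrt(1.0 - rho * rho) * e


def discretize_hwe(z: np.ndarray, p: float) -> np.ndarray:
    """Rank-discretize a latent into {0,1,2} with exact HWE class counts.

    The lowest (1-p)^2 fraction of z maps to 0, the top p^2 fraction to 2,
    the middle band to 1; counts are rounded to integers.
    """
    if not (0.0 < p <= 0.5):
        raise ValueError(f"MAF must be in (0, 0.5], got {p}")
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n == 0 or np.ptp(z) == 0.0:
        raise ValueError("degenerate latent: constant or empty")
    n0 = int(round((1.0 - p) ** 2 * n))
    n2 = int(round(p * p * n))
    if n0 + n2 > n:  # can only happen from rounding at tiny n
        n2 = n - n0
    order = np.argsort(z, kind="stable")
    g = np.ones(n, dtype=np.int8)
    g[order[:n0]] = 0
    if n2 > 0:
        g[order[n - n2:]] = 2
    return g


def _class_means(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    out = []
    for k in (0, 1, 2):
        m = g == k
        out.append(float(y[m].mean()) if m.any() else float("nan"))
    return tuple(out)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def gen_additive(
    y: np.ndarray,
    rho: float,
    p: float,
    seed=0,
    max_retries: int = 5,
) -> tuple[np.ndarray, dict]:
    """Additive spike-in: discretized y-correlated latent, linearity-checked.

    The heterozygote phenotype mean must sit near the midpoint of the two
    homozygote means (within 4 combined standard errors plus a rho-scaled
    slack for the mild nonlinearity of threshold discretization).
    """
    rng = _rng(seed)
    n = len(y)
    last = None
    for _ in range(max_retries):
        z = sample_latent(y, rho, rng)
        g = discretize_hwe(z, p)
        m0, m1, m2 = _class_means(g, y)
        n0, n1, n2 = [(g == k).sum() for k in (0, 1, 2)]
        se = math.sqrt(1.0 / max(n1, 1) + 0.25 / max(n0, 1) + 0.25 / max(n2, 1))
        dev = abs(m1 - 0.5 * (m0 + m2))
        diag = {
            "effect_type": "additive",
            "target_rho": rho,
            "maf": p,
            "latent_r": _corr(z, y),
            "realized_r": _corr(g, y),
            "m0": m0,
            "m1": m1,
            "m2": m2,
            "midpoint_dev": dev,
        }
        if dev <= 4.0 * se + 0.3 * abs(rho):
            return g, diag
        last = diag
    raise GenerationError(f"additive linearity check failed after {max_retries} tries: {last}")


def gen_dominant(
    y: np.ndarray,
    rho: float,
    p: float,
    seed=0,
    constraints: SpikeInConstraints = SpikeInConstraints(),
    max_retries: int = 5,
) -> tuple[np.ndarray, dict]:
    """Dominant spike-in: carrier indicator correlated with y, m1 ~= m2.

    Carrier status (g > 0) is assigned by thresholding a y-correlated latent
    at the carrier-fraction quantile; carriers are split into g=1 vs g=2 at
    the HWE conditional ratio 2(1-p):p independently of y.
    """
    carrier_frac = p * (2.0 - p)
    lo, hi = constraints.carrier_range
    if not (lo <= carrier_frac <= hi):
        raise SpecError(
            f"MAF {p:.4f} gives carrier fraction {carrier_frac:.4f} outside [{lo}, {hi}]"
        )
    rng = _rng(seed)
    n = len(y)
    n_carrier = int(round(carrier_frac * n))
    n2 = min(int(round(p * p * n)), n_carrier)
    last = None
    for _ in range(max_retries):
        z = sample_latent(y, rho, rng)
        order = np.argsort(z, kind="stable")
        carriers = order[n - n_carrier:]
        g = np.zeros(n, dtype=np.int8)
        g[carriers] = 1
        # within-carrier genotype split is independent of y
        hom = rng.permutation(n_carrier)[:n2]
        g[carriers[hom]] = 2
        m0, m1, m2 = _class_means(g, y)
        n1 = n_carrier - n2
        se12 = math.sqrt(1.0 / max(n1, 1) + 1.0 / max(n2, 1))
        diag = {
            "effect_type": "dominant",
            "target_rho": rho,
            "maf": p,
            "latent_r": _corr(z, y),
            "realized_r": _corr(g, y),
            "m0": m0,
            "m1": m1,
            "m2": m2,
            "carrier_fraction": n_carrier / n,
        }
        if abs(m1 - m2) <= 4.0 * se12:
            return g, diag
        last = diag
    raise GenerationError(f"dominant m1~=m2 check failed after {max_retries} tries: {last}")


def gen_recessive(
    y: np.ndarray,
    rho: float,
    p: float,
    seed=0,
    constraints: SpikeInConstraints = SpikeInConstraints(),
    max_retries: int = 5,
) -> tuple[np.ndarray, dict]:
    """Recessive spike-in: homozygous-alternate indicator correlated with y.

    Requires the scaled expected hom-alt count n*p^2 to meet the feasibility
    floor (1200 at the 240k reference scale, i.e. p >= sqrt(1200/240000)).
    """
    n = len(y)
    floor = constraints.recessive_maf_floor
    if p < floor:
        raise SpecError(
            f"MAF {p:.4f} infeasible for recessive effect: expected hom-alt count "
            f"n*p^2 = {n * p * p:.1f} below the scaled minimum "
            f"{constraints.min_homalt_expected * n / REFERENCE_N:.1f}; MAF floor is {floor:.4f}"
        )
    rng = _rng(seed)
    n2 = int(round(p * p * n))
    n1 = min(int(round(2.0 * p * (1.0 - p) * n)), n - n2)
    last = None
    for _ in range(max_retries):
        z = sample_latent(y, rho, rng)
        order = np.argsort(z, kind="stable")
        g = np.zeros(n, dtype=np.int8)
        homalt = order[n - n2:]
        g[homalt] = 2
        rest = order[: n - n2]
        het = rng.permutation(n - n2)[:n1]
        g[rest[het]] = 1
        m0, m1, m2 = _class_means(g, y)
        n0 = n - n1 - n2
        se01 = math.sqrt(1.0 / max(n0, 1) + 1.0 / max(n1, 1))
        diag = {
            "effect_type": "recessive",
            "target_rho": rho,
            "maf": p,
            "latent_r": _corr(z, y),
            "realized_r": _corr(g, y),
            "m0": m0,
            "m1": m1,
            "m2": m2,
            "homalt_count": int(n2),
            "homalt_expected": n * p * p,
        }
        if abs(m0 - m1) <= 4.0 * se01:
            return g, diag
        last = diag
    raise GenerationError(f"recessive m0~=m1 check failed after {max_retries} tries: {last}")


def gen_epistatic_pair(
    y: np.ndarray,
    rho_epi: float,
    pA: float,
    pB: float,
    seed=0,
    constraints: SpikeInConstraints = SpikeInConstraints(),
    line_search_tol: float = 0.005,
    max_line_search: int = 40,
    max_retries: int = 5,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Epistatic pair: interaction H = (gA-2pA)(gB-2pB) correlated with y.

    gA is a null HWE SNP. gB's latent is coupled to y with a weight whose
    sign follows sign(gA - 2pA) and whose magnitudes are balanced against
    the carrier fraction q: carriers get weight +alpha*(1-q), non-carriers
    -alpha*q. Because E[y | latent] is linear in the coupling weight, the
    marginal covariance of gB with y cancels exactly to first order while
    corr(H, y) grows monotonically in alpha. alpha is found by bisection on
    [0, 0.95] using common random numbers; marginal correlations are
    re-checked against the cap (relaxed to 4/sqrt(n) at small cohort sizes
    where sampling noise alone exceeds it) and the pair is regenerated on
    failure.
    """
    rng = _rng(seed)
    n = len(y)
    target = abs(rho_epi)
    sgn = 1.0 if rho_epi >= 0 else -1.0
    cap = max(constraints.epistatic_marginal_cap, 4.0 / math.sqrt(n))
    best_diag = None
    for _ in range(max_retries):
        gA = discretize_hwe(rng.standard_normal(n), pA)
        carrier = gA > 0  # same sign split as sign(gA - 2pA) for pA <= 0.25
        q = float(carrier.mean())
        w = np.where(carrier, 1.0 - q, -q) * sgn
        eB = rng.standard_normal(n)

        def h_corr(alpha: float) -> tuple[float, np.ndarray]:
            wa = alpha * w
            zB = wa * y + np.sqrt(1.0 - wa * wa) * eB
            gB = discretize_hwe(zB, pB)
            H = (gA - 2.0 * pA) * (gB - 2.0 * pB)
            return _corr(H, y), gB

        r_hi, gB_hi = h_corr(0.95)
        if sgn * r_hi < target - line_search_tol:
            best_diag = {"best_achievable_h_corr": r_hi, "alpha": 0.95}
            continue
        lo, hi = 0.0, 0.95
        alpha, r_cur, gB = 0.95, r_hi, gB_hi
        err = abs(sgn * r_hi - target)
        for _ in range(max_line_search):
            if err <= line_search_tol:
                break
            mid = 0.5 * (lo + hi)
            r_mid, gB_mid = h_corr(mid)
            e_mid = abs(sgn * r_mid - target)
            if e_mid < err:
                alpha, r_cur, gB, err = mid, r_mid, gB_mid, e_mid
            if sgn * r_mid < target:
                lo = mid
            else:
                hi = mid
        rA, rB = _corr(gA, y), _corr(gB, y)
        diag = {
            "effect_type": "epistatic",
            "target_rho": rho_epi,
            "maf_A": pA,
            "maf_B": pB,
            "alpha": alpha,
            "h_corr": r_cur,
            "marginal_r_A": rA,
            "marginal_r_B": rB,
        }
        if abs(sgn * r_cur - target) <= line_search_tol and max(abs(rA), abs(rB)) < cap:
            return gA, gB, diag
        best_diag = diag
    raise GenerationError(
        f"epistatic pair failed after {max_retries} tries (target {rho_epi}): {best_diag}"
    )


def build_spikein_set(
    y: np.ndarray,
    counts: tuple[int, int, int, int] = (100, 100, 100, 100),
    seed=0,
    constraints: SpikeInConstraints = SpikeInConstraints(),
) -> SpikeInSet:
    """Generate a full spike-in set (additive, dominant, recessive, epistatic).

    Target |rho| is drawn uniformly from the constraint range with random
    sign; MAFs are drawn uniformly from each effect type's feasible
    sub-range. Deterministic given ``seed``.
    """
    n_add, n_dom, n_rec, n_epi = counts
    if n_epi % 2 != 0:
        raise SpecError(f"epistatic count must be even (pairs), got {n_epi}")
    rng = _rng(seed)
    rho_lo, rho_hi = constraints.rho_range
    columns: list[np.ndarray] = []
    specs: list[SpikeInSpec] = []
    diags: list[dict] = []

    def draw_rho() -> float:
        mag = rng.uniform(rho_lo, rho_hi)
        return mag if rng.random() < 0.5 else -mag

    for i in range(n_add):
        rho = draw_rho()
        p = rng.uniform(*constraints.maf_range)
        g, d = gen_additive(y, rho, p, rng)
        d["snp_id"] = f"SPIKE_additive_{i}"
        columns.append(g)
        specs.append(SpikeInSpec("additive", rho, p))
        diags.append(d)
    dom_range = constraints.dominant_maf_range() if n_dom else None
    for i in range(n_dom):
        rho = draw_rho()
        p = rng.uniform(*dom_range)
        g, d = gen_dominant(y, rho, p, rng, constraints)
        d["snp_id"] = f"SPIKE_dominant_{i}"
        columns.append(g)
        specs.append(SpikeInSpec("dominant", rho, p))
        diags.append(d)
    rec_range = constraints.recessive_maf_range() if n_rec else None
    for i in range(n_rec):
        rho = draw_rho()
        p = rng.uniform(*rec_range)
        g, d = gen_recessive(y, rho, p, rng, constraints)
        d["snp_id"] = f"SPIKE_recessive_{i}"
        columns.append(g)
        specs.append(SpikeInSpec("recessive", rho, p))
        diags.append(d)
    epi_lo, epi_hi = constraints.epistatic_rho_range or constraints.rho_range
    for i in range(n_epi // 2):
        mag = rng.uniform(epi_lo, epi_hi)
        rho = mag if rng.random() < 0.5 else -mag
        pA = rng.uniform(*constraints.maf_range)
        pB = rng.uniform(*constraints.maf_range)
        gA, gB, d = gen_epistatic_pair(y, rho, pA, pB, rng, constraints)
        idA, idB = f"SPIKE_epistatic_{2 * i}", f"SPIKE_epistatic_{2 * i + 1}"
        dA = dict(d, snp_id=idA, maf=pA)
        dB = dict(d, snp_id=idB, maf=pB)
        columns.extend([gA, gB])
        specs.append(SpikeInSpec("epistatic", rho, pA, partner_id=idB))
        specs.append(SpikeInSpec("epistatic", rho, pB, partner_id=idA))
        diags.extend([dA, dB])

    genotypes = (
        np.column_stack(columns).astype(np.int8)
        if columns
        else np.empty((len(y), 0), dtype=np.int8)
    )
    return SpikeInSet(genotypes=genotypes, specs=specs, diagnostics=diags)
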