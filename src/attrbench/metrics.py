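"""Benchmark metrics: recall, precision, ensemble consistency, composite.

Recall counts spike-in SNPs recovered in the top-K of the combined ranking;
precision compares decoy vs real counts in the top-K of the expanded
ranking; consistency summarizes per-SNP relative standard deviation (RSD)
across an ensemble; the composite score is the geometric mean of top-1%
micro recall, top-1% precision, and the half-life-transformed median RSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "MAD_SCALE",
    "TopKSelection",
    "ConsistencyStats",
    "topk",
    "recall_by_effect",
    "micro_recall",
    "precision_at_k",
    "consistency",
    "median_rsd_tau",
    "half_life_transform",
    "composite",
]

#: normal-consistency constant 1/Phi^-1(0.75), conventionally quoted as 1.4826
MAD_SCALE = 1.0 / stats.norm.ppf(0.75)


@dataclass
class TopKSelection:
    q: float
    k: int
    members: np.ndarray  # feature indices, |members| = k


@dataclass
class ConsistencyStats:
    rsd: np.ndarray          # per-SNP RSD over SNPs with nonzero mean
    median_rsd: float
    scaled_mad: float
    n_excluded_zero_mean: int


def topk(S: np.ndarray, q: float) -> TopKSelection:
    """Top floor(q * len(S)) features by score, ties broken by lower index."""
    if not (0.0 < q <= 1.0):
        raise ConfigurationError(f"quantile must be in (0, 1], got {q}")
    S = np.asarray(S, dtype=float)
    k = int(np.floor(q * len(S)))
    # primary key: descending score; secondary: ascending index (stable)
    order = np.lexsort((np.arange(len(S)), -S))
    return TopKSelection(q=q, k=k, members=order[:k])


def recall_by_effect(
    sel: TopKSelection,
    effect_types: np.ndarray,
    spike_indices: np.ndarray,
) -> dict[str, float | None]:
    """Fraction of each effect class's spike-ins inside the top-K.

    ``spike_indices`` are the positions of the spike-in columns within the
    ranked feature vector; ``effect_types`` labels each spike-in. Empty
    classes are reported as None.
    """
    members = set(sel.members.tolist())
    out: dict[str, float | None] = {}
    for effect in dict.fromkeys(effect_types.tolist()):
        idx = spike_indices[effect_types == effect]
        if len(idx) == 0:
            out[effect] = None
            continue
        hits = sum(1 for j in idx.tolist() if j in members)
        out[effect] = hits / len(idx)
    return out


def micro_recall(per_effect: dict[str, tuple[int, int]]) -> float:
    """Total true positives over total spike-ins, pooled across effect types.

    ``per_effect`` maps effect type -> (hits, class size).
    """
    hits = sum(h for h, _ in per_effect.values())
    total = sum(t for _, t in per_effect.values())
    if total == 0:
        raise ConfigurationError("no spike-ins to compute micro recall over")
    return hits / total


def precision_at_k(sel: TopKSelection, is_decoy: np.ndarray) -> float | None:
    """1 - (#decoys in top-K) / (#real in top-K); None if no real features."""
    is_decoy = np.asarray(is_decoy, dtype=bool)
    in_top = is_decoy[sel.members]
    n_decoy = int(in_top.sum())
    n_real = len(in_top) - n_decoy
    if n_real == 0:
        return None
    return 1.0 - n_decoy / n_real


def consistency(ensemble_scores: np.ndarray) -> ConsistencyStats:
    """Per-SNP RSD = sd/mean across M >= 2 ensemble importance vectors.

    Uses the sample (n-1) standard deviation. SNPs whose across-ensemble
    mean is zero are excluded and counted.
    """
    S = np.asarray(ensemble_scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ConfigurationError("need an M x n_snps matrix with M >= 2")
    mu = S.mean(axis=0)
    sd = S.std(axis=0, ddof=1)
    nonzero = mu != 0
    rsd = sd[nonzero] / mu[nonzero]
    med = float(np.median(rsd))
    mad = float(MAD_SCALE * np.median(np.abs(rsd - med)))
    return ConsistencyStats(
        rsd=rsd,
        median_rsd=med,
        scaled_mad=mad,
        n_excluded_zero_mean=int((~nonzero).sum()),
    )


def median_rsd_tau(median_rsds) -> float:
    """Half-life constant: median of the per-variant median RSDs."""
    vals = np.asarray(list(median_rsds), dtype=float)
    if len(vals) == 0:
        raise ConfigurationError("tau requires at least one method variant")
    return float(np.median(vals))


def half_life_transform(x: float, tau: float) -> float:
    """Stability S = 2^(-x/tau) in [0, 1]; halves for every tau of RSD."""
    if tau <= 0:
        raise ConfigurationError(f"tau must be positive, got {tau}")
    return float(2.0 ** (-x / tau))


def composite(recall: float, precision: float, stability: float) -> float:
    """Geometric mean of the three [0, 1] components."""
    comps = (recall, precision, stability)
    if any(c < 0 for c in comps):
        raise ConfigurationError(f"composite components must be non-negative: {comps}")
    if any(c == 0 for c in comps):
        return 0.0
    return float(np.prod(comps) ** (1.0 / 3.0))
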