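"""End-to-end benchmark orchestration.

Three experiments are run from a single :class:`RunConfig`:

* recall      — train on base genotypes + spike-ins, measure per-effect
                recall of each attribution variant (plus a GWAS baseline);
* precision   — train on [real | decoy] expanded features, measure the
                decoy-estimated precision of each variant;
* consistency — train an M-member ensemble on real features, summarize
                per-SNP attribution RSD per variant.

Every random draw derives from the master seed through named
``numpy.random.SeedSequence`` children, so a report is reproducible
byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import attributions as attr
from . import metrics
from .cohort import (
    adjust_phenotype,
    generate_base_genotypes,
    generate_covariates,
    generate_phenotype,
    stratified_split,
)
from .decoys import DecoyConfig, expand_features
from .errors import ConfigurationError
from .models import EnsembleSpec, NetworkSpec, TrainConfig, gwas_scan, train_model
from .spikein import SpikeInConstraints, build_spikein_set

__all__ = [
    "CohortConfig",
    "RunConfig",
    "BenchmarkReport",
    "desk_profile",
    "paper_profile",
    "run_recall_benchmark",
    "run_precision_benchmark",
    "run_consistency_benchmark",
    "run_all",
]

DEFAULT_THRESHOLDS = (0.01, 0.02, 0.03, 0.05, 0.10, 0.20)


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 2000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_background: int = 50
    h2: float = 0.6
    age_effect: float = 0.02
    sex_effect: float = 0.5
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)


@dataclass(frozen=True)
class RunConfig:
    profile: str = "desk"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spike_counts: tuple[int, int, int, int] = (10, 10, 10, 10)
    spike_constraints: SpikeInConstraints = field(default_factory=SpikeInConstraints)
    decoy: DecoyConfig = field(default_factory=DecoyConfig)
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(hidden_sizes=(64, 32, 16)))
    training: TrainConfig = field(default_factory=lambda: TrainConfig(lr=1e-3, epochs=20))
    ensemble_size: int = 3
    methods: tuple[str, ...] = attr.METHODS
    smoothing_flags: tuple[bool, ...] = (False, True)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    master_seed: int = 0
    ig_steps: int = 50
    shap_samples: int = 5
    sg_noise: int = 5
    sg_noise_scale: float = 0.1  # times per-feature training std

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ConfigurationError("thresholds must be sorted ascending")
        if any(not (0 < t <= 1) for t in self.thresholds):
            raise ConfigurationError("thresholds must lie in (0, 1]")


def desk_profile(master_seed: int = 0) -> RunConfig:
    """Reduced configuration sized for a single CPU and a few minutes.

    Spike-in correlation targets and MAFs are inflated relative to the
    reference constraints so that the small network can learn them from
    ~2k samples; the carrier-fraction window is widened accordingly.
    """
    return RunConfig(
        profile="desk",
        master_seed=master_seed,
        cohort=CohortConfig(n_background=200, h2=0.6),
        spike_constraints=SpikeInConstraints(
            rho_range=(0.40, 0.55),
            epistatic_rho_range=(0.12, 0.22),
            maf_range=(0.15, 0.30),
            carrier_range=(0.10, 0.51),
        ),
        network=NetworkSpec(hidden_sizes=(64, 32, 16), dropout=0.2),
        training=TrainConfig(lr=1e-3, epochs=40),
        decoy=DecoyConfig(decoy_seed=master_seed, chunk_size=250),
    )


def paper_profile(master_seed: int = 0) -> RunConfig:
    """Full-scale configuration mirroring the published experiment sizes."""
    return RunConfig(
        profile="paper",
        cohort=CohortConfig(n_samples=300_000, n_snps=500_000, n_background=200, h2=0.5),
        spike_counts=(100, 100, 100, 100),
        spike_constraints=SpikeInConstraints(),
        decoy=DecoyConfig(decoy_seed=master_seed),
        network=NetworkSpec(hidden_sizes=(1000, 200, 50)),
        training=TrainConfig(lr=1e-6, epochs=100),
        ensemble_size=10,
        master_seed=master_seed,
    )


# ----- seed bookkeeping -------------------------------------------------------

_STAGE_IDS = {
    "cohort": 0,
    "covariates": 1,
    "phenotype": 2,
    "split": 3,
    "spikein": 4,
    "train_recall": 5,
    "train_precision": 6,
    "train_ensemble": 7,
    "attribution": 8,
}


def _stable_hash(text: str) -> int:
    """Process-independent 31-bit hash (Python's str hash is randomized)."""
    import zlib

    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_IDS[stage], index))
    return int(ss.generate_state(1)[0])


# ----- shared pipeline pieces -------------------------------------------------


def _build_cohort(cfg: RunConfig):
    c = cfg.cohort
    G = generate_base_genotypes(
        c.n_samples, c.n_snps, c.maf_range, seed=stage_seed(cfg.master_seed, "cohort")
    )
    cov = generate_covariates(c.n_samples, seed=stage_seed(cfg.master_seed, "covariates"))
    pheno = generate_phenotype(
        G, cov, c.n_background, c.h2, c.age_effect, c.sex_effect,
        seed=stage_seed(cfg.master_seed, "phenotype"),
    )
    split = stratified_split(cov, c.fractions, seed=stage_seed(cfg.master_seed, "split"))
    pheno = adjust_phenotype(pheno, cov, fit_mask=split.mask("train"))
    return G, cov, pheno, split


def _attribute_variants(cfg: RunConfig, model, X_test, X_train, tag: str):
    """All method x smoothing attribution results for one trained model."""
    baseline = attr.mode_baseline(X_train)
    sg_sd = cfg.sg_noise_scale * X_train.std(axis=0)
    out = {}
    for method in cfg.methods:
        for smoothing in cfg.smoothing_flags:
            res = attr.compute_attribution(
                method,
                model,
                X_test,
                baseline,
                smoothing=smoothing,
                n_steps=cfg.ig_steps,
                shap_samples=cfg.shap_samples,
                sg_noise=cfg.sg_noise,
                sg_noise_sd=sg_sd,
                seed=stage_seed(cfg.master_seed, "attribution",
                                index=_stable_hash(f"{tag}|{method}|{smoothing}")),
            )
            out[(method, smoothing)] = res
    return out


def _variant_key(method: str, smoothing: bool) -> str:
    return f"{method}|{'smooth' if smoothing else 'raw'}"


# ----- benchmarks -------------------------------------------------------------


def run_recall_benchmark(cfg: RunConfig) -> dict:
    """Spike-in recall per method variant, threshold, and effect type."""
    t0 = time.time()
    G, cov, pheno, split = _build_cohort(cfg)
    y = pheno.adjusted
    spikes = build_spikein_set(
        y, cfg.spike_counts, seed=stage_seed(cfg.master_seed, "spikein"),
        constraints=cfg.spike_constraints,
    )
    X = np.concatenate([G.dosages, spikes.genotypes], axis=1).astype(float)
    spike_idx = np.arange(G.n_snps, X.shape[1])
    tr, va, te = split.mask("train"), split.mask("validation"), split.mask("test")
    model, log = train_model(
        X[tr], y[tr], X[va], y[va], cfg.network,
        replace(cfg.training, shuffle_seed=stage_seed(cfg.master_seed, "train_recall")),
    )
    results = _attribute_variants(cfg, model, X[te], X[tr], tag="recall")
    gwas = gwas_scan(X[tr], y[tr])
    effect_types = spikes.effect_types
    class_sizes = {e: int((effect_types == e).sum()) for e in dict.fromkeys(effect_types)}

    rows = {}
    importances = {_variant_key(m, s): r.importance for (m, s), r in results.items()}
    importances["gwas|raw"] = gwas.importance
    for key, S in importances.items():
        per_thr = {}
        for q in cfg.thresholds:
            sel = metrics.topk(S, q)
            rec = metrics.recall_by_effect(sel, effect_types, spike_idx)
            hits = {e: (int(round(r * class_sizes[e])) if r is not None else 0, class_sizes[e])
                    for e, r in rec.items()}
            per_thr[f"{q:g}"] = {
                "k": sel.k,
                "recall": rec,
                "micro_recall": metrics.micro_recall(hits),
            }
        rows[key] = per_thr
    return {
        "benchmark": "recall",
        "n_features": int(X.shape[1]),
        "val_pearson": log["best_val_pearson"],
        "variants": rows,
        "elapsed_s": round(time.time() - t0, 2),
    }


def run_precision_benchmark(cfg: RunConfig) -> dict:
    """Decoy-estimated precision per method variant and threshold."""
    t0 = time.time()
    G, cov, pheno, split = _build_cohort(cfg)
    y = pheno.adjusted
    tr, va, te = split.mask("train"), split.mask("validation"), split.mask("test")
    Xtr, is_decoy = expand_features(G.dosages[tr], cfg.decoy, "train")
    Xva, _ = expand_features(G.dosages[va], cfg.decoy, "validation")
    Xte, _ = expand_features(G.dosages[te], cfg.decoy, "test")
    Xtr = Xtr.astype(float)
    model, log = train_model(
        Xtr, y[tr], Xva.astype(float), y[va], cfg.network,
        replace(cfg.training, shuffle_seed=stage_seed(cfg.master_seed, "train_precision")),
    )
    results = _attribute_variants(cfg, model, Xte.astype(float), Xtr, tag="precision")
    rows = {}
    for (method, smoothing), res in results.items():
        per_thr = {}
        for q in cfg.thresholds:
            sel = metrics.topk(res.importance, q)
            per_thr[f"{q:g}"] = {
                "k": sel.k,
                "precision": metrics.precision_at_k(sel, is_decoy),
            }
        rows[_variant_key(method, smoothing)] = per_thr
    return {
        "benchmark": "precision",
        "n_features": int(Xtr.shape[1]),
        "val_pearson": log["best_val_pearson"],
        "variants": rows,
        "elapsed_s": round(time.time() - t0, 2),
    }


def run_consistency_benchmark(cfg: RunConfig) -> dict:
    """Ensemble RSD statistics per method variant."""
    t0 = time.time()
    G, cov, pheno, split = _build_cohort(cfg)
    y = pheno.adjusted
    tr, va, te = split.mask("train"), split.mask("validation"), split.mask("test")
    X = G.dosages.astype(float)
    member_scores: dict[str, list[np.ndarray]] = {}
    for m_idx in range(cfg.ensemble_size):
        member_cfg = replace(
            cfg.training,
            shuffle_seed=stage_seed(cfg.master_seed, "train_ensemble", index=2 * m_idx),
            init_seed=stage_seed(cfg.master_seed, "train_ensemble", index=2 * m_idx + 1),
        )
        model, _ = train_model(X[tr], y[tr], X[va], y[va], cfg.network, member_cfg)
        results = _attribute_variants(cfg, model, X[te], X[tr], tag=f"ens{m_idx}")
        for (method, smoothing), res in results.items():
            member_scores.setdefault(_variant_key(method, smoothing), []).append(res.importance)
    rows = {}
    for key, scores in member_scores.items():
        stats_ = metrics.consistency(np.stack(scores))
        rows[key] = {
            "median_rsd": stats_.median_rsd,
            "scaled_mad": stats_.scaled_mad,
            "n_excluded_zero_mean": stats_.n_excluded_zero_mean,
        }
    return {
        "benchmark": "consistency",
        "ensemble_size": cfg.ensemble_size,
        "variants": rows,
        "elapsed_s": round(time.time() - t0, 2),
    }


@dataclass
class BenchmarkReport:
    """Full machine-readable benchmark output (recall/precision/consistency
    fragments, composite table, and the reproducibility manifest)."""

    recall: dict
    precision: dict
    consistency: dict
    composite: dict
    manifest: dict

    def to_json(self, include_timing: bool = False) -> str:
        """Serialize deterministically; wall-clock timings are excluded by
        default so reruns with the same seed are byte-identical."""
        payload = {
            "recall": dict(self.recall),
            "precision": dict(self.precision),
            "consistency": dict(self.consistency),
            "composite": self.composite,
            "manifest": self.manifest,
        }
        if not include_timing:
            for frag in ("recall", "precision", "consistency"):
                payload[frag].pop("elapsed_s", None)
        return json.dumps(payload, indent=2, sort_keys=True)


def run_all(cfg: RunConfig, composite_threshold: float | None = None) -> BenchmarkReport:
    """Run the three benchmarks and assemble the composite table.

    tau for the half-life transform is the median of the median RSDs over
    exactly the method x smoothing variants configured for this run. The
    composite uses the top-1% threshold when configured, else the strictest
    configured threshold.
    """
    if composite_threshold is None:
        composite_threshold = 0.01 if 0.01 in cfg.thresholds else cfg.thresholds[0]
    recall = run_recall_benchmark(cfg)
    precision = run_precision_benchmark(cfg)
    consist = run_consistency_benchmark(cfg)
    qkey = f"{composite_threshold:g}"
    variant_keys = [
        _variant_key(m, s) for m in cfg.methods for s in cfg.smoothing_flags
    ]
    tau = metrics.median_rsd_tau(
        consist["variants"][k]["median_rsd"] for k in variant_keys
    )
    comp_rows = {}
    for key in variant_keys:
        rec = recall["variants"][key][qkey]["micro_recall"]
        prec = precision["variants"][key][qkey]["precision"]
        stab = metrics.half_life_transform(consist["variants"][key]["median_rsd"], tau)
        comp_rows[key] = {
            "micro_recall_top": rec,
            "precision_top": prec,
            "stability": stab,
            # a negative (decoy-dominated) precision has no composite reading;
            # the cell is flagged missing rather than failing the report
            "composite": (
                metrics.composite(rec, prec, stab)
                if prec is not None and prec >= 0
                else None
            ),
        }
    manifest = {
        "master_seed": cfg.master_seed,
        "profile": cfg.profile,
        "config": _config_dict(cfg),
        "tau": tau,
        "composite_threshold": composite_threshold,
    }
    return BenchmarkReport(recall, precision, consist, comp_rows, manifest)


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    # dict keys and tuples already JSON-friendly; ensure determinism via sort in to_json
    return d
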