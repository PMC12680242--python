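"""Feed-forward regression network and GWAS linear baseline.

The network is a plain NumPy implementation (dense layers with ReLU, batch
normalization and dropout; single linear output) trained with Adam on mean
absolute error plus an explicit L2 penalty. Both the optimizer weight decay
and the explicit L2 factor are implemented and independently switchable,
since under Adam they are not redundant.

In inference mode batch normalization uses running statistics and dropout is
disabled, so the network reduces to a stack of affine maps and ReLUs; the
attribution module relies on that folded form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError, StageError

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "EnsembleSpec",
    "GwasResult",
    "MLPRegressor",
    "train_model",
    "train_ensemble",
    "gwas_scan",
]


@dataclass(frozen=True)
class NetworkSpec:
    hidden_sizes: tuple[int, ...] = (1000, 200, 50)
    dropout: float = 0.5
    batchnorm: bool = True
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ConfigurationError("need at least one hidden layer")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-6
    weight_decay: float = 1e-3   # Adam-coupled decay, added to the gradient
    l2_factor: float = 1e-3      # explicit penalty l2 * sum(W^2) in the loss
    batch_size: int = 128
    epochs: int = 100
    shuffle_seed: int = 0
    init_seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1 or self.lr <= 0:
            raise ConfigurationError("batch_size and lr must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    n_members: int = 10
    member_seeds: tuple[int, ...] | None = None

    def seeds(self) -> tuple[int, ...]:
        seeds = (
            tuple(self.member_seeds)
            if self.member_seeds is not None
            else tuple(range(self.n_members))
        )
        if len(seeds) != self.n_members:
            raise ConfigurationError("member_seeds length must equal n_members")
        if len(set(seeds)) != len(seeds):
            raise ConfigurationError("ensemble member seeds must be pairwise distinct")
        return seeds


class MLPRegressor:
    """Fully connected ReLU regressor with per-layer batch-norm and dropout."""

    def __init__(self, n_features: int, spec: NetworkSpec, init_seed: int = 0):
        self.spec = spec
        self.n_features = n_features
        rng = np.random.default_rng(init_seed)
        sizes = [n_features, *spec.hidden_sizes, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / math.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))
        nh = len(spec.hidden_sizes)
        self.gamma = [np.ones(h) for h in spec.hidden_sizes] if spec.batchnorm else [None] * nh
        self.beta = [np.zeros(h) for h in spec.hidden_sizes] if spec.batchnorm else [None] * nh
        self.run_mean = [np.zeros(h) for h in spec.hidden_sizes]
        self.run_var = [np.ones(h) for h in spec.hidden_sizes]

    # ----- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        params = [*self.W, *self.b]
        if self.spec.batchnorm:
            params += [*self.gamma, *self.beta]
        return params

    def state(self) -> dict:
        return {
            "W": [w.copy() for w in self.W],
            "b": [b.copy() for b in self.b],
            "gamma": [g.copy() if g is not None else None for g in self.gamma],
            "beta": [b.copy() if b is not None else None for b in self.beta],
            "run_mean": [m.copy() for m in self.run_mean],
            "run_var": [v.copy() for v in self.run_var],
        }

    def load_state(self, state: dict) -> None:
        self.W = [w.copy() for w in state["W"]]
        self.b = [b.copy() for b in state["b"]]
        self.gamma = [g.copy() if g is not None else None for g in state["gamma"]]
        self.beta = [b.copy() if b is not None else None for b in state["beta"]]
        self.run_mean = [m.copy() for m in state["run_mean"]]
        self.run_var = [v.copy() for v in state["run_var"]]

    # ----- inference ----------------------------------------------------------

    def folded_layers(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Inference-mode network as affine layers [(A, c), ...].

        Hidden layer l computes ReLU(x @ A + c) with batch-norm (running
        statistics) folded into the affine map; the last tuple is the linear
        output layer.
        """
        layers = []
        for l, h in enumerate(self.spec.hidden_sizes):
            W, b = self.W[l], self.b[l]
            if self.spec.batchnorm:
                scale = self.gamma[l] / np.sqrt(self.run_var[l] + self.spec.bn_eps)
                A = W * scale
                c = (b - self.run_mean[l]) * scale + self.beta[l]
            else:
                A, c = W, b
            layers.append((A, c))
        layers.append((self.W[-1], self.b[-1]))
        return layers

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass; returns shape (n,)."""
        a = np.asarray(X, dtype=float)
        layers = self.folded_layers()
        for A, c in layers[:-1]:
            a = np.maximum(a @ A + c, 0.0)
        A, c = layers[-1]
        return (a @ A + c)[:, 0]

    # ----- training -----------------------------------------------------------

    def _forward_train(self, X: np.ndarray, drop_rng: np.random.Generator):
        cache = {"a": [X], "z": [], "zhat": [], "mu": [], "var": [], "mask": []}
        a = X
        p = self.spec.dropout
        for l in range(len(self.spec.hidden_sizes)):
            z = a @ self.W[l] + self.b[l]
            cache["z"].append(z)
            if self.spec.batchnorm:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                zhat = (z - mu) / np.sqrt(var + self.spec.bn_eps)
                out = self.gamma[l] * zhat + self.beta[l]
                m = self.spec.bn_momentum
                nb = z.shape[0]
                unbiased = var * nb / max(nb - 1, 1)
                self.run_mean[l] = (1 - m) * self.run_mean[l] + m * mu
                self.run_var[l] = (1 - m) * self.run_var[l] + m * unbiased
                cache["mu"].append(mu)
                cache["var"].append(var)
                cache["zhat"].append(zhat)
            else:
                out = z
                cache["mu"].append(None)
                cache["var"].append(None)
                cache["zhat"].append(None)
            a = np.maximum(out, 0.0)
            if p > 0:
                mask = (drop_rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
            else:
                mask = None
            cache["mask"].append(mask)
            cache["a"].append(a)
        yhat = (a @ self.W[-1] + self.b[-1])[:, 0]
        return yhat, cache

    def _backward(self, yhat: np.ndarray, y: np.ndarray, cache: dict, l2: float):
        nb = len(y)
        nh = len(self.spec.hidden_sizes)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gGamma = [None] * nh
        gBeta = [None] * nh
        # MAE loss
        dy = np.sign(yhat - y)[:, None] / nb
        a_last = cache["a"][-1]
        gW[-1] = a_last.T @ dy
        gb[-1] = dy.sum(axis=0)
        da = dy @ self.W[-1].T
        for l in range(nh - 1, -1, -1):
            mask = cache["mask"][l]
            if mask is not None:
                da = da * mask
            if self.spec.batchnorm:
                bn_out = self.gamma[l] * cache["zhat"][l] + self.beta[l]
            else:
                bn_out = cache["z"][l]
            dout = da * (bn_out > 0)
            if self.spec.batchnorm:
                zhat, var = cache["zhat"][l], cache["var"][l]
                std = np.sqrt(var + self.spec.bn_eps)
                gGamma[l] = (dout * zhat).sum(axis=0)
                gBeta[l] = dout.sum(axis=0)
                dzhat = dout * self.gamma[l]
                m = dout.shape[0]
                dz = (
                    dzhat - dzhat.mean(axis=0) - zhat * (dzhat * zhat).mean(axis=0)
                ) / std
            else:
                dz = dout
            gW[l] = cache["a"][l].T @ dz
            gb[l] = dz.sum(axis=0)
            if l > 0:
                da = dz @ self.W[l].T
        if l2 > 0:
            for l in range(len(self.W)):
                gW[l] = gW[l] + 2.0 * l2 * self.W[l]
        grads = [*gW, *gb]
        if self.spec.batchnorm:
            grads += [*gGamma, *gBeta]
        return grads


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], weights: int) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.adam_beta1**self.t
        b2t = 1.0 - c.adam_beta2**self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            if c.weight_decay > 0 and i < weights:  # decay weight matrices only
                g = g + c.weight_decay * p
            self.m[i] = c.adam_beta1 * self.m[i] + (1 - c.adam_beta1) * g
            self.v[i] = c.adam_beta2 * self.v[i] + (1 - c.adam_beta2) * g * g
            p -= c.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + c.adam_eps)


def train_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: NetworkSpec = NetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[MLPRegressor, dict]:
    """Train with Adam on MAE + L2, checkpointing the best-validation epoch.

    Returns the model restored to the epoch with the highest validation
    Pearson correlation, plus a log with per-epoch train loss and
    validation r.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if X_train.shape[1] != X_val.shape[1]:
        raise ConfigurationError("train/validation feature dimensions differ")
    model = MLPRegressor(X_train.shape[1], spec, init_seed=cfg.init_seed)
    params = model.parameters()
    opt = _Adam(params, cfg)
    shuffle_rng = np.random.default_rng(cfg.shuffle_seed)
    drop_rng = np.random.default_rng(cfg.shuffle_seed + 1)
    n = len(y_train)
    log = {"train_loss": [], "val_pearson": [], "best_epoch": -1}
    best_r, best_state = -np.inf, None
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            yhat, cache = model._forward_train(xb, drop_rng)
            loss = np.abs(yhat - yb).mean()
            if not np.isfinite(loss):
                raise StageError(f"non-finite training loss at epoch {epoch}")
            if cfg.l2_factor > 0:
                loss += cfg.l2_factor * sum(float((w * w).sum()) for w in model.W)
            epoch_loss += loss * len(idx)
            grads = model._backward(yhat, yb, cache, cfg.l2_factor)
            opt.step(params, grads, weights=len(model.W))
        val_r = _pearson(model.predict(X_val), y_val)
        log["train_loss"].append(epoch_loss / n)
        log["val_pearson"].append(val_r)
        if val_r > best_r:
            best_r = val_r
            best_state = model.state()
            log["best_epoch"] = epoch
    model.load_state(best_state)
    log["best_val_pearson"] = best_r
    return model, log


def train_ensemble(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: NetworkSpec = NetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
    ens: EnsembleSpec = EnsembleSpec(),
) -> list[tuple[MLPRegressor, dict]]:
    """Train M models differing only by seed-controlled shuffling and init."""
    members = []
    for seed in ens.seeds():
        member_cfg = replace(cfg, shuffle_seed=cfg.shuffle_seed + 7919 * (seed + 1),
                             init_seed=cfg.init_seed + 104729 * (seed + 1))
        members.append(train_model(X_train, y_train, X_val, y_val, spec, member_cfg))
    return members


@dataclass
class GwasResult:
    """Per-SNP simple linear regression against the adjusted phenotype."""

    snp_ids: list[str]
    beta: np.ndarray
    pvalue: np.ndarray
    importance: np.ndarray  # -log10(p); 0 for monomorphic SNPs
    monomorphic: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta": self.beta,
                "p": self.pvalue,
                "neglog10p": self.importance,
            }
        )


def gwas_scan(
    genotypes: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str] | None = None,
) -> GwasResult:
    """Vectorized per-SNP OLS slope + two-sided t-test; importance = -log10 p.

    Monomorphic SNPs get beta 0, p 1, importance 0 and are flagged.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if n < 3:
        raise ConfigurationError("need at least 3 samples for the t-test")
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ss_g = (gc * gc).sum(axis=0)
    mono = ss_g == 0
    ss_g_safe = np.where(mono, 1.0, ss_g)
    beta = (gc * yc[:, None]).sum(axis=0) / ss_g_safe
    ss_y = float((yc * yc).sum())
    r2 = np.clip(beta * beta * ss_g_safe / ss_y if ss_y > 0 else np.zeros(m), 0.0, 1.0)
    df = n - 2
    denom = np.maximum(1.0 - r2, np.finfo(float).tiny)
    tstat = np.sqrt(r2 * df / denom)
    p = 2.0 * stats.t.sf(tstat, df)
    p = np.where(mono, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    beta = np.where(mono, 0.0, beta)
    importance = -np.log10(p)
    importance = np.where(mono, 0.0, np.maximum(importance, 0.0))
    ids = snp_ids if snp_ids is not None else [f"snp_{j}" for j in range(m)]
    return GwasResult(list(ids), beta, p, importance, mono)
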