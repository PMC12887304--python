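"""Reliability-weighted training of the window-level free-energy network.

Labels are cumulative free energies F(leg, λ) in kcal/mol with a per-sample
uncertainty σ (kcal/mol) as produced by multistate estimators such as UWHAM.
The loss is a weighted MSE with inverse-variance weights w = 1/(σ² + ε²),
rescaled to mean one per batch, so high-precision windows dominate without
any sample being discarded outright. Optimization is AdamW with linear
warm-up, reduce-on-plateau learning-rate decay and early stopping; the best
validation checkpoint is returned. Runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from . import autodiff as ad
from .graphs import GraphPair
from .model import (BatchedGraphs, LambdaWindow, ModelConfig, ModelParams,
                    encode_graphs, init_params, predict_windows_batch)

__all__ = ["TrainingSample", "TrainConfig", "reliability_weight", "weighted_mse",
           "train", "evaluate"]


@dataclass(frozen=True)
class TrainingSample:
    pair: GraphPair
    window: LambdaWindow
    target_cumulative_dG: float  # kcal/mol
    sigma: float                 # label uncertainty, kcal/mol

    def __post_init__(self):
        if not math.isfinite(self.target_cumulative_dG):
            raise ValueError("non-finite training target")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and >= 0")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-3
    weight_decay: float = 5e-3
    warmup_steps: int = 100
    plateau_patience: int = 20
    plateau_factor: float = 0.5
    early_stop_patience: int = 80
    batch_size: int = 64
    epsilon_kcal: float = 0.1     # ε in w = 1/(σ² + ε²)
    use_reliability_weights: bool = True
    max_epochs: int = 250
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must lie in (0, 1)")
        for name in ("learning_rate", "weight_decay", "epsilon_kcal", "batch_size",
                     "max_epochs", "early_stop_patience", "plateau_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def reliability_weight(sigma, epsilon: float = 0.1):
    """Raw inverse-variance weight w = 1/(σ² + ε²).

    ε keeps perfectly converged labels (σ=0) from dominating the batch.
    Weights are subsequently rescaled to mean one per batch.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    return 1.0 / (sigma**2 + epsilon**2)


def normalize_weights(raw):
    """Rescale raw weights to mean 1 (preserves relative emphasis)."""
    raw = np.asarray(raw, dtype=np.float64)
    if np.all(raw == 0):
        raise ValueError("all-zero weights")
    return raw / raw.mean()


def weighted_mse(predictions, targets, weights) -> float:
    """Σ wᵢ(predᵢ−targetᵢ)² / Σ wᵢ  (kcal²/mol²)."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if not (len(p) == len(t) == len(w)):
        raise ValueError("predictions, targets, weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if w.sum() == 0:
        raise ValueError("all-zero weights")
    return float(np.sum(w * (p - t) ** 2) / w.sum())


def evaluate(predictions, targets) -> dict:
    """RMSE (kcal/mol) and Pearson r; Pearson requires non-constant inputs."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if len(p) < 2:
        raise ValueError("need at least two points")
    if np.std(p) == 0 or np.std(t) == 0:
        raise ValueError("Pearson r undefined for zero-variance inputs")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    r = float(stats.pearsonr(p, t).statistic)
    return {"rmse": rmse, "pearson_r": r}


class _AdamW:
    """Adam with decoupled weight decay (biases not decayed)."""

    def __init__(self, params: ModelParams, weight_decay: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and k.endswith(".w"):
                p.data -= lr * self.wd * p.data


@dataclass
class _PairBatch:
    batch: BatchedGraphs
    pair_local: np.ndarray   # sample → local pair index within this batch
    leg_ids: np.ndarray
    lams: np.ndarray
    targets: np.ndarray
    weights: np.ndarray      # mean-1 normalized within the batch


def _index_samples(samples: list[TrainingSample]):
    """Unique pairs (by identity) and per-sample pair index."""
    pair_ids: dict[int, int] = {}
    pairs: list[GraphPair] = []
    idx = np.empty(len(samples), dtype=int)
    for s_i, s in enumerate(samples):
        key = id(s.pair)
        if key not in pair_ids:
            pair_ids[key] = len(pairs)
            pairs.append(s.pair)
        idx[s_i] = pair_ids[key]
    return pairs, idx


def _make_batches(samples, pairs, pair_idx, sample_rows, config) -> list[_PairBatch]:
    """Group samples by pair so each batch forwards only its own graphs."""
    rows_by_pair: dict[int, list[int]] = {}
    for r in sample_rows:
        rows_by_pair.setdefault(int(pair_idx[r]), []).append(r)
    pair_list = sorted(rows_by_pair)
    batches = []
    group: list[int] = []
    count = 0
    for p_i in pair_list + [None]:
        if p_i is None or (count >= config.batch_size and group):
            if group:
                rows = [r for g in group for r in rows_by_pair[g]]
                local = {g: k for k, g in enumerate(group)}
                graphs = [g for g_i in group
                          for g in (pairs[g_i].graph_a, pairs[g_i].graph_b)]
                raw = (reliability_weight(np.array([samples[r].sigma for r in rows]),
                                          config.epsilon_kcal)
                       if config.use_reliability_weights
                       else np.ones(len(rows)))
                batches.append(_PairBatch(
                    batch=BatchedGraphs.from_graphs(graphs),
                    pair_local=np.array([local[int(pair_idx[r])] for r in rows]),
                    leg_ids=np.array([samples[r].window.leg_id for r in rows]),
                    lams=np.array([samples[r].window.lam for r in rows]),
                    targets=np.array([samples[r].target_cumulative_dG for r in rows]),
                    weights=normalize_weights(raw),
                ))
                group, count = [], 0
        if p_i is not None:
            group.append(p_i)
            count += len(rows_by_pair[p_i])
    return batches


def _batch_loss(pb: _PairBatch, params: ModelParams) -> ad.Tensor:
    z = encode_graphs(pb.batch, params)
    preds = predict_windows_batch(z, pb.pair_local, pb.leg_ids, pb.lams, params)
    resid = ad.sub(preds, ad.constant(pb.targets[:, None]))
    w = pb.weights / pb.weights.sum()
    return ad.sum_all(ad.mul(ad.constant(w[:, None]), ad.square(resid)))


def train(samples: list[TrainingSample], config: TrainConfig = TrainConfig(),
          model_config: ModelConfig | None = None,
          init: ModelParams | None = None):
    """Fit the network on window-level samples.

    Returns ``(best_params, log)`` where ``log`` is a list of per-epoch
    dicts (epoch, lr, train_loss, val_loss). The checkpoint with the lowest
    validation loss is returned.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(config.seed)
    model_config = model_config or ModelConfig(seed=config.seed)
    params = init.detached_copy() if init is not None else init_params(model_config)

    pairs, pair_idx = _index_samples(samples)
    order = rng.permutation(len(samples))
    n_val = max(1, int(round(config.val_fraction * len(samples))))
    if n_val >= len(samples):
        raise ValueError("validation split leaves no training samples")
    val_rows, train_rows = order[:n_val], order[n_val:]

    train_batches = _make_batches(samples, pairs, pair_idx, train_rows, config)
    val_batches = _make_batches(samples, pairs, pair_idx, val_rows, config)

    opt = _AdamW(params, config.weight_decay)
    lr_scale = 1.0
    step = 0
    best_val, best_params = np.inf, params.detached_copy()
    plateau_wait, stop_wait = 0, 0
    log = []

    for epoch in range(config.max_epochs):
        ep_loss, ep_w = 0.0, 0
        for b_i in rng.permutation(len(train_batches)):
            pb = train_batches[b_i]
            step += 1
            warm = min(1.0, step / config.warmup_steps)
            lr = config.learning_rate * warm * lr_scale
            loss = _batch_loss(pb, params)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}; "
                    "lower the learning rate or inspect the labels")
            loss.backward()
            opt.step(lr)
            ep_loss += float(loss.data) * len(pb.targets)
            ep_w += len(pb.targets)

        val_loss = sum(float(_batch_loss(pb, params).data) * len(pb.targets)
                       for pb in val_batches) / sum(len(pb.targets) for pb in val_batches)
        log.append({"epoch": epoch, "lr": lr, "train_loss": ep_loss / ep_w,
                    "val_loss": val_loss})

        if val_loss < best_val - 1e-12:
            best_val, best_params = val_loss, params.detached_copy()
            plateau_wait, stop_wait = 0, 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.plateau_patience:
                lr_scale *= config.plateau_factor
                plateau_wait = 0
            if stop_wait >= config.early_stop_patience:
                break
    return best_params, log
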