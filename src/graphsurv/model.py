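"""Edge-weighted two-layer GraphSAGE risk model trained with a Cox loss.

The network takes the whole population graph as input (transductive
setting: every node's features and every edge are visible; only the loss is
restricted to the training nodes) and emits one scalar risk score per
patient node.  Each layer updates a node from the concatenation of its own
representation and the edge-weight-normalized mean of its neighbours':

    agg_v = sum_{u in N(v)} w_uv h_u / sum_{u in N(v)} w_uv
    h'_v  = relu(W [h_v ; agg_v] + b)

Isolated nodes aggregate a zero vector.  The classification loss is
replaced by the negative Cox partial log-likelihood

    L = -(1/D) sum_{i: event} [ s_i - log sum_{j: t_j >= t_i} exp(s_j) ]

with Breslow (default) or Efron handling of tied event times.  Training is
full-batch gradient descent (Adam) with analytic gradients, dropout on the
hidden layers, and early stopping on the validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .similarity import PopulationGraph

TIES_METHODS = ("breslow", "efron")


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    d_in: int
    hidden1: int = 128
    hidden2: int = 64
    dropout: float = 0.1
    mean_augment: bool = False  # concatenate the graph-mean embedding before the head

    @property
    def d_head(self) -> int:
        return self.hidden2 * (2 if self.mean_augment else 1)


@dataclass
class SageLayerParams:
    """One GraphSAGE layer: W acts on [self ; aggregated] features."""

    W: np.ndarray  # (2*d_in, d_out)
    b: np.ndarray  # (d_out,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[1],):
            raise ModelError(f"inconsistent layer shapes W{self.W.shape} b{self.b.shape}")


@dataclass
class SurvivalModel:
    layer1: SageLayerParams
    layer2: SageLayerParams
    head_W: np.ndarray  # (d_head,)
    head_b: float
    config: ModelConfig
    feature_mean: Optional[np.ndarray] = None
    feature_scale: Optional[np.ndarray] = None

    def parameters(self) -> List[np.ndarray]:
        return [self.layer1.W, self.layer1.b, self.layer2.W, self.layer2.b, self.head_W]


def init_model(config: ModelConfig, seed: int = 0) -> SurvivalModel:
    """Glorot-uniform initialization of all weights."""
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, (fan_in, fan_out))

    l1 = SageLayerParams(glorot(2 * config.d_in, config.hidden1), np.zeros(config.hidden1))
    l2 = SageLayerParams(glorot(2 * config.hidden1, config.hidden2), np.zeros(config.hidden2))
    head = glorot(config.d_head, 1).ravel()
    return SurvivalModel(l1, l2, head, 0.0, config)


def _norm_adj(g: Union[PopulationGraph, sp.spmatrix]) -> sp.csr_matrix:
    if isinstance(g, PopulationGraph):
        return g.normalized_adjacency()
    return sp.csr_matrix(g)


def sage_layer(g: Union[PopulationGraph, sp.spmatrix], H: np.ndarray,
               params: SageLayerParams, activation: Optional[str] = "relu") -> np.ndarray:
    """One GraphSAGE update of all node representations.

    ``g`` may be a PopulationGraph or a pre-computed row-normalized
    adjacency.  ``activation=None`` returns the pre-activation (useful for
    exact hand verification).
    """
    A = _norm_adj(g)
    H = np.asarray(H, dtype=float)
    if H.shape[0] != A.shape[0] or 2 * H.shape[1] != params.W.shape[0]:
        raise ModelError(
            f"shape mismatch: H{H.shape}, adjacency {A.shape}, W{params.W.shape}"
        )
    Z = np.hstack([H, A @ H]) @ params.W + params.b
    if activation is None:
        return Z
    if activation == "relu":
        return np.maximum(Z, 0.0)
    raise ModelError(f"unknown activation {activation!r}")


def forward(g: PopulationGraph, model: SurvivalModel) -> np.ndarray:
    """Deterministic per-node risk scores (no dropout)."""
    A = g.normalized_adjacency()
    H0 = np.asarray(g.features, dtype=float)
    if model.feature_mean is not None:
        H0 = (H0 - model.feature_mean) / model.feature_scale
    H1 = sage_layer(A, H0, model.layer1)
    H2 = sage_layer(A, H1, model.layer2)
    if model.config.mean_augment:
        Hc = np.hstack([H2, np.tile(H2.mean(axis=0), (H2.shape[0], 1))])
    else:
        Hc = H2
    return Hc @ model.head_W + model.head_b


# --------------------------------------------------------------------------
# Cox partial likelihood

def _cox_prepare(risks, times, events, mask):
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (risks.shape == times.shape == events.shape):
        raise ModelError("risks/times/events must have identical shapes")
    if mask is None:
        mask = np.ones(risks.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if events[idx].sum() < 1:
        raise ModelError("Cox loss undefined: no events inside the mask")
    return risks, times, events, idx


def cox_loss_grad(risks, times, events, mask=None,
                  ties: str = "breslow") -> Tuple[float, np.ndarray]:
    """Negative mean partial log-likelihood and its gradient w.r.t. risks.

    Risk sets are formed inside the mask only; gradient entries outside the
    mask are zero.  Ties: Breslow (shared denominator) or Efron (staged
    denominators within each tied event group).
    """
    if ties not in TIES_METHODS:
        raise ModelError(f"unknown ties method {ties!r}; use one of {TIES_METHODS}")
    risks, times, events, idx = _cox_prepare(risks, times, events, mask)
    s, t, e = risks[idx], times[idx], events[idx]
    smax = s.max()
    es = np.exp(s - smax)

    order = np.argsort(t, kind="stable")
    t_s, e_s, es_s, s_s = t[order], e[order], es[order], s[order]
    uniq, starts = np.unique(t_s, return_index=True)
    bounds = np.append(starts, t_s.size)
    # reverse cumulative sum of exp(s) gives each group's full risk-set mass
    rev = np.cumsum(es_s[::-1])[::-1]

    D = int(e.sum())
    loglik = 0.0
    grad_s = np.zeros_like(s_s)
    # accumulated d_g/R_g-style mass for all groups with t_g <= current
    for gi in range(len(uniq)):
        lo, hi = bounds[gi], bounds[gi + 1]
        ev = np.flatnonzero(e_s[lo:hi]) + lo
        d = ev.size
        if d == 0:
            continue
        R = rev[lo]  # sum over t_j >= t_g of exp(s_j - smax)
        loglik += s_s[ev].sum()
        if ties == "breslow":
            loglik -= d * (np.log(R) + smax)
            # gradient mass: every j with t_j >= t_g gets exp(s_j) * d/R
            grad_s[lo:] -= es_s[lo:] * (d / R)
        else:  # efron
            E = es_s[ev].sum()
            frac = np.arange(d) / d
            denoms = R - frac * E
            loglik -= (np.log(denoms) + smax).sum()
            inv = 1.0 / denoms
            grad_s[lo:] -= es_s[lo:] * inv.sum()
            # tied events see reduced membership in the staged denominators
            grad_s[ev] += es_s[ev] * (frac * inv).sum()
    grad_s[e_s == 1] += 1.0

    loss = -loglik / D
    grad = np.zeros_like(risks)
    grad_sub = np.zeros_like(s)
    grad_sub[order] = -grad_s / D
    grad[idx] = grad_sub
    return float(loss), grad


def cox_loss(risks, times, events, mask=None, ties: str = "breslow") -> float:
    """Negative mean Cox partial log-likelihood over the masked nodes."""
    return cox_loss_grad(risks, times, events, mask, ties)[0]


# --------------------------------------------------------------------------
# Training

@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 300
    patience: int = 30
    seed: int = 0
    endpoint: str = "OS"
    ties: str = "breslow"
    hidden1: int = 128
    hidden2: int = 64
    dropout: float = 0.1
    mean_augment: bool = False
    standardize_features: bool = True
    weight_decay: float = 0.0

    def validate(self) -> "TrainConfig":
        if self.epochs < 1:
            raise ModelError("epochs must be positive")
        if self.patience > self.epochs:
            raise ModelError("patience must be <= epochs")
        if not 0.0 <= self.dropout < 1.0:
            raise ModelError("dropout must lie in [0, 1)")
        return self


@dataclass
class TrainResult:
    model: SurvivalModel
    risks: np.ndarray
    log: List[Tuple[int, float, float]]  # (epoch, train_loss, val_loss)
    best_epoch: int


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        for p, gr, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * gr
            v *= self.b2
            v += (1 - self.b2) * gr * gr
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(g: PopulationGraph, cfg: TrainConfig) -> TrainResult:
    """Transductive full-graph training minimizing the Cox loss on train nodes.

    Early stopping monitors the validation Cox loss; the parameters of the
    best validation epoch are returned together with eval-mode risks for
    every node.
    """
    cfg.validate()
    if not g.masks:
        raise ModelError("graph has no train/val/test masks; assign splits first")
    times, events = g.survival(cfg.endpoint)
    train_mask, val_mask = g.masks["train"], g.masks["val"]
    if events[train_mask].sum() < 1:
        raise ModelError("no events in the training mask")
    has_val = bool(val_mask.any()) and events[val_mask].sum() >= 1

    rng = np.random.default_rng(cfg.seed)
    n, d_in = g.features.shape
    mconf = ModelConfig(d_in, cfg.hidden1, cfg.hidden2, cfg.dropout, cfg.mean_augment)
    model = init_model(mconf, seed=int(rng.integers(2 ** 31)))

    H0 = np.asarray(g.features, dtype=float)
    if cfg.standardize_features:
        mu = H0.mean(axis=0)
        sd = H0.std(axis=0)
        sd[sd < 1e-12] = 1.0
        model.feature_mean, model.feature_scale = mu, sd
        H0 = (H0 - mu) / sd

    A = g.normalized_adjacency()
    AT = sp.csr_matrix(A.T)
    p_drop = cfg.dropout
    params = [model.layer1.W, model.layer1.b, model.layer2.W, model.layer2.b,
              model.head_W]
    head_b = np.array([model.head_b])
    params.append(head_b)
    opt = _Adam(params, cfg.lr)

    def eval_risks() -> np.ndarray:
        H1 = np.maximum(np.hstack([H0, A @ H0]) @ params[0] + params[1], 0.0)
        H2 = np.maximum(np.hstack([H1, A @ H1]) @ params[2] + params[3], 0.0)
        Hc = np.hstack([H2, np.tile(H2.mean(0), (n, 1))]) if cfg.mean_augment else H2
        return Hc @ params[4] + head_b[0]

    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = 0
    log: List[Tuple[int, float, float]] = []
    since_best = 0
    C0 = np.hstack([H0, A @ H0])  # layer-1 input never changes

    for epoch in range(1, cfg.epochs + 1):
        # ---- forward (train mode, inverted dropout)
        Z1 = C0 @ params[0] + params[1]
        R1 = np.maximum(Z1, 0.0)
        if p_drop > 0:
            m1 = (rng.random(R1.shape) >= p_drop) / (1 - p_drop)
            H1 = R1 * m1
        else:
            m1 = None
            H1 = R1
        C1 = np.hstack([H1, A @ H1])
        Z2 = C1 @ params[2] + params[3]
        R2 = np.maximum(Z2, 0.0)
        if p_drop > 0:
            m2 = (rng.random(R2.shape) >= p_drop) / (1 - p_drop)
            H2 = R2 * m2
        else:
            m2 = None
            H2 = R2
        if cfg.mean_augment:
            Hc = np.hstack([H2, np.tile(H2.mean(0), (n, 1))])
        else:
            Hc = H2
        risks = Hc @ params[4] + head_b[0]

        train_loss, drisk = cox_loss_grad(risks, times, events, train_mask, cfg.ties)

        # ---- backward
        h2 = cfg.hidden2
        dw_head = Hc.T @ drisk
        db_head = np.array([drisk.sum()])
        dHc = np.outer(drisk, params[4])
        if cfg.mean_augment:
            dH2 = dHc[:, :h2] + dHc[:, h2:].sum(axis=0, keepdims=True) / n
        else:
            dH2 = dHc
        dR2 = dH2 * m2 if m2 is not None else dH2
        dZ2 = dR2 * (Z2 > 0)
        dW2 = C1.T @ dZ2
        db2 = dZ2.sum(axis=0)
        dC1 = dZ2 @ params[2].T
        h1 = cfg.hidden1
        dH1 = dC1[:, :h1] + AT @ dC1[:, h1:]
        dR1 = dH1 * m1 if m1 is not None else dH1
        dZ1 = dR1 * (Z1 > 0)
        dW1 = C0.T @ dZ1
        db1 = dZ1.sum(axis=0)

        grads = [dW1, db1, dW2, db2, dw_head, db_head]
        if cfg.weight_decay > 0:
            for gr, p in zip(grads[:-1], params[:-1]):
                gr += cfg.weight_decay * p
        opt.step(params, grads)

        # ---- validation (eval mode)
        r_eval = eval_risks()
        val_loss = (cox_loss(r_eval, times, events, val_mask, cfg.ties)
                    if has_val else train_loss)
        log.append((epoch, float(train_loss), float(val_loss)))

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    for p, bp in zip(params, best_params):
        p[...] = bp
    model.head_b = float(head_b[0])
    return TrainResult(model, eval_risks(), log, best_epoch)


# --------------------------------------------------------------------------
# Persistence: flat array archive + JSON sidecar of shapes and config

def save_model(model: SurvivalModel, path_prefix: str) -> None:
    arrays = {
        "layer1_W": model.layer1.W, "layer1_b": model.layer1.b,
        "layer2_W": model.layer2.W, "layer2_b": model.layer2.b,
        "head_W": model.head_W, "head_b": np.array([model.head_b]),
    }
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_scale"] = model.feature_scale
    np.savez(path_prefix + ".npz", **arrays)
    sidecar = {
        "config": {
            "d_in": model.config.d_in, "hidden1": model.config.hidden1,
            "hidden2": model.config.hidden2, "dropout": model.config.dropout,
            "mean_augment": model.config.mean_augment,
        },
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path_prefix: str) -> SurvivalModel:
    with open(path_prefix + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig(**sidecar["config"])
    with np.load(path_prefix + ".npz") as z:
        model = SurvivalModel(
            SageLayerParams(z["layer1_W"], z["layer1_b"]),
            SageLayerParams(z["layer2_W"], z["layer2_b"]),
            z["head_W"], float(z["head_b"][0]), cfg,
            z["feature_mean"] if "feature_mean" in z else None,
            z["feature_scale"] if "feature_scale" in z else None,
        )
    return model
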