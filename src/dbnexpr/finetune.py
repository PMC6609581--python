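"""Supervised fine-tuning of unrolled networks.

Two optimizers are provided:

* **Bprop** — classic backpropagation with mini-batch stochastic gradient
  descent, momentum and weight-cost:

      θ(t+1) = θ(t) − η·g − λ·θ(t) + ν·Δθ(t−1)

  where Δθ(t−1) is the previous parameter change, η the learning rate,
  λ the weight-cost (applied to weights only) and ν the momentum, which
  switches from an initial to a final value at a configurable epoch.

* **Rprop (iRprop+)** — sign-based resilient backpropagation with
  per-parameter step sizes and weight backtracking, run full-batch once per
  epoch.  Constants η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δ_min = 1e−6, Δ_max = 50.

The optimized objective is the squared-error loss whose per-output
derivative is (a − t), summed over the mini-batch; reported errors use the
mean squared error E = (1/n) Σ ‖o − t‖².  Optional regularization:
end-of-epoch weight normalization (every weight-matrix column rescaled to
unit L2 norm) and a fixed-epoch early stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    NetworkModel,
    OutputEncoding,
    encode_targets,
    forward_batch,
    mse_error,
)

__all__ = [
    "TrainConfig",
    "GradientSet",
    "RpropState",
    "TrainingHistory",
    "backprop_gradients",
    "sgd_step",
    "irpropplus_step",
    "normalize_weights",
    "momentum_at_epoch",
    "train",
    "batch_objective",
]

# iRprop+ constants (standard literature values)
RPROP_ETA_PLUS = 1.2
RPROP_ETA_MINUS = 0.5
RPROP_DELTA_INIT = 0.1
RPROP_DELTA_MIN = 1e-6
RPROP_DELTA_MAX = 50.0


@dataclass
class TrainConfig:
    """Fine-tuning hyperparameters.

    ``algorithm`` is "bprop" (mini-batch SGD) or "rprop" (full-batch
    iRprop+); other resilient-backprop variants are deliberately rejected.
    The momentum schedule holds ``momentum`` through ``momentum_switch_epoch``
    and ``final_momentum`` afterwards.  ``early_stop_epoch`` caps training at
    a fixed epoch regardless of ``epochs``.
    """

    algorithm: str = "rprop"
    learning_rate: float = 0.1
    weight_cost: float = 0.0
    momentum: float = 0.5
    final_momentum: float = 0.9
    momentum_switch_epoch: int = 50
    epochs: int = 100
    batch_size: int = 10
    early_stop_epoch: int | None = None
    weight_normalization: bool = False
    patience: int | None = None  # optional monitor-based stop, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("bprop", "rprop"):
            raise ValueError(
                f"unsupported algorithm {self.algorithm!r}; only 'bprop' "
                "(SGD backpropagation) and 'rprop' (iRprop+) are provided"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_cost < 0:
            raise ValueError("weight_cost must be >= 0")
        if not (0 <= self.momentum < 1 and 0 <= self.final_momentum < 1):
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class GradientSet:
    """Per-layer error signals δ^(l) and parameter gradients."""

    deltas: list[np.ndarray]
    weight_grads: list[np.ndarray]
    bias_grads: list[np.ndarray]


def batch_objective(m: NetworkModel, X: np.ndarray, T: np.ndarray) -> float:
    """The objective the gradients differentiate: (1/2) Σ_i ‖o_i − t_i‖².

    The per-output derivative of this sum is exactly (a − t) summed over the
    batch, matching :func:`backprop_gradients`.
    """
    out = forward_batch(m, X)[-1]
    return 0.5 * float(np.sum((out - np.atleast_2d(T)) ** 2))


def backprop_gradients(m: NetworkModel, X: np.ndarray, T: np.ndarray) -> GradientSet:
    """Backpropagated gradients summed over a mini-batch.

    Output-layer error δ^(L) = (a^(L) − t) ⊙ φ′(z^(L)); hidden layers
    δ^(l) = (w^(l+1)ᵀ δ^(l+1)) ⊙ φ′(z^(l)); ∂E/∂b = δ, ∂E/∂w^(l) = δ a^(l−1)ᵀ.
    For the logistic activation φ′(z) = a (1 − a).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape != (X.shape[0], m.output_size):
        raise ValueError(
            f"targets shape {T.shape} incompatible with batch "
            f"({X.shape[0]} samples, {m.output_size} outputs)"
        )
    activations = forward_batch(m, X)
    L = len(m.weights)
    deltas: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    a_out = activations[-1]
    deltas[L - 1] = (a_out - T) * a_out * (1.0 - a_out)
    for l in range(L - 2, -1, -1):
        a = activations[l + 1]
        deltas[l] = (deltas[l + 1] @ m.weights[l + 1]) * a * (1.0 - a)
    weight_grads = [deltas[l].T @ activations[l] for l in range(L)]
    bias_grads = [deltas[l].sum(axis=0) for l in range(L)]
    return GradientSet(deltas, weight_grads, bias_grads)


@dataclass
class SGDState:
    """Previous parameter changes, for the momentum term."""

    weight_updates: list[np.ndarray]
    bias_updates: list[np.ndarray]

    @classmethod
    def zeros_like(cls, m: NetworkModel) -> "SGDState":
        return cls([np.zeros_like(w) for w in m.weights],
                   [np.zeros_like(b) for b in m.biases])


def sgd_step(
    m: NetworkModel,
    g: GradientSet,
    cfg: TrainConfig,
    prev: SGDState,
    momentum: float | None = None,
) -> tuple[NetworkModel, SGDState]:
    """One regularized gradient-descent step.

    Applies −η·g − λ·θ + ν·Δθ(t−1) to the weights (the weight-cost term is
    not applied to biases) and records the realized parameter change for the
    next momentum term.
    """
    if momentum is None:
        momentum = cfg.momentum
    new_w, new_b, upd_w, upd_b = [], [], [], []
    for w, gw, pw in zip(m.weights, g.weight_grads, prev.weight_updates):
        dw = -cfg.learning_rate * gw - cfg.weight_cost * w + momentum * pw
        new_w.append(w + dw)
        upd_w.append(dw)
    for b, gb, pb in zip(m.biases, g.bias_grads, prev.bias_updates):
        db = -cfg.learning_rate * gb + momentum * pb
        new_b.append(b + db)
        upd_b.append(db)
    return (NetworkModel(list(m.layer_sizes), new_w, new_b),
            SGDState(upd_w, upd_b))


@dataclass
class RpropState:
    """iRprop+ per-parameter state: step sizes, previous gradients/steps."""

    step_sizes: list[np.ndarray]
    prev_grads: list[np.ndarray]
    prev_steps: list[np.ndarray]
    prev_error: float = np.inf

    @classmethod
    def initial(cls, params: list[np.ndarray]) -> "RpropState":
        return cls(
            [np.full_like(p, RPROP_DELTA_INIT) for p in params],
            [np.zeros_like(p) for p in params],
            [np.zeros_like(p) for p in params],
        )


def irpropplus_step(
    params: list[np.ndarray],
    grads: list[np.ndarray],
    state: RpropState,
    current_error: float,
) -> tuple[list[np.ndarray], RpropState]:
    """One iRprop+ update over a flat list of parameter arrays.

    Per parameter: a repeated gradient sign grows the step size (×η⁺, capped
    at Δ_max) and steps −sign(g)·Δ; a sign flip shrinks it (×η⁻, floored at
    Δ_min), reverts the previous step when the error increased
    (weight backtracking), and zeroes the stored gradient so the next
    iteration takes the neutral branch; a zero product steps −sign(g)·Δ
    without changing Δ.
    """
    new_params: list[np.ndarray] = []
    new_steps: list[np.ndarray] = []
    new_sizes: list[np.ndarray] = []
    new_prev_grads: list[np.ndarray] = []
    worse = current_error > state.prev_error
    for p, g, delta, g_prev, s_prev in zip(
        params, grads, state.step_sizes, state.prev_grads, state.prev_steps
    ):
        prod = g_prev * g
        pos, neg = prod > 0, prod < 0
        size = delta.copy()
        size[pos] = np.minimum(size[pos] * RPROP_ETA_PLUS, RPROP_DELTA_MAX)
        size[neg] = np.maximum(size[neg] * RPROP_ETA_MINUS, RPROP_DELTA_MIN)
        step = -np.sign(g) * size
        step[neg] = -s_prev[neg] if worse else 0.0
        stored_g = g.copy()
        stored_g[neg] = 0.0
        new_params.append(p + step)
        # a backtracking step must not feed the next backtracking
        realized = step.copy()
        realized[neg] = 0.0
        new_steps.append(realized)
        new_sizes.append(size)
        new_prev_grads.append(stored_g)
    new_state = RpropState(new_sizes, new_prev_grads, new_steps,
                           prev_error=current_error)
    return new_params, new_state


def normalize_weights(m: NetworkModel) -> NetworkModel:
    """Rescale every weight-matrix column to unit L2 norm (zero columns kept)."""
    new_w = []
    for w in m.weights:
        norms = np.linalg.norm(w, axis=0)
        scale = np.where(norms > 0, norms, 1.0)
        new_w.append(w / scale)
    return NetworkModel(list(m.layer_sizes), new_w,
                        [b.copy() for b in m.biases])


def momentum_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Momentum schedule: initial value through the switch epoch, then final."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return cfg.momentum if epoch <= cfg.momentum_switch_epoch else cfg.final_momentum


@dataclass
class TrainingHistory:
    """Per-epoch training record (epoch, train error/accuracy, monitor)."""

    epochs: list[int] = field(default_factory=list)
    train_error: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    monitor_acc: list[float] = field(default_factory=list)

    def append(self, epoch: int, err: float, acc: float, mon: float) -> None:
        self.epochs.append(epoch)
        self.train_error.append(err)
        self.train_acc.append(acc)
        self.monitor_acc.append(mon)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_error\ttrain_acc\tmonitor_acc\n")
            for row in zip(self.epochs, self.train_error, self.train_acc,
                           self.monitor_acc):
                fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def _accuracy(m: NetworkModel, X: np.ndarray, T: np.ndarray,
              enc: OutputEncoding) -> float:
    out = forward_batch(m, X)[-1]
    if enc.mode == "single-node":
        pred = (out[:, 0] >= 0.5).astype(int)
        truth = (T[:, 0] >= 0.5).astype(int)
    else:
        pred = np.argmax(out, axis=1)
        truth = np.argmax(T, axis=1)
    return float(np.mean(pred == truth))


def train(
    m: NetworkModel,
    X: np.ndarray,
    T: np.ndarray,
    cfg: TrainConfig,
    enc: OutputEncoding = OutputEncoding(),
    monitor: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[NetworkModel, TrainingHistory]:
    """Fine-tune a network on encoded targets.

    Bprop shuffles the data into mini-batches and applies one SGD step per
    batch; Rprop computes a full-batch gradient and applies one iRprop+
    step per epoch.  When ``cfg.weight_normalization`` is set, columns are
    renormalized after each epoch's updates.  Training stops at
    ``early_stop_epoch`` when configured, or earlier under the optional
    patience monitor.  Deterministic given ``cfg.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    model = m.copy()
    history = TrainingHistory()
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    max_epochs = cfg.epochs
    if cfg.early_stop_epoch is not None:
        max_epochs = min(max_epochs, max(cfg.early_stop_epoch, 0))

    sgd_state = SGDState.zeros_like(model)
    rprop_state: RpropState | None = None
    best_monitor, since_best = -np.inf, 0

    for epoch in range(1, max_epochs + 1):
        if cfg.algorithm == "bprop":
            nu = momentum_at_epoch(cfg, epoch)
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                g = backprop_gradients(model, X[idx], T[idx])
                model, sgd_state = sgd_step(model, g, cfg, sgd_state, momentum=nu)
        else:  # rprop: full batch, one step per epoch
            # weight-cost enters through the penalized objective
            # E + (λ/2)‖w‖² — sign-based steps ignore magnitudes, so a bare
            # multiplicative shrink would not act as an L2 penalty here
            current_error = batch_objective(model, X, T)
            if cfg.weight_cost > 0:
                current_error += 0.5 * cfg.weight_cost * sum(
                    float(np.sum(w**2)) for w in model.weights
                )
            g = backprop_gradients(model, X, T)
            w_grads = (
                [gw + cfg.weight_cost * w
                 for gw, w in zip(g.weight_grads, model.weights)]
                if cfg.weight_cost > 0 else g.weight_grads
            )
            params = list(model.weights) + list(model.biases)
            grads = list(w_grads) + list(g.bias_grads)
            if rprop_state is None:
                rprop_state = RpropState.initial(params)
            new_params, rprop_state = irpropplus_step(
                params, grads, rprop_state, current_error
            )
            k = len(model.weights)
            model = NetworkModel(list(model.layer_sizes), new_params[:k],
                                 new_params[k:])

        if cfg.weight_normalization:
            model = normalize_weights(model)

        out = forward_batch(model, X)[-1]
        err = mse_error(out, T)
        acc = _accuracy(model, X, T, enc)
        mon = (_accuracy(model, monitor[0], monitor[1], enc)
               if monitor is not None else np.nan)
        history.append(epoch, err, acc, mon)

        if cfg.patience is not None and monitor is not None:
            if mon > best_monitor:
                best_monitor, since_best = mon, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    return model, history
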