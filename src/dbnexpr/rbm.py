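"""Binary-unit restricted Boltzmann machines and greedy layer-wise stacking.

An RBM is a two-layer undirected energy model with visible units v and hidden
units h, energy E(v, h) = −aᵀv − bᵀh − vᵀWh, and no intra-layer edges, so the
conditionals factorize:

    P(h_j = 1 | v) = σ(b_j + Σ_i v_i W_ij)
    P(v_i = 1 | h) = σ(a_i + Σ_j W_ij h_j)

Training uses contrastive divergence (CD-k): the positive statistics come
from the data and its hidden conditional, the negative statistics from k
alternating Gibbs steps started at the data.  Stacking trains RBM r > 1 on
the hidden-unit probabilities of RBM r − 1, the standard greedy pretraining
of a deep belief network.

Expression values are continuous, so inputs are min-max scaled per gene to
[0, 1] (see :class:`MinMaxScaler`) and treated as Bernoulli probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionDataset

__all__ = [
    "RBMModel",
    "CDConfig",
    "MinMaxScaler",
    "sigmoid",
    "hidden_probs",
    "visible_probs",
    "sample_binary",
    "cd_update",
    "train_rbm",
    "pretrain_stack",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class RBMModel:
    """Weights and biases of one binary-unit RBM.

    ``weights`` has shape (n_visible, n_hidden); ``visible_bias`` and
    ``hidden_bias`` match the respective layer sizes.
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        nv, nh = self.weights.shape
        if self.visible_bias.shape != (nv,) or self.hidden_bias.shape != (nh,):
            raise ValueError("bias shapes inconsistent with weight matrix")
        for arr in (self.weights, self.visible_bias, self.hidden_bias):
            if not np.all(np.isfinite(arr)):
                raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "RBMModel":
        return RBMModel(self.weights.copy(), self.visible_bias.copy(),
                        self.hidden_bias.copy())


@dataclass
class CDConfig:
    """Hyperparameters for contrastive-divergence training.

    Defaults follow common RBM practice: CD-1, learning rate 0.1,
    mini-batches of 10, momentum 0.5 switching to 0.9 after 5 epochs, and a
    small weight-cost.
    """

    k: int = 1
    learning_rate: float = 0.1
    epochs: int = 10
    batch_size: int = 10
    momentum: float = 0.5
    final_momentum: float = 0.9
    momentum_switch_epoch: int = 5
    weight_cost: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.momentum < 1 and 0 <= self.final_momentum < 1):
            raise ValueError("momentum must lie in [0, 1)")
        if self.weight_cost < 0:
            raise ValueError("weight_cost must be >= 0")


@dataclass
class MinMaxScaler:
    """Per-gene min-max scaling to [0, 1], fit on training data only.

    Constant genes map to 0 (zero range is treated as range 1 to avoid
    division by zero).  The fitted parameters travel with a pretrained stack
    so test data are scaled identically.
    """

    minimum: np.ndarray = field(default=None)  # type: ignore[assignment]
    value_range: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.minimum = X.min(axis=0)
        rng = X.max(axis=0) - self.minimum
        rng[rng == 0] = 1.0
        self.value_range = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.minimum is None:
            raise RuntimeError("scaler not fitted")
        scaled = (np.asarray(X, dtype=float) - self.minimum) / self.value_range
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# conditionals and sampling


def hidden_probs(m: RBMModel, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) for a vector or a batch of visible configurations."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != m.n_visible:
        raise ValueError(
            f"visible vector length {v.shape[-1]} != n_visible {m.n_visible}"
        )
    return sigmoid(v @ m.weights + m.hidden_bias)


def visible_probs(m: RBMModel, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h); symmetric to :func:`hidden_probs` with Wᵀ."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != m.n_hidden:
        raise ValueError(
            f"hidden vector length {h.shape[-1]} != n_hidden {m.n_hidden}"
        )
    return sigmoid(h @ m.weights.T + m.visible_bias)


def sample_binary(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws from a probability array."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(float)


# ---------------------------------------------------------------------------
# contrastive divergence


@dataclass
class CDState:
    """Momentum buffers carried across CD updates."""

    dw: np.ndarray
    dvb: np.ndarray
    dhb: np.ndarray

    @classmethod
    def zeros_like(cls, m: RBMModel) -> "CDState":
        return cls(np.zeros_like(m.weights), np.zeros_like(m.visible_bias),
                   np.zeros_like(m.hidden_bias))


def cd_update(
    m: RBMModel,
    batch: np.ndarray,
    cfg: CDConfig,
    state: CDState,
    rng: np.random.Generator,
    momentum: float | None = None,
) -> tuple[RBMModel, CDState]:
    """One CD-k parameter update from a mini-batch of visible vectors.

    Positive statistics use the data and its hidden probabilities; the Gibbs
    chain samples hidden states binary at every step but keeps visible
    reconstructions (and the final hidden layer) as probabilities, the
    usual variance-reduction choice.  The update applies learning rate,
    momentum and weight-cost (weights only) as in the regularized
    gradient-ascent rule.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[1] != m.n_visible:
        raise ValueError("batch column count != n_visible")
    if np.any(batch < 0) or np.any(batch > 1):
        raise ValueError("batch values must lie in [0, 1]")
    if momentum is None:
        momentum = cfg.momentum
    n = batch.shape[0]

    h0 = hidden_probs(m, batch)
    pos_w = batch.T @ h0
    pos_vb = batch.sum(axis=0)
    pos_hb = h0.sum(axis=0)

    h_state = sample_binary(h0, rng)
    for step in range(cfg.k):
        v_prob = visible_probs(m, h_state)
        h_prob = hidden_probs(m, v_prob)
        if step < cfg.k - 1:
            h_state = sample_binary(h_prob, rng)
    neg_w = v_prob.T @ h_prob
    neg_vb = v_prob.sum(axis=0)
    neg_hb = h_prob.sum(axis=0)

    lr = cfg.learning_rate / n
    new_state = CDState(
        dw=momentum * state.dw + lr * (pos_w - neg_w)
        - cfg.learning_rate * cfg.weight_cost * m.weights,
        dvb=momentum * state.dvb + lr * (pos_vb - neg_vb),
        dhb=momentum * state.dhb + lr * (pos_hb - neg_hb),
    )
    new_model = RBMModel(
        weights=m.weights + new_state.dw,
        visible_bias=m.visible_bias + new_state.dvb,
        hidden_bias=m.hidden_bias + new_state.dhb,
    )
    return new_model, new_state


def init_rbm(n_visible: int, n_hidden: int, seed: int) -> RBMModel:
    """Small-random initialization: weights ~ N(0, 0.01), zero biases."""
    rng = np.random.default_rng(seed)
    return RBMModel(
        weights=rng.normal(0.0, 0.01, size=(n_visible, n_hidden)),
        visible_bias=np.zeros(n_visible),
        hidden_bias=np.zeros(n_hidden),
    )


def train_rbm(data: np.ndarray, n_hidden: int, cfg: CDConfig) -> RBMModel:
    """Mini-batch CD training over shuffled data for ``cfg.epochs`` epochs."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if np.any(data < 0) or np.any(data > 1):
        raise ValueError("training data must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    model = init_rbm(data.shape[1], n_hidden, seed=cfg.seed)
    state = CDState.zeros_like(model)
    n = data.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        momentum = (cfg.momentum if epoch <= cfg.momentum_switch_epoch
                    else cfg.final_momentum)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            model, state = cd_update(model, batch, cfg, state, rng,
                                     momentum=momentum)
    return model


def pretrain_stack(
    ds: ExpressionDataset | np.ndarray,
    hidden_sizes: list[int],
    cfg: CDConfig,
) -> list[RBMModel]:
    """Greedy bottom-up pretraining of a chain of RBMs.

    The first RBM is trained on the (already [0, 1]-scaled) inputs; each
    subsequent RBM is trained on the hidden-probability outputs of its
    predecessor.  Returns one RBM per hidden layer (empty list for no
    hidden layers).
    """
    X = ds.expression if isinstance(ds, ExpressionDataset) else np.asarray(ds, float)
    stack: list[RBMModel] = []
    layer_input = X
    for depth, nh in enumerate(hidden_sizes):
        layer_cfg = CDConfig(**{**cfg.__dict__, "seed": cfg.seed + depth})
        rbm = train_rbm(layer_input, nh, layer_cfg)
        stack.append(rbm)
        layer_input = hidden_probs(rbm, layer_input)
    return stack


def stack_transform(stack: list[RBMModel], X: np.ndarray, upto: int | None = None) -> np.ndarray:
    """Chain hidden_probs through the first ``upto`` RBMs (all by default)."""
    out = np.asarray(X, dtype=float)
    for rbm in stack[: (len(stack) if upto is None else upto)]:
        out = hidden_probs(rbm, out)
    return out


# exact likelihood on tiny machines, used as an independent training oracle
def exact_log_likelihood(m: RBMModel, patterns: np.ndarray) -> float:
    """Mean exact log-likelihood by full state enumeration.

    Tractable only for tiny machines (2^(n_visible + n_hidden) states); used
    to verify that CD training raises the model probability of its training
    patterns.
    """
    nv, nh = m.n_visible, m.n_hidden
    if nv + nh > 20:
        raise ValueError("state enumeration infeasible beyond ~20 units")
    vis = np.array(np.meshgrid(*([[0, 1]] * nv), indexing="ij")).reshape(nv, -1).T
    hid = np.array(np.meshgrid(*([[0, 1]] * nh), indexing="ij")).reshape(nh, -1).T
    # energy E(v,h) = -a'v - b'h - v'Wh ; log Z by logsumexp over all states
    neg_energy = (vis @ m.visible_bias)[:, None] + (hid @ m.hidden_bias)[None, :] \
        + vis @ m.weights @ hid.T
    from scipy.special import logsumexp

    log_z = logsumexp(neg_energy)
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    lls = []
    for p in patterns:
        ne_p = p @ m.visible_bias + hid @ m.hidden_bias + p @ m.weights @ hid.T
        lls.append(logsumexp(ne_p) - log_z)
    return float(np.mean(lls))
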