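"""Restricted Boltzmann machines: energies, conditionals, CD-k training.

Two flavours are supported.  The Gaussian-Bernoulli ("GB") RBM has
real-valued visible units with unit Gaussian noise (the data are standardized
so sigma_i = 1) and binary hidden units; its energy is

    E(V, H) = sum_i (v_i - b_i)^2 / 2 - sum_j c_j h_j - sum_ij v_i h_j w_ji.

The Bernoulli-Bernoulli ("BB") RBM is fully binary with

    E(v, h) = - sum_i b_i v_i - sum_j c_j h_j - sum_ij h_j w_ji v_i.

In both flavours the hidden conditional is sigmoid(c + W v).  The visible
conditional is sigmoid(b + W^T h) for BB; for GB, sampling binary visible
states during Gibsbs chains (a denoising choice for noisy expression data)
gives sigmoid(-0.5 + b + W^T h), the -0.5 offset coming from the quadratic
visible term evaluated at v in {0, 1}.

Training maximizes the data log-likelihood by gradient ascent with the
contrastive-divergence CD-k estimator: k alternating Gibbs steps from each
data vector, positive phase at the data, negative phase at the chain end.
Exact enumeration oracles (partition function, likelihood, exact gradient)
are provided for tiny models so the stochastic estimators can be verified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "GB",
    "BB",
    "RBMParameters",
    "TrainingConfig",
    "TrainingTrace",
    "ExactRBMSummary",
    "gb_energy",
    "bb_energy",
    "p_hidden_given_visible",
    "p_visible_given_hidden",
    "sample_binary",
    "cd_k_gradients",
    "train_rbm",
    "mean_data_energy",
    "exact_partition_function",
    "exact_loglik_gradient",
    "exact_mean_loglik",
]

GB = "GB"
BB = "BB"

#: visible-unit offset entering the GB binary-visible conditional: with
#: v in {0,1} the quadratic term (v-b)^2/2 contributes 1/2 - b*v + const,
#: shifting the logit by -0.5.
_GB_VISIBLE_OFFSET = -0.5

# enumeration oracles refuse above this many total units
_ENUM_LIMIT = 20


@dataclass
class RBMParameters:
    """Weights and biases of a single RBM layer.

    W has shape (n_hidden, n_visible); B are visible biases (length
    n_visible); C are hidden biases (length n_hidden).
    """

    W: np.ndarray
    B: np.ndarray
    C: np.ndarray
    flavour: str = GB

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.flavour not in (GB, BB):
            raise ValueError(f"flavour must be {GB!r} or {BB!r}")
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (n_hidden x n_visible)")
        if self.W.shape != (self.C.size, self.B.size):
            raise ValueError(
                f"W shape {self.W.shape} inconsistent with biases "
                f"({self.C.size} hidden, {self.B.size} visible)"
            )
        if not (np.isfinite(self.W).all() and np.isfinite(self.B).all()
                and np.isfinite(self.C).all()):
            raise ValueError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.B.size

    @property
    def n_hidden(self) -> int:
        return self.C.size

    def copy(self) -> "RBMParameters":
        return RBMParameters(self.W.copy(), self.B.copy(), self.C.copy(),
                             self.flavour)


@dataclass
class TrainingConfig:
    """Hyper-parameters for CD-k mini-batch training.

    eta is the learning rate (0.5 by default), k the number of Gibbs steps
    per CD update, batch_size the mini-batch size, init_weight_sd the
    standard deviation of the Normal(0, sd) weight initialization.  The
    gradient is summed (not averaged) over the batch; ``mean_gradient=True``
    switches to the batch mean.
    """

    eta: float = 0.5
    k: int = 1
    batch_size: int = 4
    epochs: int = 50
    init_weight_sd: float = 0.01
    seed: int = 0
    mean_gradient: bool = False

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.init_weight_sd < 0:
            raise ValueError("init_weight_sd must be >= 0")


@dataclass
class TrainingTrace:
    """Per-epoch diagnostics: mean data energy and gradient norm."""

    energies: list = field(default_factory=list)
    grad_norms: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.energies)


@dataclass
class ExactRBMSummary:
    """Enumeration summary of a tiny RBM: partition function and the full
    table of state probabilities (shape 2^n_visible x 2^n_hidden, rows/cols
    indexed by the binary encoding of the state)."""

    Z: float
    probabilities: np.ndarray
    visible_states: np.ndarray
    hidden_states: np.ndarray


def _check_lengths(p: RBMParameters, V, H) -> tuple:
    V = np.asarray(V, dtype=float)
    H = np.asarray(H, dtype=float)
    if V.shape[-1] != p.n_visible or H.shape[-1] != p.n_hidden:
        raise ValueError(
            f"state lengths ({V.shape[-1]} visible, {H.shape[-1]} hidden) do "
            f"not match model ({p.n_visible} visible, {p.n_hidden} hidden)"
        )
    return V, H


def gb_energy(V, H, p: RBMParameters) -> float:
    """Gaussian-Bernoulli energy of a (real V, binary H) configuration."""
    if p.flavour != GB:
        raise ValueError("gb_energy requires a GB-flavour model")
    V, H = _check_lengths(p, V, H)
    return float(
        0.5 * np.sum((V - p.B) ** 2) - p.C @ H - H @ p.W @ V
    )


def bb_energy(V, H, p: RBMParameters) -> float:
    """Bernoulli-Bernoulli energy of a binary (V, H) configuration."""
    if p.flavour != BB:
        raise ValueError("bb_energy requires a BB-flavour model")
    V, H = _check_lengths(p, V, H)
    if not (np.isin(V, (0.0, 1.0)).all() and np.isin(H, (0.0, 1.0)).all()):
        raise ValueError("BB energy requires binary states")
    return float(-p.B @ V - p.C @ H - H @ p.W @ V)


def energy(V, H, p: RBMParameters) -> float:
    """Flavour-dispatching energy."""
    return gb_energy(V, H, p) if p.flavour == GB else bb_energy(V, H, p)


def p_hidden_given_visible(p: RBMParameters, V) -> np.ndarray:
    """P(h_k = 1 | V) = sigmoid(c_k + sum_i w_ki v_i); accepts a single
    visible vector or a (n_samples, n_visible) matrix."""
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != p.n_visible:
        raise ValueError(
            f"visible length {V.shape[-1]} != model n_visible {p.n_visible}"
        )
    return expit(p.C + V @ p.W.T)


def p_visible_given_hidden(p: RBMParameters, H) -> np.ndarray:
    """P(v_k = 1 | H): sigmoid(b + W^T h) for BB, with the extra -0.5 logit
    offset for GB binary-visible sampling.  Accepts a vector or matrix."""
    H = np.asarray(H, dtype=float)
    if H.shape[-1] != p.n_hidden:
        raise ValueError(
            f"hidden length {H.shape[-1]} != model n_hidden {p.n_hidden}"
        )
    logit = p.B + H @ p.W
    if p.flavour == GB:
        logit = logit + _GB_VISIBLE_OFFSET
    return expit(logit)


def sample_binary(probs, rng: np.random.Generator) -> np.ndarray:
    """Draw independent Bernoulli variates, one per probability entry."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(probs.shape) < probs).astype(float)


def cd_k_gradients(p: RBMParameters, batch, cfg: TrainingConfig,
                   rng: np.random.Generator):
    """CD-k log-likelihood gradient estimate summed over a batch.

    For each sample V the chain starts at V^(0) = V; each step samples a
    binary hidden state from P(h|v) then a binary visible state from P(v|h)
    (binary draws even in the GB flavour — the denoising convention).  The
    returned triple is

        dW[j, i] = sum_t [ P(h_j=1|V^(0)) v_i^(0) - P(h_j=1|V^(k)) v_i^(k) ]
        dB[i]    = sum_t [ v_i^(0) - v_i^(k) ]
        dC[j]    = sum_t [ P(h_j=1|V^(0)) - P(h_j=1|V^(k)) ]

    where V^(0) keeps its real values in the GB positive phase.
    """
    if cfg.k < 1:
        raise ValueError("k must be >= 1")
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    h0 = p_hidden_given_visible(p, batch)
    v = batch
    for _ in range(cfg.k):
        h_sample = sample_binary(p_hidden_given_visible(p, v), rng)
        v = sample_binary(p_visible_given_hidden(p, h_sample), rng)
    hk = p_hidden_given_visible(p, v)
    dW = h0.T @ batch - hk.T @ v
    dB = (batch - v).sum(axis=0)
    dC = (h0 - hk).sum(axis=0)
    if cfg.mean_gradient:
        n = batch.shape[0]
        dW, dB, dC = dW / n, dB / n, dC / n
    return dW, dB, dC


def init_parameters(n_visible: int, n_hidden: int, flavour: str,
                    cfg: TrainingConfig,
                    rng: np.random.Generator | None = None) -> RBMParameters:
    """Normal(0, init_weight_sd) weights, zero biases."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    W = rng.normal(0.0, cfg.init_weight_sd, size=(n_hidden, n_visible))
    return RBMParameters(W, np.zeros(n_visible), np.zeros(n_hidden), flavour)


def train_rbm(data, cfg: TrainingConfig, flavour: str, n_hidden: int,
              params: RBMParameters | None = None):
    """Mini-batch CD-k gradient-ascent training.

    ``data`` is samples x units (standardized real values for GB, binary for
    BB).  Each epoch shuffles the sample order, partitions it into batches of
    ``cfg.batch_size`` (the final batch may be smaller) and applies
    theta := theta + eta * gradient per batch.  The trace records the mean
    data energy and the root-mean-square gradient norm per epoch.  Fully
    deterministic given ``cfg.seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_samples, n_visible = data.shape
    if cfg.batch_size > n_samples:
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds sample count {n_samples}"
        )
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_parameters(n_visible, n_hidden, flavour, cfg, rng)
    else:
        params = params.copy()
    trace = TrainingTrace()
    for _ in range(cfg.epochs):
        order = rng.permutation(n_samples)
        sq_norm = 0.0
        for start in range(0, n_samples, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            dW, dB, dC = cd_k_gradients(params, batch, cfg, rng)
            params.W += cfg.eta * dW
            params.B += cfg.eta * dB
            params.C += cfg.eta * dC
            sq_norm += float((dW ** 2).sum() + (dB ** 2).sum()
                             + (dC ** 2).sum())
        trace.energies.append(mean_data_energy(params, data))
        trace.grad_norms.append(np.sqrt(sq_norm))
    return params, trace


def mean_data_energy(p: RBMParameters, data, mode: str = "threshold",
                     rng: np.random.Generator | None = None) -> float:
    """Mean energy of the data with hidden states set per sample.

    Hidden states default to the deterministic thresholded activation
    (probability >= 0.5 -> 1) for reproducible traces; ``mode="sample"``
    draws them instead.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    probs = p_hidden_given_visible(p, data)
    if mode == "threshold":
        H = (probs >= 0.5).astype(float)
    elif mode == "sample":
        if rng is None:
            raise ValueError("sample mode requires an rng")
        H = sample_binary(probs, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if p.flavour == GB:
        E = (0.5 * ((data - p.B) ** 2).sum(axis=1) - H @ p.C
             - np.einsum("sj,ji,si->s", H, p.W, data))
    else:
        E = (-data @ p.B - H @ p.C
             - np.einsum("sj,ji,si->s", H, p.W, data))
    return float(E.mean())


# ---------------------------------------------------------------------------
# enumeration oracles (tiny models only)
# ---------------------------------------------------------------------------

def _binary_states(n: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


def _check_enumerable(p: RBMParameters) -> None:
    if p.n_visible + p.n_hidden > _ENUM_LIMIT:
        raise ValueError(
            f"enumeration limited to n_visible + n_hidden <= {_ENUM_LIMIT}; "
            f"model has {p.n_visible + p.n_hidden} units"
        )


def _energy_table(p: RBMParameters) -> tuple:
    """All-state energy table for a binary-visible model (BB energy, or GB
    energy with visible states restricted to {0, 1})."""
    _check_enumerable(p)
    Vs = _binary_states(p.n_visible)
    Hs = _binary_states(p.n_hidden)
    cross = Hs @ p.W @ Vs.T  # (n_h_states, n_v_states)
    if p.flavour == BB:
        E = -(Vs @ p.B)[None, :] - (Hs @ p.C)[:, None] - cross
    else:
        E = (0.5 * ((Vs - p.B) ** 2).sum(axis=1)[None, :]
             - (Hs @ p.C)[:, None] - cross)
    return Vs, Hs, E.T  # (n_v_states, n_h_states)


def exact_partition_function(p: RBMParameters) -> ExactRBMSummary:
    """Brute-force partition function and state probabilities by enumerating
    every binary (V, H) configuration."""
    Vs, Hs, E = _energy_table(p)
    logZ = logsumexp(-E)
    probs = np.exp(-E - logZ)
    return ExactRBMSummary(float(np.exp(logZ)), probs, Vs, Hs)


def exact_mean_loglik(p: RBMParameters, data) -> float:
    """Exact mean log-likelihood of binary data vectors, by enumeration."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    _check_enumerable(p)
    Hs = _binary_states(p.n_hidden)
    cross = data @ p.W.T  # (n_samples, n_hidden)
    if p.flavour == BB:
        base = data @ p.B
    else:
        base = -0.5 * ((data - p.B) ** 2).sum(axis=1)
    # log sum_h exp(-E(v, h)) = base + log sum_h exp(c.h + h W v)
    free = base + logsumexp(Hs @ p.C + cross @ Hs.T, axis=1)
    Vs, _, E = _energy_table(p)
    logZ = logsumexp(-E)
    return float(free.mean() - logZ)


def exact_loglik_gradient(p: RBMParameters, data):
    """Exact log-likelihood gradient (summed over data vectors): the
    data-conditional expectation of -dE/dtheta minus the model expectation,
    both computed by enumeration."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    summary = exact_partition_function(p)
    Vs, Hs, probs = summary.visible_states, summary.hidden_states, \
        summary.probabilities
    # model expectations
    pv = probs.sum(axis=1)  # marginal over visible states
    h_probs = p_hidden_given_visible(p, Vs)  # E[h | v] per visible state
    model_W = (h_probs * pv[:, None]).T @ Vs
    model_B = pv @ Vs
    model_C = pv @ h_probs
    # data expectations
    h_data = p_hidden_given_visible(p, data)
    data_W = h_data.T @ data
    data_B = data.sum(axis=0)
    data_C = h_data.sum(axis=0)
    n = data.shape[0]
    return (data_W - n * model_W, data_B - n * model_B,
            data_C - n * model_C)
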