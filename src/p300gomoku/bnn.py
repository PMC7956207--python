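"""Bayesian convolutional neural network for single-epoch P300 detection.

Every convolutional and dense weight carries a diagonal-Gaussian variational
posterior q(w) = N(mu, sigma^2); a forward pass draws w = mu + eps * sigma
(the reparameterization trick), so gradients flow to both mu and the
unconstrained scale rho with sigma = softplus(rho).  Training minimizes the
negative evidence lower bound

    loss = CE(labels, forward with sampled weights) + (1/n_batches) * KL(q || p)

with an isotropic N(0, prior_sd^2) prior p.  Prediction averages the P300
probability over several Monte-Carlo weight draws; forcing sigma = 0
collapses the network to a plain point-estimate CNN with identical topology,
which doubles as the deterministic baseline.

Topology for a 150 x 30 time-by-channel epoch (batch B):

    L0  batch-norm of the input (single scalar statistic pair)
    L1  10 spatial filters (1 x 30) + BN + ReLU        -> (B, 150, 10)
    L2  max-pool (2 x 1), stride 2                     -> (B, 75, 10)
    L3  10 temporal filters (length 20, full depth,
        stride 6) + BN + ReLU                          -> (B, 10, 10)
        flatten                                        -> (B, 100)
    L4  dense 100 -> 100, softmax over the 100 units
    L5  dense 100 -> 2; final softmax gives class probabilities

The temporal stride of 6 is the unique value for which 75 pooled samples and
a length-20 kernel give (75 - 20)/6 + 1 = 10 positions, i.e. a flattened
feature vector of exactly 10 x 10 = 100 entering L4.

All arithmetic is plain NumPy; backward passes are written out by hand and
validated against finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .preprocess import N_ELEC, N_T

N_SPATIAL = 10      # spatial filters in L1
POOL = 2            # L2 pool size / stride
N_POOLED = N_T // POOL          # 75
TEMP_KERNEL = 20    # L3 temporal kernel length
TEMP_STRIDE = 6
N_TEMPORAL = 10     # temporal filters in L3
N_POSITIONS = (N_POOLED - TEMP_KERNEL) // TEMP_STRIDE + 1  # 10
N_FLAT = N_POSITIONS * N_TEMPORAL  # 100
N_HIDDEN = 100
N_CLASSES = 2

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclasses.dataclass
class GaussianParam:
    """Variational posterior of one weight tensor: N(mu, softplus(rho)^2)."""

    mu: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.mu.shape != self.rho.shape:
            raise ValueError(
                f"mu shape {self.mu.shape} != rho shape {self.rho.shape}"
            )

    @property
    def sigma(self) -> np.ndarray:
        return softplus(self.rho)

    @property
    def size(self) -> int:
        return self.mu.size


def sample_weight(param: GaussianParam, eps: np.ndarray) -> np.ndarray:
    """Reparameterized draw w = mu + eps * sigma; differentiable in (mu, rho)."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape != param.mu.shape:
        raise ValueError(f"eps shape {eps.shape} != param shape {param.mu.shape}")
    return param.mu + eps * param.sigma


def kl_to_prior(param: GaussianParam, prior_sd: float) -> float:
    """Closed-form KL( N(mu, sigma^2) || N(0, prior_sd^2) ), summed over
    elements.

    Per element: log(prior_sd/sigma) + (sigma^2 + mu^2) / (2 prior_sd^2) - 1/2.
    """
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be positive, got {prior_sd}")
    sigma = param.sigma
    p2 = prior_sd ** 2
    kl = np.log(prior_sd / sigma) + (sigma ** 2 + param.mu ** 2) / (2 * p2) - 0.5
    return float(kl.sum())


@dataclasses.dataclass
class _BatchNorm:
    """Batch normalization over given axes; running stats for evaluation."""

    n_features: int
    gamma: np.ndarray = None
    beta: np.ndarray = None
    running_mean: np.ndarray = None
    running_var: np.ndarray = None

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = np.ones(self.n_features)
        if self.beta is None:
            self.beta = np.zeros(self.n_features)
        if self.running_mean is None:
            self.running_mean = np.zeros(self.n_features)
        if self.running_var is None:
            self.running_var = np.ones(self.n_features)

    def forward(self, x: np.ndarray, axes: tuple[int, ...], training: bool):
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            )
            self.running_var = (
                (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        shape = [1] * x.ndim
        for ax in range(x.ndim):
            if ax not in axes:
                shape[ax] = x.shape[ax]
        mean_b = np.reshape(mean, shape)
        std_b = np.sqrt(np.reshape(var, shape) + _BN_EPS)
        xhat = (x - mean_b) / std_b
        y = np.reshape(self.gamma, shape) * xhat + np.reshape(self.beta, shape)
        cache = (xhat, std_b, shape, axes)
        return y, cache

    def backward(self, dy: np.ndarray, cache):
        """Gradient through training-mode BN (batch statistics)."""
        xhat, std_b, shape, axes = cache
        n = int(np.prod([dy.shape[ax] for ax in axes]))
        gamma_b = np.reshape(self.gamma, shape)
        dgamma = np.reshape((dy * xhat).sum(axis=axes), self.gamma.shape)
        dbeta = np.reshape(dy.sum(axis=axes), self.beta.shape)
        dxhat = dy * gamma_b
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std_b
        return dx, dgamma, dbeta


_PARAM_SHAPES = {
    "w_spat": (N_SPATIAL, N_ELEC),
    "b_spat": (N_SPATIAL,),
    "w_temp": (N_TEMPORAL, TEMP_KERNEL, N_SPATIAL),
    "b_temp": (N_TEMPORAL,),
    "w_fc1": (N_HIDDEN, N_FLAT),
    "b_fc1": (N_HIDDEN,),
    "w_out": (N_CLASSES, N_HIDDEN),
    "b_out": (N_CLASSES,),
}

# (75 - 20)/6 + 1 window start indices for the temporal convolution
_WIN_IDX = (np.arange(N_POSITIONS) * TEMP_STRIDE)[:, None] + np.arange(TEMP_KERNEL)


@dataclasses.dataclass
class TrainConfig:
    """Training hyper-parameters for Bayes-by-Backprop SGD."""

    batch_size: int = 85
    learning_rate: float = 0.01
    n_epochs: int = 50
    prior_sd: float = 0.5
    mc_train: int = 1
    mc_test: int = 20
    seed: int = 0
    optimizer: str = "sgd"  # "sgd" | "adam"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("batch_size >= 1 and learning_rate >= 0 required")
        if self.prior_sd <= 0 or self.mc_train < 1 or self.mc_test < 1:
            raise ValueError("prior_sd > 0 and mc_* >= 1 required")


class BayesianCNN:
    """The six-layer variational CNN (see module docstring).

    ``stochastic=False`` freezes every sigma at zero, giving the plain
    deterministic CNN baseline with the same topology.
    """

    def __init__(
        self,
        prior_sd: float = 0.5,
        init_sigma: float = 0.05,
        hidden_activation: str = "softmax",
        stochastic: bool = True,
        seed: int = 0,
    ):
        if hidden_activation not in ("softmax", "relu"):
            raise ValueError(f"unknown hidden_activation {hidden_activation!r}")
        self.prior_sd = prior_sd
        self.hidden_activation = hidden_activation
        self.stochastic = stochastic
        rng = np.random.default_rng(seed)
        rho0 = softplus_inv(init_sigma)
        self.params: dict[str, GaussianParam] = {}
        for name, shape in _PARAM_SHAPES.items():
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
            scale = 1.0 / np.sqrt(fan_in)
            mu = rng.normal(0.0, scale, shape) if len(shape) > 1 else np.zeros(shape)
            self.params[name] = GaussianParam(mu=mu, rho=np.full(shape, rho0))
        self.bn0 = _BatchNorm(1)
        self.bn1 = _BatchNorm(N_SPATIAL)
        self.bn3 = _BatchNorm(N_TEMPORAL)

    # ------------------------------------------------------------------ #

    def kl(self) -> float:
        """Total KL divergence of the posterior to the prior."""
        if not self.stochastic:
            return 0.0
        return sum(kl_to_prior(p, self.prior_sd) for p in self.params.values())

    def draw_eps(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        if not self.stochastic:
            return {n: np.zeros(p.mu.shape) for n, p in self.params.items()}
        return {
            n: rng.standard_normal(p.mu.shape) for n, p in self.params.items()
        }

    def _weights(self, eps: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        if not self.stochastic:
            return {n: p.mu for n, p in self.params.items()}
        return {n: sample_weight(p, eps[n]) for n, p in self.params.items()}

    def forward(
        self,
        X: np.ndarray,
        eps: dict[str, np.ndarray] | None = None,
        rng: np.random.Generator | None = None,
        training: bool = False,
        return_cache: bool = False,
    ):
        """Class probabilities (B, 2) for a batch of 150 x 30 epochs.

        Fresh weight samples are drawn per call (from ``rng``) unless an
        ``eps`` dict is passed or the model is non-stochastic.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (N_T, N_ELEC):
            raise ValueError(f"epochs must be (B, {N_T}, {N_ELEC}), got {X.shape}")
        if eps is None:
            eps = self.draw_eps(rng if rng is not None else np.random.default_rng())
        w = self._weights(eps)

        # L0: input batch-norm (one statistic pair for the whole input map)
        i0, bn0_cache = self.bn0.forward(X, axes=(0, 1, 2), training=training)
        # L1: spatial conv (1 x 30) + BN + ReLU
        z1 = np.einsum("btc,fc->btf", i0, w["w_spat"], optimize=True) + w["b_spat"]
        z1bn, bn1_cache = self.bn1.forward(z1, axes=(0, 1), training=training)
        a1 = np.maximum(z1bn, 0.0)
        # L2: max-pool (2 x 1), stride 2
        a1p = a1.reshape(-1, N_POOLED, POOL, N_SPATIAL)
        pool_arg = a1p.argmax(axis=2)
        m1 = a1p.max(axis=2)
        # L3: temporal conv (20, full depth, stride 6) + BN + ReLU
        windows = m1[:, _WIN_IDX, :]  # (B, 10, 20, 10)
        z3 = (
            np.einsum("bptf,gtf->bpg", windows, w["w_temp"], optimize=True)
            + w["b_temp"]
        )
        z3bn, bn3_cache = self.bn3.forward(z3, axes=(0, 1), training=training)
        a3 = np.maximum(z3bn, 0.0)
        h = a3.reshape(-1, N_FLAT)
        # L4: dense + softmax (as configured)
        z4 = h @ w["w_fc1"].T + w["b_fc1"]
        if self.hidden_activation == "softmax":
            a4 = _softmax(z4)
        else:
            a4 = np.maximum(z4, 0.0)
        # L5: dense to 2 scores; softmax -> class probabilities
        z5 = a4 @ w["w_out"].T + w["b_out"]
        probs = _softmax(z5)

        if not return_cache:
            return probs
        cache = dict(
            X=X, eps=eps, w=w, i0=i0, bn0=bn0_cache, z1=z1, bn1=bn1_cache,
            a1=a1, pool_arg=pool_arg, m1=m1, windows=windows, z3=z3,
            bn3=bn3_cache, a3=a3, h=h, z4=z4, a4=a4, z5=z5, probs=probs,
        )
        return probs, cache

    # ------------------------------------------------------------------ #

    def _backward(self, cache, y: np.ndarray, kl_weight: float):
        """Gradients of CE(batch mean) + kl_weight * KL wrt mu, rho and BN
        parameters.  Returns {name: grad} with keys 'mu:<p>', 'rho:<p>',
        'bn<k>:gamma', 'bn<k>:beta'."""
        w, eps = cache["w"], cache["eps"]
        B = cache["X"].shape[0]
        onehot = np.zeros((B, N_CLASSES))
        onehot[np.arange(B), y] = 1.0

        grads_w: dict[str, np.ndarray] = {}
        g: dict[str, np.ndarray] = {}

        dz5 = cache["probs"] - onehot  # CE summed over the batch
        grads_w["w_out"] = dz5.T @ cache["a4"]
        grads_w["b_out"] = dz5.sum(axis=0)
        da4 = dz5 @ w["w_out"]
        if self.hidden_activation == "softmax":
            a4 = cache["a4"]
            dz4 = a4 * (da4 - (da4 * a4).sum(axis=1, keepdims=True))
        else:
            dz4 = da4 * (cache["z4"] > 0)
        grads_w["w_fc1"] = dz4.T @ cache["h"]
        grads_w["b_fc1"] = dz4.sum(axis=0)
        dh = dz4 @ w["w_fc1"]

        da3 = dh.reshape(-1, N_POSITIONS, N_TEMPORAL)
        dz3bn = da3 * (cache["a3"] > 0)
        dz3, dg3, db3 = self.bn3.backward(dz3bn, cache["bn3"])
        g["bn3:gamma"], g["bn3:beta"] = dg3, db3
        grads_w["w_temp"] = np.einsum(
            "bpg,bptf->gtf", dz3, cache["windows"], optimize=True
        )
        grads_w["b_temp"] = dz3.sum(axis=(0, 1))
        dwindows = np.einsum("bpg,gtf->bptf", dz3, w["w_temp"], optimize=True)
        dm1 = np.zeros_like(cache["m1"])
        for p in range(N_POSITIONS):
            dm1[:, p * TEMP_STRIDE : p * TEMP_STRIDE + TEMP_KERNEL, :] += (
                dwindows[:, p]
            )

        da1 = np.zeros((B, N_T, N_SPATIAL))
        da1p = da1.reshape(B, N_POOLED, POOL, N_SPATIAL)
        bi, pi, fi = np.meshgrid(
            np.arange(B), np.arange(N_POOLED), np.arange(N_SPATIAL),
            indexing="ij",
        )
        da1p[bi, pi, cache["pool_arg"], fi] = dm1

        dz1bn = da1 * (cache["a1"] > 0)
        dz1, dg1, db1 = self.bn1.backward(dz1bn, cache["bn1"])
        g["bn1:gamma"], g["bn1:beta"] = dg1, db1
        grads_w["w_spat"] = np.einsum(
            "btf,btc->fc", dz1, cache["i0"], optimize=True
        )
        grads_w["b_spat"] = dz1.sum(axis=(0, 1))
        di0 = np.einsum("btf,fc->btc", dz1, w["w_spat"], optimize=True)
        _, dg0, db0 = self.bn0.backward(di0, cache["bn0"])
        g["bn0:gamma"], g["bn0:beta"] = dg0, db0

        p2 = self.prior_sd ** 2
        for name, param in self.params.items():
            dw = grads_w[name]
            dmu = dw.copy()
            if self.stochastic:
                sig = param.sigma
                drho = dw * eps[name] * _sigmoid(param.rho)
                if kl_weight > 0:
                    dmu += kl_weight * param.mu / p2
                    dkl_dsigma = -1.0 / sig + sig / p2
                    drho += kl_weight * dkl_dsigma * _sigmoid(param.rho)
                g[f"rho:{name}"] = drho
            g[f"mu:{name}"] = dmu
        return g

    # ------------------------------------------------------------------ #

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self.params.items():
            state[f"mu:{name}"] = p.mu
            state[f"rho:{name}"] = p.rho
        for k, bn in (("bn0", self.bn0), ("bn1", self.bn1), ("bn3", self.bn3)):
            state[f"{k}:gamma"] = bn.gamma
            state[f"{k}:beta"] = bn.beta
            state[f"{k}:running_mean"] = bn.running_mean
            state[f"{k}:running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            p.mu = np.asarray(state[f"mu:{name}"], dtype=float)
            p.rho = np.asarray(state[f"rho:{name}"], dtype=float)
        for k, bn in (("bn0", self.bn0), ("bn1", self.bn1), ("bn3", self.bn3)):
            bn.gamma = np.asarray(state[f"{k}:gamma"], dtype=float)
            bn.beta = np.asarray(state[f"{k}:beta"], dtype=float)
            bn.running_mean = np.asarray(state[f"{k}:running_mean"], dtype=float)
            bn.running_var = np.asarray(state[f"{k}:running_var"], dtype=float)

    def save(self, path_prefix: str) -> None:
        """Checkpoint: ``<prefix>.npz`` tensors + ``<prefix>.json`` config."""
        np.savez(path_prefix + ".npz", **self.state_dict())
        with open(path_prefix + ".json", "w") as fh:
            json.dump({
                "prior_sd": self.prior_sd,
                "hidden_activation": self.hidden_activation,
                "stochastic": self.stochastic,
            }, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "BayesianCNN":
        with open(path_prefix + ".json") as fh:
            cfg = json.load(fh)
        model = cls(**cfg)
        model.load_state_dict(dict(np.load(path_prefix + ".npz")))
        return model


def elbo_loss(
    model: BayesianCNN,
    X: np.ndarray,
    y: np.ndarray,
    n_batches: int = 1,
    eps: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> float:
    """Negative ELBO of one minibatch: cross-entropy (summed over the batch)
    on a sampled-weight forward pass plus (1/n_batches) of the total KL to
    the prior, so the per-epoch sum over batches estimates the full negative
    ELBO of the dataset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    probs = model.forward(X, eps=eps, rng=rng, training=training)
    ce = -float(np.sum(np.log(probs[np.arange(len(y)), y] + 1e-12)))
    return ce + model.kl() / n_batches


def train(
    model: BayesianCNN,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Minibatch Bayes-by-Backprop training; returns the per-epoch loss trace.

    Shuffling, weight sampling and everything else derive from ``cfg.seed``,
    so two runs with equal seeds produce identical traces.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    batch_size = cfg.batch_size
    if n < batch_size:
        warnings.warn(
            f"dataset ({n}) smaller than one batch ({batch_size}); "
            "falling back to a single batch per epoch"
        )
        batch_size = n
    rng = np.random.default_rng(cfg.seed)
    n_batches = int(np.ceil(n / batch_size))
    adam_m: dict[str, np.ndarray] = {}
    adam_v: dict[str, np.ndarray] = {}
    adam_t = 0
    trace: list[float] = []

    for _epoch in range(cfg.n_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = perm[b * batch_size : (b + 1) * batch_size]
            Xb, yb = X[idx], y[idx]
            grads_acc: dict[str, np.ndarray] | None = None
            loss_acc = 0.0
            for _s in range(cfg.mc_train):
                eps = model.draw_eps(rng)
                probs, cache = model.forward(
                    Xb, eps=eps, training=True, return_cache=True
                )
                ce = -float(np.sum(
                    np.log(probs[np.arange(len(yb)), yb] + 1e-12)
                ))
                loss_acc += ce + model.kl() / n_batches
                g = model._backward(cache, yb, kl_weight=1.0 / n_batches)
                if grads_acc is None:
                    grads_acc = g
                else:
                    for k in g:
                        grads_acc[k] += g[k]
            scale = 1.0 / cfg.mc_train
            epoch_loss += loss_acc * scale

            updates = {k: v * scale for k, v in grads_acc.items()}
            if cfg.optimizer == "adam":
                adam_t += 1
                b1, b2, aeps = 0.9, 0.999, 1e-8
                for k, gk in updates.items():
                    adam_m[k] = b1 * adam_m.get(k, 0.0) + (1 - b1) * gk
                    adam_v[k] = b2 * adam_v.get(k, 0.0) + (1 - b2) * gk ** 2
                    mhat = adam_m[k] / (1 - b1 ** adam_t)
                    vhat = adam_v[k] / (1 - b2 ** adam_t)
                    updates[k] = mhat / (np.sqrt(vhat) + aeps)
            _apply_sgd(model, updates, cfg.learning_rate)
        trace.append(epoch_loss / n_batches)
    return trace


def _apply_sgd(model: BayesianCNN, grads: dict[str, np.ndarray],
               lr: float) -> None:
    bns = {"bn0": model.bn0, "bn1": model.bn1, "bn3": model.bn3}
    for key, gk in grads.items():
        kind, name = key.split(":", 1)
        if kind == "mu":
            model.params[name].mu -= lr * gk
        elif kind == "rho":
            model.params[name].rho -= lr * gk
        else:
            bn = bns[kind]
            if name == "gamma":
                bn.gamma = bn.gamma - lr * gk
            else:
                bn.beta = bn.beta - lr * gk


def predict_p300(
    model: BayesianCNN,
    epochs: np.ndarray,
    T: int = 20,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Monte-Carlo P300 probability: mean over T weight draws, (B,) in [0, 1].

    Batch-norm uses the running statistics accumulated during training
    (frozen at evaluation).  For a non-stochastic model every draw is the
    same, so any T gives the deterministic value.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(epochs, dtype=float)
    if X.ndim == 2:
        X = X[None]
    acc = np.zeros(X.shape[0])
    for _ in range(T):
        probs = model.forward(X, rng=rng, training=False)
        acc += probs[:, 1]
    return acc / T


def recognize(
    model: BayesianCNN,
    averaged_epochs: np.ndarray,
    T: int = 20,
    rng: np.random.Generator | int | None = None,
    return_probs: bool = False,
):
    """Pick the candidate button with the highest Monte-Carlo P300
    probability; ties go to the lowest candidate index."""
    X = np.asarray(averaged_epochs, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[0] == 0:
        raise ValueError("empty candidate list")
    probs = predict_p300(model, X, T=T, rng=rng)
    choice = int(np.argmax(probs))
    if return_probs:
        return choice, probs
    return choice
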