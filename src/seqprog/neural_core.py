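"""Feed-forward risk models and their variational-Bayesian counterparts.

A deterministic multi-layer perceptron maps a feature vector to a
single scalar per task (a class logit or a Cox risk).  Its Bayesian
counterpart places a mean-field Gaussian q(theta) = N(mu, sigma) over
every weight, trained by reparametrized sampling (Bayes by backprop):
theta = mu + softplus(rho) * eps with external standard-normal noise,
so gradients flow to (mu, rho).  Predictive uncertainty comes from
repeated stochastic forward passes.

Defaults chosen as package policy: sigma is parametrized through
softplus to guarantee positivity; the prior is N(0, 1) per weight; the
KL term is scaled by 1/n_train; one noise draw per weight per forward
pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as F
from .autodiff import Tensor

__all__ = [
    "MLPConfig", "VariationalParameter", "PosteriorPredictive",
    "Linear", "BayesianLinear", "PReLU", "MLP",
    "mlp_forward", "variational_sample", "kl_gaussian", "elbo_loss",
    "posterior_predictive",
]


@dataclass(frozen=True)
class VariationalParameter:
    """(mu, rho) pair defining a weight's Gaussian posterior; sigma = softplus(rho)."""

    mu: Tensor
    rho: Tensor

    @property
    def sigma(self):
        return F.softplus(self.rho)


def variational_sample(vp: VariationalParameter, noise):
    """Reparametrized draw theta = mu + softplus(rho) * noise."""
    return vp.mu + vp.sigma * np.asarray(noise, float)


def kl_gaussian(vp, mu0: float = 0.0, sigma0: float = 1.0):
    """KL( N(mu, sigma) || N(mu0, sigma0) ), summed over weights.

    Accepts a :class:`VariationalParameter` (returns a Tensor on the
    tape) or a plain (mu, sigma) pair of arrays (returns a float).
    """
    if isinstance(vp, VariationalParameter):
        mu, sigma = vp.mu, vp.sigma
    else:
        mu, sigma = vp
    term = (F.log(sigma0 / sigma) if isinstance(sigma, Tensor)
            else np.log(sigma0 / np.asarray(sigma, float)))
    kl = term + (sigma * sigma + (mu - mu0) * (mu - mu0)) / (2.0 * sigma0 ** 2) - 0.5
    return F.tsum(kl)


def elbo_loss(task_loss, kl_total, n_train: int, beta: float = 1.0):
    """Minibatch variational objective: task loss + beta * KL / n_train."""
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    return task_loss + beta * kl_total / float(n_train)


# -- layers ------------------------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x, rng=None, sample=True):
        return F.matmul(x, self.W) + self.b

    def parameters(self):
        return [self.W, self.b]

    def kl(self):
        return 0.0


# rho init giving a small but trainable initial sigma (softplus(-5) ~ 6.7e-3)
_RHO_INIT = -5.0


class BayesianLinear:
    """Linear layer with a mean-field Gaussian posterior over W and b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = VariationalParameter(
            Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True),
            Tensor(np.full((n_in, n_out), _RHO_INIT), requires_grad=True))
        self.b = VariationalParameter(
            Tensor(np.zeros(n_out), requires_grad=True),
            Tensor(np.full(n_out, _RHO_INIT), requires_grad=True))

    def forward(self, x, rng=None, sample=True):
        if sample:
            if rng is None:
                raise ValueError("stochastic forward pass needs an rng")
            W = variational_sample(self.W, rng.standard_normal(self.W.mu.shape))
            b = variational_sample(self.b, rng.standard_normal(self.b.mu.shape))
        else:   # sigma frozen at 0: the deterministic (SN) limit
            W, b = self.W.mu, self.b.mu
        return F.matmul(x, W) + b

    def parameters(self):
        return [self.W.mu, self.W.rho, self.b.mu, self.b.rho]

    def kl(self):
        return kl_gaussian(self.W) + kl_gaussian(self.b)


class PReLU:
    def __init__(self, init: float = 0.25):
        self.alpha = Tensor(np.array(init), requires_grad=True)

    def forward(self, x, rng=None, sample=True):
        return F.prelu(x, self.alpha)

    def parameters(self):
        return [self.alpha]

    def kl(self):
        return 0.0


_ACTIVATIONS = {"prelu": PReLU, "tanh": None, "relu": None}


@dataclass(frozen=True)
class MLPConfig:
    """Architecture of a single-task risk model (scalar output)."""

    input_dim: int
    hidden_layers: tuple = (32, 32)
    activation: str = "prelu"
    dropout: float = 0.0
    bayesian: bool = False

    def __post_init__(self):
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden widths must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class MLP:
    """Multi-layer perceptron with one scalar output per task.

    ``forward`` returns the pre-activation q(x); classification heads
    apply a sigmoid downstream (f = sigmoid(q)), survival heads use q
    as the Cox risk directly.
    """

    def __init__(self, config: MLPConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layer_cls = BayesianLinear if config.bayesian else Linear
        dims = [config.input_dim, *config.hidden_layers, 1]
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.layers.append(layer_cls(a, b, rng))
            if i < len(dims) - 2:
                if config.activation == "prelu":
                    self.layers.append(PReLU())
                else:
                    self.layers.append(_FnActivation(config.activation))

    def forward(self, x, rng=None, sample=True, training=False,
                dropout_rng=None):
        h = x
        for layer in self.layers:
            h = layer.forward(h, rng=rng, sample=sample)
            if (training and self.config.dropout > 0.0 and isinstance(layer, (PReLU, _FnActivation))):
                keep = (dropout_rng or rng).uniform(size=np.shape(h.data if isinstance(h, Tensor) else h)) >= self.config.dropout
                h = h * (keep / (1.0 - self.config.dropout))
        # squeeze the trailing singleton output dimension
        if isinstance(h, Tensor):
            return h.reshape(h.shape[:-1]) if h.shape[-1] == 1 else h
        return np.squeeze(h, axis=-1)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def kl(self):
        total = 0.0
        for layer in self.layers:
            total = total + layer.kl()
        return total

    @property
    def bayesian(self) -> bool:
        return self.config.bayesian

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        manifest = {"config": self.config.__dict__ | {
            "hidden_layers": list(self.config.hidden_layers)}}
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path):
        archive = np.load(path, allow_pickle=False)
        manifest = json.loads(str(archive["manifest"]))
        cfg = manifest["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        model = cls(MLPConfig(**cfg))
        for i, p in enumerate(model.parameters()):
            p.data[...] = archive[f"p{i}"]
        return model


class _FnActivation:
    def __init__(self, name: str):
        self.fn = {"tanh": F.tanh, "relu": F.relu}[name]

    def forward(self, x, rng=None, sample=True):
        return self.fn(x)

    def parameters(self):
        return []

    def kl(self):
        return 0.0


def mlp_forward(model: MLP, x, rng=None, sample=False):
    """Evaluate a model; returns (q, f) with f = sigmoid(q)."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != model.config.input_dim:
        raise ValueError("input dimension mismatch")
    q = model.forward(Tensor(x), rng=rng, sample=sample and model.bayesian)
    q = q.data if isinstance(q, Tensor) else q
    return q, 1.0 / (1.0 + np.exp(-q))


@dataclass(frozen=True)
class PosteriorPredictive:
    """Summary of K stochastic forward passes."""

    mean: np.ndarray
    std: np.ndarray
    samples: np.ndarray
    std_defined: bool = True


def posterior_predictive(model: MLP, x, K: int = 100, seed: int = 0,
                         transform=None) -> PosteriorPredictive:
    """Mean/std over K reparametrized forward passes (deterministic under seed)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.atleast_2d(np.asarray(x, float))
    outs = []
    for _ in range(K):
        q = model.forward(Tensor(x), rng=rng, sample=model.bayesian)
        q = q.data if isinstance(q, Tensor) else q
        outs.append(transform(q) if transform is not None else q)
    samples = np.stack(outs)
    std_defined = K >= 2
    std = samples.std(axis=0, ddof=0) if std_defined else np.zeros_like(samples[0])
    return PosteriorPredictive(samples.mean(axis=0), std, samples, std_defined)
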