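"""Building blocks of the 2.5D CNNs: mish, switchable normalization, conv, dense."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .autograd import Var, conv2d, maxpool2d

__all__ = ["mish", "Conv2d", "SwitchableNorm2d", "Dense", "MaxPool2d", "softmax_weights"]

EPS = 1e-5


def mish(x):
    """mish(x) = x * tanh(softplus(x)); numerically stable for large |x|."""
    if isinstance(x, Var):
        return x * x.softplus().tanh()
    x = np.asarray(x, dtype=np.float64)
    sp = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
    return x * np.tanh(sp)


def softmax_weights(logits: Var) -> Var:
    e = (logits - float(logits.data.max())).exp()
    return e / e.sum()


class Module:
    def parameters(self) -> List[Var]:
        return []

    def state(self) -> Dict[str, np.ndarray]:
        return {}

    def load_state(self, state: Dict[str, np.ndarray], prefix: str) -> None:
        pass


class Conv2d(Module):
    """3x3 (or 1x1) convolution, stride 1, 'same' padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, name: str):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Var(rng.normal(0.0, scale, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Var(np.zeros(c_out), requires_grad=True)
        self.pad = k // 2
        self.name = name

    def __call__(self, x: Var) -> Var:
        return conv2d(x, self.weight, self.bias, pad=self.pad)

    def parameters(self):
        return [self.weight, self.bias]

    def state(self):
        return {f"{self.name}.weight": self.weight.data, f"{self.name}.bias": self.bias.data}

    def load_state(self, state, prefix=""):
        self.weight.data = state[f"{self.name}.weight"]
        self.bias.data = state[f"{self.name}.bias"]


class SwitchableNorm2d(Module):
    """Switchable normalization over NCHW feature maps.

    Normalizes with a softmax-weighted blend of instance, layer and batch
    statistics (separate mixing weights for means and variances), then
    applies a per-channel affine transform.  Batch statistics use running
    averages at inference.
    """

    def __init__(self, channels: int, name: str, momentum: float = 0.9):
        self.gamma = Var(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Var(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.mean_logits = Var(np.zeros(3), requires_grad=True)
        self.var_logits = Var(np.zeros(3), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.momentum = momentum
        self.name = name
        self.training = True

    def __call__(self, x: Var) -> Var:
        if x.data.shape[0] == 0:
            raise ValueError("empty batch")
        # instance: per (N, C); layer: per N; batch: per C
        mu_in = x.mean(axis=(2, 3), keepdims=True)
        var_in = ((x - mu_in) ** 2).mean(axis=(2, 3), keepdims=True)
        mu_ln = x.mean(axis=(1, 2, 3), keepdims=True)
        var_ln = ((x - mu_ln) ** 2).mean(axis=(1, 2, 3), keepdims=True)
        if self.training:
            mu_bn = x.mean(axis=(0, 2, 3), keepdims=True)
            var_bn = ((x - mu_bn) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu_bn.data
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var_bn.data
        else:
            mu_bn = Var(self.running_mean)
            var_bn = Var(self.running_var)
        wm = softmax_weights(self.mean_logits)
        wv = softmax_weights(self.var_logits)
        # blend statistics (Var indexing unsupported; split via masked sums)
        wm0, wm1, wm2 = _split3(wm)
        wv0, wv1, wv2 = _split3(wv)
        mu = mu_in * wm0 + mu_ln * wm1 + mu_bn * wm2
        var = var_in * wv0 + var_ln * wv1 + var_bn * wv2
        xhat = (x - mu) * (var + EPS) ** -0.5
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta, self.mean_logits, self.var_logits]

    def state(self):
        p = self.name
        return {
            f"{p}.gamma": self.gamma.data,
            f"{p}.beta": self.beta.data,
            f"{p}.mean_logits": self.mean_logits.data,
            f"{p}.var_logits": self.var_logits.data,
            f"{p}.running_mean": self.running_mean,
            f"{p}.running_var": self.running_var,
        }

    def load_state(self, state, prefix=""):
        p = self.name
        self.gamma.data = state[f"{p}.gamma"]
        self.beta.data = state[f"{p}.beta"]
        self.mean_logits.data = state[f"{p}.mean_logits"]
        self.var_logits.data = state[f"{p}.var_logits"]
        self.running_mean = state[f"{p}.running_mean"]
        self.running_var = state[f"{p}.running_var"]


def _split3(w: Var):
    """Split a 3-vector Var into three scalar Vars (autograd-compatible)."""
    outs = []
    for k in range(3):
        mask = np.zeros(3)
        mask[k] = 1.0
        outs.append((w * mask).sum())
    return outs


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Var(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Var(np.zeros(n_out), requires_grad=True)
        self.name = name

    def __call__(self, x: Var) -> Var:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]

    def state(self):
        return {f"{self.name}.weight": self.weight.data, f"{self.name}.bias": self.bias.data}

    def load_state(self, state, prefix=""):
        self.weight.data = state[f"{self.name}.weight"]
        self.bias.data = state[f"{self.name}.bias"]


class MaxPool2d(Module):
    def __init__(self, name: str):
        self.name = name

    def __call__(self, x: Var) -> Var:
        return maxpool2d(x, 2)
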