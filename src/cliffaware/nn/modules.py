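"""Trainable layers and the Adam optimizer for the tensor engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Linear", "BatchNorm1d", "Adam"]


class Module:
    """Base class: tracks parameters and buffers of nested modules."""

    buffer_names: tuple[str, ...] = ()

    def _children(self) -> list["Module"]:
        out: list["Module"] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                out.append(value)
            elif isinstance(value, (list, tuple)):
                out.extend(v for v in value if isinstance(v, Module))
        return out

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, (list, tuple)):
                params.extend(
                    v for v in value if isinstance(v, Tensor) and v.requires_grad
                )
        for child in self._children():
            params.extend(child.parameters())
        return params

    def _buffer_refs(self) -> list[tuple["Module", str]]:
        refs = [(self, name) for name in self.buffer_names]
        for child in self._children():
            refs.extend(child._buffer_refs())
        return refs

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """Snapshot of parameters and buffers (running statistics), so a
        restored state reproduces evaluation outputs exactly."""
        state = [p.data.copy() for p in self.parameters()]
        state += [getattr(obj, name).copy() for obj, name in self._buffer_refs()]
        return state

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        refs = self._buffer_refs()
        if len(arrays) != len(params) + len(refs):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy()
        for (obj, name), a in zip(refs, arrays[len(params):]):
            setattr(obj, name, a.copy())


class Linear(Module):
    """Affine layer with Glorot-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_dim, out_dim)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Per-channel batch normalization over rows.

    Training mode normalizes with batch statistics and updates running
    estimates; evaluation mode uses the running estimates, so outputs
    are deterministic functions of the input.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            n = x.data.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            xhat = centered / ((var + self.eps).sqrt())
        else:
            xhat = (x - self.running_mean[None, :]) / np.sqrt(
                self.running_var[None, :] + self.eps
            )
        return xhat * self.gamma + self.beta


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
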