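"""Parameterised layers: convolution, batch normalisation, linear.

Initialisation follows common CNN practice (He-uniform fan-in for conv and
linear weights); every layer owns named parameter tensors so optimizers and
checkpoints can address them as ``{layer_name}.{param_name}``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, linear


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
        return out

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = mod.running_mean.copy()
                state[f"__bn{i}.running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].astype(np.float32).copy()
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = state[f"__bn{i}.running_mean"].copy()
                mod.running_var = state[f"__bn{i}.running_var"].copy()

    def zero_init(self) -> None:
        for p in self.parameters():
            p.data[...] = 0.0


def _he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.weight = Tensor(_he_uniform((c_out, c_in, k, k), fan_in, rng),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
                     if bias else None)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_uniform((n_out, n_in), n_in, rng), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running statistics
    for inference mode (exponential update, momentum 0.1)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out_data = (self.gamma.data[None, :, None, None] * xhat
                    + self.beta.data[None, :, None, None])
        gamma, beta = self.gamma, self.beta

        def bw(g):
            gam = gamma.data[None, :, None, None]
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            gxhat = g * gam
            if train:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv_std[None, :, None, None] / n) * (n * gxhat - s1 - xhat * s2)
            else:
                gx = gxhat * inv_std[None, :, None, None]
            x._accumulate(gx.astype(np.float32))

        from .autograd import _make
        return _make(out_data.astype(np.float32), (x, gamma, beta), bw)
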