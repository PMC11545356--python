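"""Neural-network modules: parameters, conv/linear/batch-norm layers.

Modules own :class:`~scaphonet.nnkit.tensor.Tensor` parameters and optional
non-trainable buffers (batch-norm running statistics).  ``state_dict`` /
``load_state_dict`` serialize to flat ``{name: ndarray}`` dicts so checkpoints
are plain ``npz`` files.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, matmul, relu


class Module:
    """Base class with parameter registration and train/eval switching."""

    def __init__(self):
        self.training = True

    # -- registry ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).items():
            pass
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.array(buf, copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = {name for name, _ in self.named_buffers()}
        for key, arr in state.items():
            if key in params:
                if params[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(arr, dtype=params[key].data.dtype)
            elif key in bufs:
                self._set_buffer(key, arr)
            else:
                raise KeyError(f"unexpected state key {key!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing state keys: {sorted(missing)}")

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            attr = getattr(obj, part) if not part.isdigit() else obj[int(part)]  # type: ignore[index]
            obj = attr
        cur = getattr(obj, parts[-1])
        setattr(obj, parts[-1], np.asarray(arr, dtype=np.asarray(cur).dtype))

    def __getitem__(self, idx):  # lists of modules live in Sequential
        raise TypeError(f"{type(self).__name__} is not indexable")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __getitem__(self, idx):
        return self.layers[idx]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer.forward(x)
        return x


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None,
                 dilation: int = 1, bias: bool = True, dtype=np.float32):
        super().__init__()
        k = kernel_size
        self.stride = stride
        self.dilation = dilation
        # "same" padding by default for odd kernels at stride 1
        self.padding = padding if padding is not None else dilation * (k - 1) // 2
        fan_in = in_channels * k * k
        self.weight = Tensor(
            he_init(rng, (out_channels, in_channels, k, k), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
            if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(
            he_init(rng, (in_features, out_features), in_features, dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if self.training:
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * v).astype(self.running_var.dtype)
            inv = 1.0 / np.sqrt(v + self.eps)
            xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
            count = n * h * w
            gamma = self.gamma

            def grad_x(g):
                gg = gamma.data[None, :, None, None]
                gxhat = g * gg
                sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                return (inv[None, :, None, None] *
                        (gxhat - sum_g / count - xhat * sum_gx / count))

            parents = (
                (x, grad_x),
                (self.gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
                (self.beta, lambda g: g.sum(axis=(0, 2, 3))),
            )
            y = xhat * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
            return Tensor(y.astype(x.data.dtype), _parents=parents)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.data * inv)[None, :, None, None]
        shift = (self.beta.data - self.gamma.data * self.running_mean * inv)[None, :, None, None]
        xhat_eval = (x.data - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        parents = (
            (x, lambda g: g * scale),
            (self.gamma, lambda g: (g * xhat_eval).sum(axis=(0, 2, 3))),
            (self.beta, lambda g: g.sum(axis=(0, 2, 3))),
        )
        return Tensor((x.data * scale + shift).astype(x.data.dtype), _parents=parents)


class ConvBNReLU(Module):
    """3x3 (or kxk) conv -> batch norm -> ReLU, the package's standard block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel_size: int = 3, stride: int = 1, dilation: int = 1):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel_size, rng, stride=stride,
                           dilation=dilation, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn.forward(self.conv.forward(x)))


class ResidualBlock(Module):
    """Two 3x3 conv-BN stages with an identity (or projected) skip."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, rng, stride=stride, padding=0, bias=False)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        y = relu(self.bn1.forward(self.conv1.forward(x)))
        y = self.bn2.forward(self.conv2.forward(y))
        skip = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x))
        return relu(y + skip)
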