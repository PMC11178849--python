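"""Layer abstractions over the autodiff primitives.

Modules register parameters and sub-modules by attribute assignment and expose
ordered ``state_dict`` / ``load_state_dict`` for checkpointing. Weight
initialization draws from an explicit ``numpy.random.Generator`` so that two
builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        for name, p in self._params.items():
            out.append((prefix + name, p))
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def summary(self) -> str:
        lines = [f"{self.__class__.__name__}: {self.n_parameters():,} parameters"]
        for name, p in self.named_parameters():
            lines.append(f"  {name:50s} {str(p.data.shape):24s} {p.data.size:>10,}")
        return "\n".join(lines)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv3d(Module):
    """3x3x3 (or 1x1x1) volumetric convolution, channels-last, He init."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, pad: int | None = None, bias: bool = True):
        super().__init__()
        if pad is None:
            pad = k // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        fan_in = cin * k ** 3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(k, k, k, cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class GroupNorm(Module):
    """Affine group normalization; ``groups`` clipped to a divisor of channels."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        while channels % groups:
            groups -= 1
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x):
        return F.group_norm(x, self.gamma, self.beta, self.groups, self.eps)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class MaxPool2(Module):
    def forward(self, x):
        return F.maxpool2(x)


class Upsample2(Module):
    def forward(self, x):
        return F.upsample2(x)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator, std: float | None = None):
        super().__init__()
        if std is None:
            std = float(np.sqrt(1.0 / fin))
        self.weight = Parameter(rng.normal(0.0, std, size=(fin, fout)))
        self.bias = Parameter(np.zeros(fout))

    def forward(self, x):
        return T.add(T.matmul(x, self.weight), self.bias)


class GlobalAvgPool(Module):
    """Mean over the three spatial axes: (N, D, H, W, C) -> (N, C)."""

    def forward(self, x):
        return T.mean_axes(x, (1, 2, 3))
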