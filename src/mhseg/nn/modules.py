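"""Minimal module/layer system over the autodiff tensors."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor


class Module:
    """Base class: parameter traversal, naming, and output recording.

    Every call stores the output tensor on ``_last_output`` so that
    saliency code can reach intermediate feature maps by module name
    after a forward pass.
    """

    def __init__(self):
        self._last_output: Tensor | None = None

    def forward(self, *args, **kwargs) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs) -> Tensor:
        out = self.forward(*args, **kwargs)
        self._last_output = out
        return out

    # -- traversal ---------------------------------------------------------

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if name.startswith("_last"):
                continue
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self) -> list[Parameter]:
        """Unique parameters in traversal order (shared tensors once)."""
        seen: set[int] = set()
        out: list[Parameter] = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        seen: dict[int, str] = {}
        for name, p in self.named_parameters():
            if id(p) in seen:  # shared tensor: store once under first name
                continue
            seen[id(p)] = name
            state[name] = p.data.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name not in params:
                raise KeyError(f"unknown parameter {name!r}")
            if params[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}: "
                                 f"{params[name].data.shape} vs {arr.shape}")
            params[name].data = np.asarray(arr, dtype=np.float32).copy()


def kaiming_init(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int, a: float = 0.25) -> np.ndarray:
    """He fan-in normal init with the parametric-rectifier gain."""
    std = np.sqrt(2.0 / ((1.0 + a * a) * fan_in))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.dilation = kernel, stride, dilation
        fan_in = cin * kernel ** 3
        self.weight = Parameter(kaiming_init(rng, (cout, cin, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor, dilation: int | None = None) -> Tensor:
        d = self.dilation if dilation is None else dilation
        return F.conv3d(x, self.weight, self.bias, stride=self.stride, dilation=d)


class ConvTranspose3d(Module):
    def __init__(self, cin: int, cout: int, stride: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.stride = cin, cout, stride
        fan_in = cin * stride ** 3
        self.weight = Parameter(kaiming_init(rng, (cin, cout, stride, stride, stride), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm3d(x, self.gamma, self.beta, eps=self.eps)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.full(channels, init, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.slope)
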