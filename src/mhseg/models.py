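"""Segmentation network architectures.

Four variants built on one residual U-Net trunk:

``multichannel``
    The baseline: all input channels stacked and fed to a single first
    encoder level.
``multihead_1``
    The first encoder level is replaced by three encoding heads: a
    non-dilated head reading t2w only, plus two dilated heads (rates 2
    and 4) reading *all* input channels. The two dilated heads share one
    set of convolution weights (the same kernels applied at different
    dilation rates), and the three head outputs are fused by elementwise
    summation.
``multihead_2``
    As ``multihead_1`` but the dilated heads read only the DWI-derived
    channels (b1000/adc), separating anatomical from diffusion encoding
    while keeping the weight sharing.
``multihead_3``
    Separate (unshared) dilated heads for the DWI-derived channels; their
    outputs are concatenated, projected back down with a 1x1x1
    convolution, and summed with the t2w head.

The trunk: each encoder level is two residual blocks
(conv -> instance norm -> PReLU, twice, with an additive identity path
that is a 1x1x1 projection when shapes change); downsampling happens in
the first convolution of a level (stride 2); four downsampling steps with
filters (32, 64, 128, 256) and a 512-channel bottleneck; the decoder
mirrors it with kernel-2/stride-2 transposed convolutions and skip
concatenation. Dilated convolutions pad by their dilation rate so every
head emits the same spatial shape, which summation fusion requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigurationError, ValidationError
from .nn import (Conv3d, ConvTranspose3d, InstanceNorm3d, Module, PReLU,
                 Tensor, as_tensor, concat, no_grad)

KNOWN_CHANNELS = ("t2w", "b1000", "adc")
Variant = Literal["multichannel", "multihead_1", "multihead_2", "multihead_3"]


class ModelConfig(BaseModel):
    """Architecture configuration; serializable into run configs and
    checkpoints."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    variant: Variant = "multichannel"
    input_channels: tuple[str, ...] = ("t2w", "b1000", "adc")
    encoder_filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    bottleneck_filters: int = 512
    head_dilations: tuple[int, int, int] = (1, 2, 4)
    norm: Literal["instance"] = "instance"
    activation: Literal["prelu"] = "prelu"
    out_channels: int = 1
    width_multiplier: float = 1.0
    # alternative reading of the shared-head wiring: independent kernels for
    # the two dilated heads even in variants 1/2
    shared_head_kernels: bool = True

    @field_validator("input_channels")
    @classmethod
    def _known(cls, v):
        bad = [c for c in v if c not in KNOWN_CHANNELS]
        if bad:
            raise ValueError(f"unknown channels {bad}; known: {KNOWN_CHANNELS}")
        if len(set(v)) != len(v):
            raise ValueError("duplicate channels")
        return tuple(v)

    @model_validator(mode="after")
    def _check(self):
        if not (1 <= len(self.input_channels) <= 3):
            raise ValueError("1-3 input channels required")
        if self.variant != "multichannel":
            if "t2w" not in self.input_channels:
                raise ValueError(f"{self.variant} requires the t2w channel")
            if not any(c in self.input_channels for c in ("b1000", "adc")):
                raise ValueError(f"{self.variant} requires b1000 and/or adc")
        if self.head_dilations[0] != 1:
            raise ValueError("the first (t2w) head is non-dilated; head_dilations[0] must be 1")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        return self

    def scaled_filters(self) -> tuple[list[int], int]:
        f = [max(1, int(round(v * self.width_multiplier))) for v in self.encoder_filters]
        fb = max(1, int(round(self.bottleneck_filters * self.width_multiplier)))
        return f, fb


@dataclass(frozen=True)
class HeadWiring:
    """Per-head channel sets and dilations plus the fusion scheme."""

    heads: tuple[tuple[tuple[str, ...], int], ...]  # ((channels, dilation), ...)
    sharing: Literal["shared", "independent", "none"]
    fusion: Literal["sum", "concat_project_sum", "none"]

    @classmethod
    def from_config(cls, config: ModelConfig) -> "HeadWiring":
        chans = config.input_channels
        d1, d2, d3 = config.head_dilations
        if config.variant == "multichannel":
            return cls(heads=((tuple(chans), 1),), sharing="none", fusion="none")
        dwi = tuple(c for c in chans if c != "t2w")
        if config.variant == "multihead_1":
            return cls(heads=((("t2w",), d1), (tuple(chans), d2), (tuple(chans), d3)),
                       sharing="shared" if config.shared_head_kernels else "independent",
                       fusion="sum")
        if config.variant == "multihead_2":
            return cls(heads=((("t2w",), d1), (dwi, d2), (dwi, d3)),
                       sharing="shared" if config.shared_head_kernels else "independent",
                       fusion="sum")
        return cls(heads=((("t2w",), d1), (dwi, d2), (dwi, d3)),
                   sharing="independent", fusion="concat_project_sum")


class ResidualBlock(Module):
    """conv-norm-act twice plus an identity path (projected when shapes
    change). The dilation of the convolutions can be overridden per call,
    which is how two dilated heads share one set of kernels."""

    def __init__(self, cin: int, cout: int, stride: int = 1, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, stride=stride, dilation=dilation, rng=rng)
        self.norm1 = InstanceNorm3d(cout)
        self.act1 = PReLU(cout)
        self.conv2 = Conv3d(cout, cout, 3, stride=1, dilation=dilation, rng=rng)
        self.norm2 = InstanceNorm3d(cout)
        self.act2 = PReLU(cout)
        if cin != cout or stride != 1:
            self.skip = Conv3d(cin, cout, 1, stride=stride, rng=rng)
        else:
            self.skip = None

    def forward(self, x: Tensor, dilation: int | None = None) -> Tensor:
        h = self.act1(self.norm1(self.conv1(x, dilation=dilation)))
        h = self.norm2(self.conv2(h, dilation=dilation))
        identity = self.skip(x) if self.skip is not None else x
        return self.act2(h + identity)


class BlockPair(Module):
    """Two residual blocks — one encoder/decoder level."""

    def __init__(self, cin: int, cout: int, stride: int = 1, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.b1 = ResidualBlock(cin, cout, stride=stride, dilation=dilation, rng=rng)
        self.b2 = ResidualBlock(cout, cout, stride=1, dilation=dilation, rng=rng)

    def forward(self, x: Tensor, dilation: int | None = None) -> Tensor:
        return self.b2(self.b1(x, dilation=dilation), dilation=dilation)


class MultiHeadResUNet(Module):
    """The configurable segmentation network (all four variants)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.wiring = HeadWiring.from_config(config)
        rng = np.random.default_rng(seed)
        f, fb = config.scaled_filters()
        nchan = len(config.input_channels)
        self._chan_index = {c: i for i, c in enumerate(config.input_channels)}

        # --- stem: first encoder level or the multi-head replacement ------
        self.input_convs: list[tuple[Conv3d, tuple[str, ...]]] = []
        if config.variant == "multichannel":
            self.stem = BlockPair(nchan, f[0], rng=rng)
            self._register_input_block(self.stem, config.input_channels)
            self.t2w_head = None
            self.dwi_head_shared = None
            self.dwi_head_d2 = None
            self.dwi_head_d4 = None
            self.fusion_proj = None
        else:
            (t2w_set, _), (set2, d2), (set3, d3) = self.wiring.heads
            self.stem = None
            self.t2w_head = BlockPair(len(t2w_set), f[0], dilation=1, rng=rng)
            self._register_input_block(self.t2w_head, t2w_set)
            if self.wiring.sharing == "shared":
                self.dwi_head_shared = BlockPair(len(set2), f[0], dilation=d2, rng=rng)
                self.dwi_head_d2 = self.dwi_head_d4 = None
                self._register_input_block(self.dwi_head_shared, set2)
            else:
                self.dwi_head_shared = None
                self.dwi_head_d2 = BlockPair(len(set2), f[0], dilation=d2, rng=rng)
                self.dwi_head_d4 = BlockPair(len(set3), f[0], dilation=d3, rng=rng)
                self._register_input_block(self.dwi_head_d2, set2)
                self._register_input_block(self.dwi_head_d4, set3)
            if self.wiring.fusion == "concat_project_sum":
                self.fusion_proj = Conv3d(2 * f[0], f[0], 1, rng=rng)
            else:
                self.fusion_proj = None

        # --- encoder trunk ------------------------------------------------
        self.enc = [BlockPair(f[i - 1], f[i], stride=2, rng=rng) for i in range(1, 4)]
        self.bottleneck = BlockPair(f[3], fb, stride=2, rng=rng)

        # --- decoder --------------------------------------------------------
        dec_in = [fb, f[3], f[2], f[1]]
        dec_out = [f[3], f[2], f[1], f[0]]
        self.ups = [ConvTranspose3d(ci, co, stride=2, rng=rng)
                    for ci, co in zip(dec_in, dec_out)]
        self.dec_stages = [BlockPair(2 * co, co, rng=rng) for co in dec_out]
        self.out_conv = Conv3d(f[0], config.out_channels, 1, rng=rng)

        self.last_head_outputs: dict[str, Tensor] = {}

    # name of the last decoder residual block before the output convolution;
    # the default source layer for saliency mapping
    penultimate_layer = "dec_stages.3.b2"

    def _register_input_block(self, pair: BlockPair, channels: Sequence[str]) -> None:
        self.input_convs.append((pair.b1.conv1, tuple(channels)))
        if pair.b1.skip is not None:
            self.input_convs.append((pair.b1.skip, tuple(channels)))

    def _select(self, x: Tensor, channels: Sequence[str]) -> Tensor:
        idx = [self._chan_index[c] for c in channels]
        if len(idx) == len(self._chan_index) and idx == sorted(idx):
            return x
        return x.take_channels(idx)

    def _stem_forward(self, x: Tensor) -> Tensor:
        self.last_head_outputs = {}
        if self.config.variant == "multichannel":
            return self.stem(x)
        (t2w_set, _), (set2, d2), (set3, d3) = self.wiring.heads
        t2w_out = self.t2w_head(self._select(x, t2w_set))
        if self.dwi_head_shared is not None:
            h2 = self.dwi_head_shared(self._select(x, set2), dilation=d2)
            h4 = self.dwi_head_shared(self._select(x, set3), dilation=d3)
        else:
            h2 = self.dwi_head_d2(self._select(x, set2))
            h4 = self.dwi_head_d4(self._select(x, set3))
        self.last_head_outputs = {"t2w@1": t2w_out, f"dwi@{d2}": h2, f"dwi@{d3}": h4}
        if self.wiring.fusion == "concat_project_sum":
            return self.fusion_proj(concat([h2, h4], axis=1)) + t2w_out
        return t2w_out + h2 + h4

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 5 or x.shape[1] != len(self.config.input_channels):
            raise ValidationError(
                f"expected batch of shape (N, {len(self.config.input_channels)}, X, Y, Z) "
                f"for channels {self.config.input_channels}, got {x.shape}", field="batch")
        h = self._stem_forward(x)
        skips = [h]
        for level in self.enc:
            h = level(h)
            skips.append(h)
        h = self.bottleneck(h)
        for up, stage, skip in zip(self.ups, self.dec_stages, reversed(skips)):
            h = up(h)
            h = stage(concat([h, skip], axis=1))
        return self.out_conv(h)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Inference on one (C, X, Y, Z) array; returns (1, X, Y, Z) logits."""
        with no_grad():
            out = self(np.asarray(x, dtype=np.float32)[None])
        return out.data[0]


def head_gradient_footprint(pair: BlockPair, cin: int,
                            size: tuple[int, int, int] = (33, 33, 9),
                            dilation: int | None = None,
                            seed: int = 0) -> np.ndarray:
    """Nonzero-gradient support of a head's center output voxel w.r.t. its
    input — a direct receptive-field measurement of the convolution path.

    The head's instance-norm layers are bypassed for the probe: their
    spatial-mean statistics couple every voxel to every other, which would
    mask the local footprint the dilated kernels actually read. The
    pointwise activations do not change the support either, so the probe
    composes exactly the head's convolutions (with its real weights,
    strides, and dilations).
    """
    rng = np.random.default_rng(seed)
    x = Tensor(rng.normal(size=(1, cin) + size).astype(np.float32),
               requires_grad=True)

    def block(b: ResidualBlock, h: Tensor) -> Tensor:
        out = b.conv2(b.conv1(h, dilation=dilation), dilation=dilation)
        return out + (b.skip(h) if b.skip is not None else h)

    out = block(pair.b2, block(pair.b1, x))
    seed_grad = np.zeros(out.shape, dtype=np.float32)
    seed_grad[(0, 0) + tuple(s // 2 for s in size)] = 1.0
    out.backward(seed_grad)
    return np.abs(x.grad).sum(axis=(0, 1)) > 0


def build_model(config: ModelConfig, seed: int = 0) -> MultiHeadResUNet:
    """Construct a seeded network from its configuration."""
    try:
        return MultiHeadResUNet(config, seed=seed)
    except ValueError as e:
        if isinstance(e, (ValidationError, ConfigurationError)):
            raise
        raise ConfigurationError(str(e)) from e


def describe(network: MultiHeadResUNet) -> dict:
    """Machine-readable architecture summary."""
    cfg = network.config
    f, fb = cfg.scaled_filters()
    param_names: dict[int, list[str]] = {}
    for name, p in network.named_parameters():
        param_names.setdefault(id(p), []).append(name)
    shared = sorted(names[0] for names in param_names.values() if len(names) > 1)
    if network.dwi_head_shared is not None:
        # one module object serving both dilated heads: its tensors are shared
        shared = sorted(set(shared) |
                        {n for n, _ in network.dwi_head_shared.named_parameters("dwi_head_shared")})
    heads = []
    if cfg.variant != "multichannel":
        labels = ["t2w_head", "dwi_head_shared" if network.dwi_head_shared else "dwi_head_d2",
                  "dwi_head_shared" if network.dwi_head_shared else "dwi_head_d4"]
        for (chans, dil), label in zip(network.wiring.heads, labels):
            heads.append({"channels": list(chans), "dilation": dil, "weights": label,
                          "shared": label == "dwi_head_shared"})
    return {
        "variant": cfg.variant,
        "input_channels": list(cfg.input_channels),
        "filters": f + [fb],
        "width_multiplier": cfg.width_multiplier,
        "heads": heads,
        "head_dilations": [d for _, d in network.wiring.heads] if heads else [],
        "fusion": network.wiring.fusion,
        "sharing": network.wiring.sharing,
        "shared_tensors": shared,
        "num_parameters": network.num_parameters(),
        "penultimate_layer": network.penultimate_layer,
    }


def save_checkpoint(network: MultiHeadResUNet, path: str | Path,
                    extra: dict | None = None) -> None:
    """Weights + config (+ training state) as a single .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": network.config.model_dump(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **network.state_dict())


def load_checkpoint(path: str | Path, seed: int = 0
                    ) -> tuple[MultiHeadResUNet, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    network = build_model(config, seed=seed)
    network.load_state_dict(state)
    return network, meta.get("extra", {})
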