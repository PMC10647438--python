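"""Apparent diffusion coefficient (ADC) fitting from DWI b-value series.

The signal model is mono-exponential decay, S_bi = S_b0 * exp(-b_i * D).
Two estimators are provided:

* a two-point fit, D = -(1/b) * ln(S_b / S_0), for the (b0, b1000)
  protocol;
* a closed-form log-linear least-squares fit over multiple b-values,

      D = -[N * sum(b_i ln S_i) - sum(b_i) sum(ln S_i)]
           / [N * sum(b_i^2) - (sum(b_i))^2]

  (the negated OLS slope of ln S against b), for protocols such as
  (b200, b600, b1000) that exclude the b=0 image.

D is stored in mm^2/s; any x1e-3 display scaling is presentation-only.
Voxels with non-positive signal are marked invalid and carry the fill
value rather than a clamped estimate; negative fitted D (noise-induced)
is retained unless ``clip_negative`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import GridMismatchError, ValidationError
from .grid import VolumeGrid


@dataclass
class DWISignalSeries:
    """One signal volume per b-value, all on a common grid."""

    b_values: tuple[float, ...]
    signals: list[VolumeGrid]

    def __post_init__(self):
        self.b_values = tuple(float(b) for b in self.b_values)
        if len(self.b_values) != len(self.signals):
            raise ValidationError("one signal volume per b-value required", field="signals")
        if any(b2 <= b1 for b1, b2 in zip(self.b_values, self.b_values[1:])):
            raise ValidationError("b_values must be strictly increasing", field="b_values")
        if any(b < 0 for b in self.b_values):
            raise ValidationError("b_values must be non-negative", field="b_values")
        ref = self.signals[0]
        for s in self.signals[1:]:
            ref.require_same_grid(s, what="signal volume")

    @property
    def N(self) -> int:
        return len(self.b_values)


@dataclass
class ADCMap:
    """Fitted diffusion coefficient map (mm^2/s) with its validity mask."""

    values: VolumeGrid
    fit_protocol: Literal["two_point", "loglinear"]
    valid_mask: np.ndarray = field(repr=False)
    fill_value: float = 0.0


def _finalize(d: np.ndarray, valid: np.ndarray, grid: VolumeGrid,
              protocol: str, fill_value: float, clip_negative: bool) -> ADCMap:
    d = np.where(valid, d, fill_value)
    if clip_negative:
        d = np.where(valid & (d < 0), 0.0, d)
    return ADCMap(values=grid.with_data(d), fit_protocol=protocol,  # type: ignore[arg-type]
                  valid_mask=valid, fill_value=fill_value)


def fit_adc_two_point(s0: VolumeGrid, sb: VolumeGrid, b: float,
                      fill_value: float = 0.0, clip_negative: bool = False) -> ADCMap:
    """Mono-exponential two-point fit: D = -(1/b) ln(S_b / S_0).

    ``b`` is the b-value difference between the two acquisitions (equal to
    the high b-value for the usual b=0 baseline).
    """
    if b <= 0:
        raise ValidationError("b must be > 0", field="b")
    if not s0.same_grid(sb):
        raise GridMismatchError(f"s0 {s0.shape}@{s0.spacing} vs sb {sb.shape}@{sb.spacing}")
    a0 = np.asarray(s0.data, dtype=np.float64)
    ab = np.asarray(sb.data, dtype=np.float64)
    valid = (a0 > 0) & (ab > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(np.where(valid, ab / a0, 1.0)) / b
    return _finalize(d, valid, s0, "two_point", fill_value, clip_negative)


def fit_adc_loglinear(series: DWISignalSeries, fill_value: float = 0.0,
                      clip_negative: bool = False) -> ADCMap:
    """Closed-form log-linear least-squares fit over all b-values in the
    series (the negated OLS slope of ln S on b).

    The customary multi-b protocol excludes the b=0 image; callers who
    want it included simply put it in the series.
    """
    if series.N < 2:
        raise ValidationError("at least two b-values required", field="series")
    b = np.asarray(series.b_values, dtype=np.float64)
    stack = np.stack([np.asarray(s.data, dtype=np.float64) for s in series.signals])
    valid = np.all(stack > 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(np.where(stack > 0, stack, 1.0))
    n = series.N
    sb, sb2 = b.sum(), (b * b).sum()
    s_l = logs.sum(axis=0)
    s_bl = np.tensordot(b, logs, axes=(0, 0))
    denom = n * sb2 - sb * sb
    d = -(n * s_bl - sb * s_l) / denom
    return _finalize(d, valid, series.signals[0], "loglinear", fill_value, clip_negative)


def fit_study_adc(signals: Sequence[VolumeGrid], b_values: Sequence[float],
                  protocol: Literal["two_point", "loglinear"] = "two_point",
                  **kwargs) -> ADCMap:
    """Convenience dispatcher used by the CLI."""
    b_values = [float(b) for b in b_values]
    if protocol == "two_point":
        if len(b_values) != 2:
            raise ValidationError("two_point needs exactly two b-values", field="b_values")
        return fit_adc_two_point(signals[0], signals[1], b_values[1] - b_values[0], **kwargs)
    return fit_adc_loglinear(DWISignalSeries(tuple(b_values), list(signals)), **kwargs)
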