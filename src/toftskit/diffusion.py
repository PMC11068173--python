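"""ADC mapping from multi-b-value diffusion-weighted images.

The signal is modeled as a monoexponential decay S(b) = S0·exp(−b·ADC).
The estimator is a weighted linear regression of ln S on b with weights
S², which mitigates the noise-amplification bias of the log transform at
high b. ADC is carried internally in mm²/s and reported in the
conventional 10⁻⁴ mm²/s units only at the summary stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridGeometry
from .pharmacokinetics import RoiSummary, summarize_roi

__all__ = ["DwiStack", "fit_adc", "summarize_adc"]

#: default protocol b-values, s/mm²
DEFAULT_B_VALUES = (0.0, 200.0, 400.0, 800.0, 1200.0)


@dataclass(frozen=True)
class DwiStack:
    """Per-b-value signal volumes; last axis of ``signals`` indexes b."""

    b_values: tuple[float, ...]
    signals: np.ndarray
    grid: GridGeometry = field(default_factory=GridGeometry)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if np.unique(b).size < 2:
            raise ValueError("need at least two distinct b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        sig = np.asarray(self.signals, dtype=float)
        if sig.shape[-1] != b.size:
            raise ValueError("last axis of signals must match the b-values")
        object.__setattr__(self, "signals", sig)


def fit_adc(stack: DwiStack, mask: np.ndarray | None = None,
            min_b: float = 0.0):
    """Voxelwise ADC and S0 by S²-weighted log-linear regression.

    Only b-values >= ``min_b`` enter the fit (raising ``min_b`` above 0
    excludes the perfusion-sensitive b = 0 image). Voxels with fewer
    than two positive signals are flagged invalid, not errored.

    Returns ``(adc, s0, valid)``; ADC in mm²/s.
    """
    b = np.asarray(stack.b_values, dtype=float)
    use = b >= min_b
    if use.sum() < 2:
        raise ValueError("min_b leaves fewer than two b-values")
    b = b[use]
    sig = stack.signals[..., use]
    shape = sig.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)

    pos = sig > 0
    w = np.where(pos, sig * sig, 0.0)
    y = np.where(pos, np.log(np.where(pos, sig, 1.0)), 0.0)

    sw = w.sum(axis=-1)
    enough = (pos.sum(axis=-1) >= 2) & mask
    with np.errstate(divide="ignore", invalid="ignore"):
        bw = (w * b).sum(axis=-1) / sw
        yw = (w * y).sum(axis=-1) / sw
        sxx = (w * (b - bw[..., None]) ** 2).sum(axis=-1)
        sxy = (w * (b - bw[..., None]) * (y - yw[..., None])).sum(axis=-1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    valid = enough & np.isfinite(slope) & (sxx > 0)
    adc = np.where(valid, -slope, np.nan)
    s0 = np.where(valid, np.exp(yw - slope * bw), np.nan)
    return adc, s0, valid


def summarize_adc(adc: np.ndarray, roi: np.ndarray,
                  valid: np.ndarray | None = None) -> RoiSummary:
    """ROI median (IQR) of an ADC map, reported in 10⁻⁴ mm²/s.

    The ×10⁴ unit conversion is applied exactly once, here.
    """
    s = summarize_roi(adc, roi, valid)
    if s.empty:
        return s
    return RoiSummary(s.median * 1e4, s.q1 * 1e4, s.q3 * 1e4,
                      s.n_total, s.n_valid)
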