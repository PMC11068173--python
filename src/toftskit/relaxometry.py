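"""SPGR relaxometry: VFA T1/M0 mapping and signal <-> concentration conversion.

The spoiled-gradient-echo (SPGR/FLASH) steady-state signal is

    S = M0 · sin(α) · (1 − E1) / (1 − E1 · cos(α)),   E1 = exp(−TR / T1).

Variable-flip-angle (VFA) T1 mapping inverts this by the classical
linearization S/sin(α) = E1 · S/tan(α) + M0·(1 − E1).

Contrast agent shortens T1 via fast-exchange linear relaxivity,
1/T1(t) = 1/T10 + r1·C(t) with rates in 1/s, which turns a dynamic SPGR
signal curve into a gadolinium concentration curve C(t) in mM. TE/T2*
effects are neglected (TE = 2 ms is short relative to tissue T2*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridGeometry

__all__ = [
    "AcquisitionParams",
    "RelaxometryConfig",
    "spgr_signal",
    "fit_t1_vfa",
    "concentration_from_signal",
    "signal_from_concentration",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence metadata shared by simulation and fitting.

    Defaults follow the small-animal protocol this package emulates:
    FLASH DCE at TR 20 ms / TE 2 ms / flip 25° with 0.6 s temporal
    resolution over 300 repetitions, VFA flip angles 5–70°, and DWI
    b-values 0–1200 s/mm².
    """

    tr_ms: float = 20.0
    te_ms: float = 2.0
    flip_angle_deg: float = 25.0
    vfa_angles_deg: tuple[float, ...] = (5.0, 15.0, 35.0, 45.0, 60.0, 70.0)
    temporal_resolution_s: float = 0.6
    n_frames: int = 300
    n_baseline: int = 50
    b_values: tuple[float, ...] = (0.0, 200.0, 400.0, 800.0, 1200.0)
    grid: GridGeometry = field(default_factory=GridGeometry)

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.temporal_resolution_s <= 0:
            raise ValueError("TR and temporal resolution must be positive")
        if len(self.vfa_angles_deg) < 2:
            raise ValueError("VFA needs at least two flip angles")
        if self.n_baseline < 1:
            raise ValueError("at least one pre-bolus baseline frame is required")
        if self.n_frames < self.n_baseline:
            raise ValueError("n_frames must be >= n_baseline")

    def times_s(self) -> np.ndarray:
        """DCE frame times in seconds, first frame at t = 0."""
        return np.arange(self.n_frames) * self.temporal_resolution_s


@dataclass(frozen=True)
class RelaxometryConfig:
    """Contrast-agent relaxivity and conversion assumptions.

    r1 defaults to 3.5 /mM/s, a 7 T literature value for gadoterate; the
    linear fast-water-exchange relationship 1/T1 = 1/T10 + r1·C is assumed.
    """

    r1: float = 3.5  # longitudinal relaxivity, 1/mM/s
    neglect_te: bool = True

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be positive")


def spgr_signal(m0, t1_ms, flip_angle_deg, tr_ms):
    """SPGR steady-state signal; accepts scalars or broadcastable arrays.

    S = M0·sinα·(1−E1)/(1−E1·cosα), E1 = exp(−TR/T1); S ∈ [0, M0].
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    alpha = np.deg2rad(flip_angle_deg)
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(alpha) > np.pi / 2):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    e1 = np.exp(-tr_ms / t1)
    return np.asarray(m0) * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def fit_t1_vfa(signals: np.ndarray, angles_deg, tr_ms: float):
    """VFA T1/M0 mapping by the linearized SPGR fit.

    Parameters
    ----------
    signals : array, last axis indexes flip angles.
    angles_deg : flip angles matching the last axis; >= 2 distinct values.
    tr_ms : repetition time in ms.

    Returns
    -------
    (t1_ms, m0, valid) — voxels whose fitted E1 slope falls outside (0, 1)
    (including all-zero voxels) are flagged invalid instead of raising.
    """
    sig = np.asarray(signals, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim != 1 or np.unique(angles).size < 2:
        raise ValueError("need at least two distinct flip angles")
    if sig.shape[-1] != angles.size:
        raise ValueError("last axis of signals must match the number of angles")
    if np.any(sig < 0):
        raise ValueError("signals must be nonnegative")

    alpha = np.deg2rad(angles)
    y = sig / np.sin(alpha)
    x = sig / np.tan(alpha)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=-1)
    sxy = ((x - xm) * (y - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    intercept = ym[..., 0] - slope * xm[..., 0]

    # a perfectly angle-independent signal has no SPGR solution
    degenerate = np.ptp(sig, axis=-1) == 0
    valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -tr_ms / np.log(np.where(valid, slope, 0.5)), np.nan)
        m0 = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)), np.nan)
    valid = valid & np.isfinite(m0) & (m0 > 0)
    return t1, m0, valid


def _invert_spgr_e1(signal, m0, alpha):
    """Solve S = M0·sinα(1−E1)/(1−E1·cosα) for E1."""
    s_sat = m0 * np.sin(alpha)  # supremum of attainable signal (T1 -> 0)
    num = s_sat - signal
    den = s_sat - signal * np.cos(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den, s_sat


def concentration_from_signal(
    signal: np.ndarray,
    n_baseline: int,
    t10_ms,
    config: RelaxometryConfig,
    acq: AcquisitionParams,
):
    """Convert a dynamic SPGR signal curve to gadolinium concentration (mM).

    The mean of the first ``n_baseline`` (pre-bolus) frames fixes M0 by
    SPGR inversion at the DCE flip angle and the supplied T10; each frame
    is then inverted for T1(t) and C(t) = (1/T1(t) − 1/T10)/r1 with rates
    in 1/s. Frames whose signal meets or exceeds the SPGR-attainable
    maximum M0·sinα are clamped to it (minus a small epsilon) and flagged.

    Returns ``(conc, clamped)`` where ``clamped`` marks clamped frames.
    Last axis of ``signal`` is time.
    """
    sig = np.asarray(signal, dtype=float)
    t10 = np.asarray(t10_ms, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("T10 must be positive")
    if not (1 <= n_baseline <= sig.shape[-1]):
        raise ValueError("n_baseline must lie within the time axis")

    alpha = np.deg2rad(acq.flip_angle_deg)
    e10 = np.exp(-acq.tr_ms / t10)
    base = sig[..., :n_baseline].mean(axis=-1)
    # M0 from baseline signal at known T10
    m0 = base * (1.0 - e10 * np.cos(alpha)) / (np.sin(alpha) * (1.0 - e10))

    e1, s_sat = _invert_spgr_e1(sig, m0[..., None], alpha)
    clamped = sig >= s_sat * (1.0 - 1e-12)
    eps = 1e-12
    e1 = np.clip(e1, eps, 1.0 - eps)
    t1_t = -acq.tr_ms / np.log(e1)  # ms
    r1_t = 1000.0 / t1_t  # 1/s
    r10 = 1000.0 / t10
    conc = (r1_t - r10[..., None]) / config.r1
    return conc, clamped


def signal_from_concentration(
    conc: np.ndarray,
    t10_ms,
    m0,
    config: RelaxometryConfig,
    acq: AcquisitionParams,
):
    """Forward model: concentration curve (mM) to SPGR signal curve.

    Exact inverse of :func:`concentration_from_signal`:
    1/T1(t) = 1/T10 + r1·C(t) with rates in 1/s. Last axis is time.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    t10 = np.asarray(t10_ms, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("T10 must be positive")
    r1_t = 1000.0 / t10[..., None] + config.r1 * c  # 1/s
    t1_t = 1000.0 / r1_t  # ms
    return spgr_signal(np.asarray(m0)[..., None], t1_t, acq.flip_angle_deg, acq.tr_ms)
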