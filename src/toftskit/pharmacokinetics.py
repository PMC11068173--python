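"""Extended Tofts model: forward curves, voxelwise fitting, and filters.

The extended Tofts model describes the tissue contrast-agent
concentration as a plasma term plus transendothelial exchange:

    Ct(t) = vp·Cp(t) + Ktrans · ∫_0^t Cp(τ) · exp[−(Ktrans/ve)·(t−τ)] dτ

with Ktrans the volume transfer constant (1/min), ve the
extravascular–extracellular volume fraction, vp the plasma volume
fraction, and kep = Ktrans/ve the efflux rate constant. For a
sum-of-exponentials AIF the convolution has a closed form, used both to
simulate and to fit; a trapezoidal numeric path covers tabulated AIFs.

Voxels whose fit lands on non-physiological values (Ktrans < 0.01 1/min,
Ktrans > 5 1/min, or ve > 1) are eliminated from all downstream
summaries rather than being clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .aif import AIFModel

__all__ = [
    "TissueCurve",
    "VoxelFitResult",
    "FilterRules",
    "RoiSummary",
    "tofts_ct",
    "tofts_ct_numeric",
    "fit_tofts_voxel",
    "fit_tofts_map",
    "compute_kep",
    "apply_physio_filter",
    "summarize_roi",
]

logger = logging.getLogger(__name__)

#: default optimizer start and fallback multi-start (Ktrans, ve, vp)
_INIT = (0.1, 0.3, 0.05)
_INIT_FALLBACK = (1.0, 0.5, 0.1)
_LOWER = (0.0, 1e-6, 0.0)
_UPPER = (5.0, 1.0, 1.0 - 1e-6)


@dataclass(frozen=True)
class TissueCurve:
    """A tissue concentration curve Ct(t): time in minutes from zero, mM."""

    t_min: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        c = np.asarray(self.ct, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time axis and Ct must be 1-D and equal length")
        if t[0] != 0:
            raise ValueError("time axis must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "ct", c)


@dataclass(frozen=True)
class FilterRules:
    """Physiological plausibility bounds on the fitted parameters."""

    ktrans_min: float = 0.01  # 1/min
    ktrans_max: float = 5.0  # 1/min
    ve_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.ktrans_min < self.ktrans_max:
            raise ValueError("ktrans_min must be below ktrans_max")
        if self.ve_max > 1.0:
            raise ValueError(
                "ve_max above 1 is non-physiological: ve is a volume "
                "fraction and voxels with ve > 1 are eliminated"
            )


@dataclass(frozen=True)
class VoxelFitResult:
    ktrans: float  # 1/min
    ve: float  # fraction
    vp: float  # fraction
    kep: float  # 1/min, Ktrans/ve
    rss: float
    converged: bool
    valid: bool


@dataclass(frozen=True)
class RoiSummary:
    """Median (Q1, Q3) over the valid voxels of an ROI."""

    median: float
    q1: float
    q3: float
    n_total: int
    n_valid: int

    @property
    def empty(self) -> bool:
        return self.n_valid == 0


def tofts_ct(ktrans, ve, vp, aif: AIFModel, t_min) -> np.ndarray:
    """Extended Tofts tissue curve, closed form for an exponential-sum AIF.

    Parameters may be scalars or broadcastable arrays of shape ``P``;
    ``t_min`` is a 1-D time axis in minutes. Returns shape ``P + (nt,)``.
    Requires ve > 0 wherever Ktrans > 0 (kep would be undefined).
    """
    kt = np.asarray(ktrans, dtype=float)
    ve_ = np.asarray(ve, dtype=float)
    vp_ = np.asarray(vp, dtype=float)
    t = np.asarray(t_min, dtype=float)
    if np.any(kt < 0):
        raise ValueError("Ktrans must be nonnegative")
    if np.any((kt > 0) & (ve_ <= 0)):
        raise ValueError("ve must be positive where Ktrans > 0")
    if np.any((vp_ < 0) | (vp_ >= 1)):
        raise ValueError("vp must lie in [0, 1)")

    kt, ve_, vp_ = np.broadcast_arrays(kt, ve_, vp_)
    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(ve_ > 0, kt / np.where(ve_ > 0, ve_, 1.0), 0.0)

    u = t - aif.t0_min
    post = u >= 0
    up = np.where(post, u, 0.0)

    cp = aif.cp(t)
    ct = vp_[..., None] * cp

    kep_b = kep[..., None]
    e_kep = np.exp(-kep_b * up)
    for a, m in zip(aif.amplitudes, aif.rates):
        diff = kep_b - m
        near = np.abs(diff) < 1e-12
        safe = np.where(near, 1.0, diff)
        term = np.where(
            near,
            up * np.exp(-kep_b * up),
            (np.exp(-m * up) - e_kep) / safe,
        )
        ct = ct + kt[..., None] * aif.dose * a * np.where(post, term, 0.0)
    return ct


def tofts_ct_numeric(ktrans: float, ve: float, vp: float,
                     cp: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Trapezoidal evaluation of the Tofts convolution for a tabulated AIF.

    O(n²) in the number of time points; serves as the fallback for AIFs
    given only as samples and as the cross-check for the analytic path.
    """
    t = np.asarray(t_min, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if ktrans < 0:
        raise ValueError("Ktrans must be nonnegative")
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be positive where Ktrans > 0")
    kep = ktrans / ve if ktrans > 0 else 0.0
    # integrand at time t_i: Cp(τ)·exp(−kep·(t_i − τ)) on τ ∈ [0, t_i]
    ct = np.empty_like(t)
    for i, ti in enumerate(t):
        integrand = cp[: i + 1] * np.exp(-kep * (ti - t[: i + 1]))
        ct[i] = np.trapezoid(integrand, t[: i + 1]) if i > 0 else 0.0
    return vp * cp + ktrans * ct


def fit_tofts_voxel(
    curve: TissueCurve,
    aif: AIFModel,
    init: tuple[float, float, float] = _INIT,
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] = (_LOWER, _UPPER),
    rules: FilterRules | None = None,
) -> VoxelFitResult:
    """Bounded trust-region least-squares fit of one tissue curve.

    Fits (Ktrans, ve, vp) by minimizing the residual of :func:`tofts_ct`
    against the curve; kep is derived as Ktrans/ve. On non-convergence a
    single multi-start fallback at (1.0, 0.5, 0.1) is tried. The result
    is deterministic for identical inputs. Physiological filter rules
    (default: the standard elimination bounds) set the validity flag.
    """
    t = curve.t_min
    if t.size < 10:
        raise ValueError("need at least 10 time points to fit")
    y = curve.ct
    rules = rules if rules is not None else FilterRules()

    def resid(p):
        return tofts_ct(p[0], p[1], p[2], aif, t) - y

    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)

    def run(x0):
        x0 = np.clip(np.asarray(x0, float), lo, hi)
        return least_squares(resid, x0, bounds=(lo, hi), method="trf",
                             xtol=1e-12, ftol=1e-12, gtol=1e-12)

    res = run(init)
    if not res.success:
        res = run(_INIT_FALLBACK)
    kt, ve, vp = (float(v) for v in res.x)
    kep = kt / ve if ve > 0 else float("nan")
    rss = float(2.0 * res.cost)
    converged = bool(res.success)
    filtered = kt < rules.ktrans_min or kt > rules.ktrans_max or ve > rules.ve_max
    return VoxelFitResult(kt, ve, vp, kep, rss, converged,
                          valid=converged and not filtered)


def fit_tofts_map(
    conc: np.ndarray,
    t_min: np.ndarray,
    aif: AIFModel,
    mask: np.ndarray,
    rules: FilterRules | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Voxelwise extended Tofts fit over a masked 4-D concentration series.

    Parameters
    ----------
    conc : 4-D array (x, y, z, t) of tissue concentration in mM.
    t_min : time axis in minutes, starting at 0.
    aif : population AIF.
    mask : boolean 3-D mask of voxels to fit; must be nonempty.

    Returns
    -------
    (maps, valid) — ``maps`` holds 'Ktrans', 'Ve', 'Vp', 'Kep' (NaN
    outside the mask), ``valid`` marks masked voxels that converged and
    passed the physiological filter. Fitted/filtered counts are logged.
    """
    conc = np.asarray(conc, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if conc.ndim != 4:
        raise ValueError("concentration series must be 4-D (x, y, z, t)")
    if mask.shape != conc.shape[:3]:
        raise ValueError("mask shape must match the spatial grid")
    if not mask.any():
        raise ValueError("mask is empty: nothing to fit")
    rules = rules if rules is not None else FilterRules()

    shape = conc.shape[:3]
    maps = {k: np.full(shape, np.nan) for k in ("Ktrans", "Ve", "Vp", "Kep")}
    valid = np.zeros(shape, dtype=bool)
    n_fail = 0
    idx = np.argwhere(mask)
    for i, j, k in idx:
        curve = TissueCurve(t_min, conc[i, j, k])
        r = fit_tofts_voxel(curve, aif, rules=rules)
        maps["Ktrans"][i, j, k] = r.ktrans
        maps["Ve"][i, j, k] = r.ve
        maps["Vp"][i, j, k] = r.vp
        maps["Kep"][i, j, k] = r.kep
        valid[i, j, k] = r.valid
        n_fail += not r.converged
    physio = apply_physio_filter(maps, rules)
    valid &= physio
    n_masked = int(mask.sum())
    n_valid = int(valid.sum())
    logger.info(
        "tofts map fit: %d voxels fitted, %d valid, %d filtered, %d non-converged",
        n_masked, n_valid, n_masked - n_valid, n_fail,
    )
    return maps, valid


def compute_kep(ktrans: np.ndarray, ve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Efflux rate map kep = Ktrans/ve, elementwise.

    Voxels with ve <= 0 are flagged invalid (NaN in the map) instead of
    producing infinities. Returns ``(kep, valid)``.
    """
    kt = np.asarray(ktrans, dtype=float)
    ve_ = np.asarray(ve, dtype=float)
    if kt.shape != ve_.shape:
        raise ValueError("Ktrans and Ve maps must share a grid")
    valid = np.isfinite(kt) & np.isfinite(ve_) & (ve_ > 0)
    kep = np.full(kt.shape, np.nan)
    kep[valid] = kt[valid] / ve_[valid]
    return kep, valid


def apply_physio_filter(maps: dict[str, np.ndarray], rules: FilterRules) -> np.ndarray:
    """Validity mask: voxel invalid iff any plausibility rule fires.

    Rules: Ktrans below ``ktrans_min``, Ktrans above ``ktrans_max``, or
    ve above ``ve_max``. Idempotent — the mask depends only on the maps.
    """
    kt = np.asarray(maps["Ktrans"], dtype=float)
    ve = np.asarray(maps["Ve"], dtype=float)
    ok = np.isfinite(kt) & np.isfinite(ve)
    ok &= (kt >= rules.ktrans_min) & (kt <= rules.ktrans_max) & (ve <= rules.ve_max)
    return ok


def summarize_roi(map_: np.ndarray, roi: np.ndarray,
                  valid: np.ndarray | None = None) -> RoiSummary:
    """Median and IQR of a parameter map over ROI ∩ valid voxels.

    Quantiles use linear interpolation. If every ROI voxel is filtered
    out the summary is explicitly empty (NaN statistics, n_valid = 0).
    """
    m = np.asarray(map_, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != m.shape:
        raise ValueError("ROI mask must share the map's grid")
    if valid is None:
        valid = np.isfinite(m)
    elif valid.shape != m.shape:
        raise ValueError("validity mask must share the map's grid")
    sel = roi & valid & np.isfinite(m)
    n_total = int(roi.sum())
    n_valid = int(sel.sum())
    if n_valid == 0:
        return RoiSummary(float("nan"), float("nan"), float("nan"), n_total, 0)
    vals = m[sel]
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    return RoiSummary(float(med), float(q1), float(q3), n_total, n_valid)
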