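"""Population arterial input function (AIF).

A single fixed plasma concentration curve Cp(t) drives the kinetic model
for every subject ("population-based" AIF). The parametric form is a
dose-scaled sum of decaying exponentials with a bolus-arrival time t0:

    Cp(t) = D · Σ_i  a_i · exp(−m_i · (t − t0))   for t >= t0,  else 0

with D the injected dose in mmol/kg, amplitudes a_i in kg/L (so Cp is in
mM) and decay rates m_i in 1/min. The default amplitudes and rates are
Weinmann-type surrogate values for a gadoterate bolus; they are not
measured mouse values and every field is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AIFModel", "sample_aif"]

#: Weinmann biexponential surrogate: amplitudes kg/L, rates 1/min.
_DEFAULT_AMPLITUDES = (3.99, 4.78)
_DEFAULT_RATES = (0.144, 0.0111)


@dataclass(frozen=True)
class AIFModel:
    """Sum-of-exponentials plasma concentration function Cp(t).

    Parameters
    ----------
    dose : injected contrast dose, mmol/kg (default 0.1, gadoterate).
    amplitudes : a_i terms, kg/L.
    rates : m_i decay rates, 1/min; all must be >= 0.
    t0_s : bolus arrival time in seconds on the acquisition clock.
    """

    dose: float = 0.1
    amplitudes: tuple[float, ...] = field(default=_DEFAULT_AMPLITUDES)
    rates: tuple[float, ...] = field(default=_DEFAULT_RATES)
    t0_s: float = 60.0

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.rates):
            raise ValueError("amplitudes and rates must have equal length")
        if any(m < 0 for m in self.rates):
            raise ValueError("decay rates must be nonnegative")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be nonnegative")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")

    @property
    def t0_min(self) -> float:
        return self.t0_s / 60.0

    def cp(self, t_min: np.ndarray | float) -> np.ndarray:
        """Plasma concentration (mM) at times given in minutes."""
        t = np.asarray(t_min, dtype=float)
        u = t - self.t0_min
        out = np.zeros_like(u)
        post = u >= 0
        for a, m in zip(self.amplitudes, self.rates):
            out = out + np.where(post, a * np.exp(-m * np.where(post, u, 0.0)), 0.0)
        return self.dose * out


def sample_aif(aif: AIFModel, times_s: np.ndarray) -> np.ndarray:
    """Evaluate Cp (mM) on a time axis given in seconds.

    Times must be nonnegative and strictly increasing; the curve is zero
    before the bolus-arrival time and continuous afterwards.
    """
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return aif.cp(t / 60.0)
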