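"""CO₂ concentration-decay air exchange estimation (the reference method).

After a room is charged with CO₂ and the source removed, a well-mixed zone
at air exchange rate λ decays as C(t) = background + (C₀ − background)·e^(−λt),
so λ is minus the slope of ln(C − background) against time.  Background is
an explicit required input (ambient handling is the operator's call; 400
ppm is a typical outdoor value but is never applied silently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = ["DecaySeries", "decay_air_exchange_rate", "compare_methods"]


@dataclass(frozen=True)
class DecaySeries:
    """CO₂ decay record: times (h), concentrations (ppm), baseline (ppm)."""

    times: np.ndarray
    concentrations: np.ndarray
    background: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("times and concentrations must be 1-D, equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if c[0] <= self.background:
            raise ValueError("initial concentration must exceed background")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def decay_air_exchange_rate(series: DecaySeries, *, two_point: bool = False) -> dict:
    """Air exchange rate (h⁻¹) from a CO₂ decay series.

    Default: least-squares regression of ln(C − background) on time over all
    points above background; points at or below background are excluded and
    counted.  ``two_point=True`` uses only the first and last usable points
    (ln-ratio over elapsed time), flagged in the output.

    Returns a dict with ``rate_per_h``, ``r_squared``, ``n_used``,
    ``n_excluded`` and ``mode``.
    """
    excess = series.concentrations - series.background
    usable = excess > 0
    n_excluded = int((~usable).sum())
    t = series.times[usable]
    y = np.log(excess[usable])
    if t.size < 3:
        raise ValueError(
            f"need >= 3 points above background, have {t.size} "
            f"({n_excluded} at or below background)"
        )
    if two_point:
        rate = -(y[-1] - y[0]) / (t[-1] - t[0])
        return {
            "rate_per_h": float(rate),
            "r_squared": None,
            "n_used": 2,
            "n_excluded": n_excluded,
            "mode": "two_point",
        }
    fit = scipy.stats.linregress(t, y)
    return {
        "rate_per_h": float(-fit.slope),
        "r_squared": float(fit.rvalue**2) if np.std(y) > 0 else 1.0,
        "n_used": int(t.size),
        "n_excluded": n_excluded,
        "mode": "regression",
    }


def compare_methods(pft_rate: float, decay_rate: float) -> float:
    """Relative difference (%) of a tracer-derived rate vs the decay rate.

    100 × (pft_rate − decay_rate) / decay_rate; positive means the tracer
    method reads high relative to the reference.
    """
    if decay_rate <= 0:
        raise ValueError("decay_rate must be > 0")
    return 100.0 * (pft_rate - decay_rate) / decay_rate
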