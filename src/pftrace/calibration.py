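"""Passive-sampler and doser calibration computations.

Covers the full calibration chain for a perfluorocarbon-tracer survey:
solvent-extraction recovery efficiency, passive sampling rate from chamber
exposures, analytical limits of detection/quantification (3σ / 10σ of the
blank), their conversion to 24-h air limits, concentration from a sampler
extract, gravimetric dosing rate, and the exponential temperature model of
the dosing rate.

Unit conventions: analytical limits and extract concentrations in µg/mL,
air concentrations in µg/m³ (1 µg/mL = 1e6 µg/m³), sampling rates in
mL/min, dosing rates in mg/h, sampling durations in minutes.

Note an asymmetry that is deliberate: :func:`air_limit_24h` by default does
*not* correct for recovery (so reported limits describe what the analysis
chain can see in the extract), while :func:`concentration_from_sampler`
*does* divide by recovery (otherwise air concentrations are biased low by
the unrecovered fraction, 16–60 % for the tracers used here).  A
recovery-corrected limit mode is available as the conservative variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "CalibrationSet",
    "GravimetrySeries",
    "SamplerResult",
    "recovery_efficiency",
    "sampling_rate",
    "analytical_limits",
    "air_limit_24h",
    "concentration_from_sampler",
    "dosing_rate_from_gravimetry",
    "fit_temperature_model",
]

#: µg/mL → µg/m³ (1 m³ = 1e6 mL)
_UGML_TO_UGM3 = 1e6


@dataclass(frozen=True)
class CalibrationSet:
    """Per-tracer calibration constants.

    recovery is the solvent-extraction recovery fraction in [0, 1];
    sampling_rate is the passive uptake rate in mL/min; analytical limits
    are in µg/mL of extract; extract_volume defaults to 1.0 mL.
    """

    tracer_id: str
    recovery: float
    sampling_rate: float
    analytical_lod: float
    analytical_loq: float
    recovery_sd: float = 0.0
    sampling_rate_sd: float = 0.0
    blank_sd: float | None = None
    extract_volume: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.recovery <= 1:
            raise ValueError(f"recovery must be in (0, 1], got {self.recovery}")
        for name in ("sampling_rate", "analytical_lod", "analytical_loq",
                     "extract_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GravimetrySeries:
    """Doser weights over time: times in h since start, weights in mg."""

    times: np.ndarray
    weights: np.ndarray
    temperature: float | None = None  # °C

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.shape != w.shape or t.ndim != 1:
            raise ValueError("times and weights must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("need >= 3 points for a slope with diagnostics")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class SamplerResult:
    """Mass found in one sampler extract, with its calibration reference."""

    tracer_id: str
    zone: int
    extracted_mass: float  # µg in the extract
    duration: float  # min
    calibration: CalibrationSet

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.extracted_mass < 0:
            raise ValueError("extracted_mass must be >= 0")


def recovery_efficiency(
    spiked_mass: float, measured_masses: Sequence[float]
) -> tuple[float, float]:
    """Mean recovery fraction and sample SD from spiked-cartridge replicates.

    Each replicate's recovery is measured/spiked; needs >= 2 replicates.
    """
    if spiked_mass <= 0:
        raise ValueError("spiked_mass must be > 0")
    m = np.asarray(measured_masses, dtype=float)
    if m.size < 2:
        raise ValueError("need >= 2 replicates for a mean and SD")
    if np.any(m < 0):
        raise ValueError("measured masses must be >= 0")
    fractions = m / spiked_mass
    return float(fractions.mean()), float(fractions.std(ddof=1))


def sampling_rate(
    adsorbed_mass: float, chamber_concentration: float, duration: float
) -> float:
    """Passive sampling rate (mL/min) from a chamber exposure.

    SR = adsorbed mass / (chamber concentration × exposure time), i.e. the
    equivalent air volume drawn per minute.  ``chamber_concentration`` is
    in µg/m³ (converted internally to µg/mL), duration in minutes.
    """
    if adsorbed_mass <= 0 or duration <= 0:
        raise ValueError("adsorbed_mass and duration must be > 0")
    if chamber_concentration <= 0:
        raise ValueError("chamber concentration must be > 0")
    c_ugml = chamber_concentration / _UGML_TO_UGM3
    return adsorbed_mass / (c_ugml * duration)


def analytical_limits(blank_sd: float) -> tuple[float, float]:
    """Analytical LOD and LOQ (µg/mL) from the blank SD: 3σ and 10σ."""
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    return 3.0 * blank_sd, 10.0 * blank_sd


def air_limit_24h(
    analytical_limit: float,
    extract_volume: float,
    sampling_rate: float,
    duration: float,
    *,
    recovery: float | None = None,
) -> float:
    """Air-concentration limit (µg/m³) equivalent to an analytical limit.

    The smallest air concentration whose sampled-and-extracted mass reaches
    ``analytical_limit`` (µg/mL) in ``extract_volume`` mL of extract after
    passive sampling at ``sampling_rate`` mL/min for ``duration`` min:

        limit_air = analytical_limit × extract_volume / (SR × t)

    rescaled to µg/m³.  Pass ``recovery`` for the conservative
    recovery-corrected variant (divides by the recovery fraction, raising
    the limit); the default reports the uncorrected extract-side limit.
    """
    if min(analytical_limit, extract_volume, sampling_rate, duration) <= 0:
        raise ValueError("all inputs must be > 0")
    limit = analytical_limit * extract_volume / (sampling_rate * duration)
    if recovery is not None:
        if not 0 < recovery <= 1:
            raise ValueError("recovery must be in (0, 1]")
        limit /= recovery
    return limit * _UGML_TO_UGM3


def concentration_from_sampler(result: SamplerResult) -> float:
    """Air concentration (µg/m³) from a sampler extract mass.

    C = extracted_mass / (recovery × SR × duration), recovery-corrected so
    the unrecovered fraction does not bias the concentration low.
    """
    cal = result.calibration
    if cal.recovery <= 0:
        raise ValueError("recovery must be > 0 to correct a sampler mass")
    c_ugml = result.extracted_mass / (
        cal.recovery * cal.sampling_rate * result.duration
    )
    return c_ugml * _UGML_TO_UGM3


def dosing_rate_from_gravimetry(series: GravimetrySeries) -> dict:
    """Dosing rate (mg/h) as the OLS slope of cumulative weight loss vs time.

    Returns the rate, the standard error of the slope, the R² of the fit,
    and flags: ``negative_slope`` if the fitted release rate is negative,
    and a warning when cumulative release decreases beyond the noise
    suggested by the fit residuals.
    """
    released = series.weights[0] - series.weights  # cumulative emission, mg
    fit = scipy.stats.linregress(series.times, released)
    rate = float(fit.slope)
    # robust per-interval noise scale: a doser handling artefact (apparent
    # weight gain) would inflate an SD-based estimate and mask itself
    diffs = np.diff(released)
    mad = float(np.median(np.abs(diffs - np.median(diffs))))
    noise_scale = max(3.0 * 1.4826 * mad, 1e-9)
    out = {
        "rate_mg_per_h": rate,
        "rate_se": float(fit.stderr),
        "r_squared": float(fit.rvalue**2) if np.std(released) > 0 else 1.0,
        "negative_slope": rate < 0,
        "n_points": series.times.size,
        "temperature_c": series.temperature,
    }
    drops = diffs < -noise_scale
    if np.any(drops):
        out["warning"] = (
            f"cumulative release decreased beyond noise at "
            f"{int(drops.sum())} interval(s); check for doser handling artefacts"
        )
        warnings.warn(out["warning"], stacklevel=2)
    return out


def fit_temperature_model(
    temperatures: Sequence[float], rates: Sequence[float]
) -> dict:
    """Fit the exponential dosing-rate model R(T) = a·exp(b·T).

    Log-linear least squares: ln R = ln a + b·T.  Returns a (mg/h at 0 °C),
    b (1/°C) and the R² of the log fit.  Rates must be strictly positive.
    """
    T = np.asarray(temperatures, dtype=float)
    R = np.asarray(rates, dtype=float)
    if T.shape != R.shape or T.ndim != 1:
        raise ValueError("temperatures and rates must be 1-D and equal length")
    if np.unique(T).size < 2:
        raise ValueError("need >= 2 distinct temperatures")
    if np.any(R <= 0):
        raise ValueError("all rates must be > 0 (log fit)")
    logR = np.log(R)
    fit = scipy.stats.linregress(T, logR)
    return {
        "a": float(np.exp(fit.intercept)),
        "b": float(fit.slope),
        "r_squared": float(fit.rvalue**2) if np.std(logR) > 0 else 1.0,
    }
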