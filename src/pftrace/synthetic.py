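"""Synthetic-survey generator: every input the pipeline consumes.

Emulates a three-zone residential tracer survey — one tracer per room,
four passive dosers per room, 24-h passive sampling at the room centre —
plus doser gravimetry series and CO₂ decay series, so the whole pipeline
is testable without field data.

Noise models: concentrations get mean-preserving multiplicative lognormal
noise (they are positive and passive-sampler errors scale with level);
doser weights and CO₂ readings get additive Gaussian noise
(instrument-dominated).  A single scenario seed fans out to independent
per-stream sub-seeds via :class:`numpy.random.SeedSequence`, so adding a
stream never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationSet, GravimetrySeries, SamplerResult
from .decay import DecaySeries
from .inversion import SurveyMeasurement
from .model import (
    ConcentrationMatrix,
    FlowMatrix,
    TracerSpec,
    ZoneSystem,
    steady_state_concentrations,
)

__all__ = [
    "SurveyScenario",
    "default_zone_system",
    "default_tracers",
    "default_calibrations",
    "generate_balanced_flows",
    "simulate_survey",
    "simulate_gravimetry",
    "simulate_decay",
]

# Reference three-room dwelling: dining room & kitchen 13.2 m², Japanese
# room 10.7 m², bedroom 9.9 m², all 2.2 m high.
_DEFAULT_AREAS_M2 = (13.2, 10.7, 9.9)
_CEILING_M = 2.2
_DEFAULT_LABELS = ("dining_kitchen", "japanese_room", "bedroom")

# Tracer set with measured 25 °C dosing rates (mg/h per doser), four
# dosers per room, and the corresponding sampler calibrations.
_DEFAULT_DOSING_MG_H = {"HxFBz": 0.23, "OFT": 0.082, "PFABz": 0.015}
_N_DOSERS = 4
_DEFAULT_CAL = {
    # tracer: (recovery, recovery_sd, SR mL/min, SR sd, LOD, LOQ µg/mL)
    "HxFBz": (0.40, 0.03, 10.5, 1.1, 0.0030, 0.010),
    "OFT": (0.72, 0.05, 14.4, 1.4, 0.0036, 0.012),
    "PFABz": (0.84, 0.06, 12.2, 0.49, 0.0045, 0.015),
}


def default_zone_system() -> ZoneSystem:
    """The reference three-room dwelling (volumes 29.04/23.54/21.78 m³)."""
    vols = np.array(_DEFAULT_AREAS_M2) * _CEILING_M
    return ZoneSystem(volumes=vols, labels=_DEFAULT_LABELS)


def default_tracers() -> tuple[TracerSpec, ...]:
    """One tracer per room, four dosers each, dosing rates in µg/h."""
    return tuple(
        TracerSpec(
            tracer_id=tid,
            source_zone=z,
            dosing_rate=rate_mg_h * _N_DOSERS * 1000.0,  # mg/h → µg/h, ×4 dosers
            n_dosers=_N_DOSERS,
        )
        for z, (tid, rate_mg_h) in enumerate(_DEFAULT_DOSING_MG_H.items(), start=1)
    )


def default_calibrations() -> dict[str, CalibrationSet]:
    return {
        tid: CalibrationSet(
            tracer_id=tid,
            recovery=rec,
            recovery_sd=rec_sd,
            sampling_rate=sr,
            sampling_rate_sd=sr_sd,
            analytical_lod=lod,
            analytical_loq=loq,
        )
        for tid, (rec, rec_sd, sr, sr_sd, lod, loq) in _DEFAULT_CAL.items()
    }


@dataclass(frozen=True)
class SurveyScenario:
    """Complete recipe for one synthetic survey day."""

    zones: ZoneSystem
    true_flows: FlowMatrix
    tracers: tuple[TracerSpec, ...]
    sampling_duration: float = 1440.0  # min (24 h)
    concentration_cv: float = 0.05
    dosing_cv: float = 0.0
    seed: int = 0
    day_label: str = "day1"
    calibrations: dict[str, CalibrationSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concentration_cv < 0 or self.dosing_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not self.true_flows.is_balanced(tol=1e-6):
            raise ValueError("true_flows must be balanced")
        if not self.calibrations:
            object.__setattr__(self, "calibrations", default_calibrations())


def generate_balanced_flows(
    n_zones: int,
    flow_range: tuple[float, float] = (1.0, 100.0),
    seed: int | None = None,
    *,
    max_redraws: int = 1000,
) -> FlowMatrix:
    """Random airflow field satisfying per-zone air closure exactly.

    Exhausts Q[i,0] and inter-room flows Q[i,j] are drawn uniformly from
    ``flow_range``; infiltrations Q[0,i] are then fixed by closure
    (Q[0,i] = total outflow of i − indoor inflow to i) and the draw is
    repeated if any infiltration would be negative.
    """
    lo, hi = flow_range
    if lo < 0 or hi <= lo:
        raise ValueError("flow_range must be positive with hi > lo")
    rng = np.random.default_rng(seed)
    n = n_zones
    for _ in range(max_redraws):
        Q = np.zeros((n + 1, n + 1))
        Q[1:, 0] = rng.uniform(lo, hi, size=n)
        inter = rng.uniform(lo, hi, size=(n, n))
        np.fill_diagonal(inter, 0.0)
        Q[1:, 1:] = inter
        outflow = Q[1:, :].sum(axis=1)
        indoor_inflow = Q[1:, 1:].sum(axis=0)
        infil = outflow - indoor_inflow
        if np.all(infil >= 0):
            Q[0, 1:] = infil
            return FlowMatrix(Q=Q)
    raise RuntimeError(
        f"could not draw a balanced flow field with nonnegative infiltration "
        f"in {max_redraws} attempts for flow_range {flow_range}"
    )


def simulate_survey(
    scenario: SurveyScenario, *, return_samplers: bool = False
) -> SurveyMeasurement | tuple[SurveyMeasurement, list[SamplerResult]]:
    """Forward-simulate one survey day.

    Concentrations are the steady-state forward solution times multiplicative
    lognormal noise at ``concentration_cv``; reported dosing rates (what the
    analyst believes) are perturbed at ``dosing_cv`` while the true emission
    drives the physics.  With ``return_samplers=True``, also returns the raw
    sampler extract masses consistent with
    :func:`~pftrace.calibration.concentration_from_sampler`:
    mass = C × SR × duration × recovery.
    """
    ss = np.random.SeedSequence(scenario.seed)
    conc_rng, dose_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    clean = steady_state_concentrations(scenario.true_flows, list(scenario.tracers))
    C = clean.C.copy()
    if scenario.concentration_cv > 0:
        sigma = np.sqrt(np.log1p(scenario.concentration_cv**2))
        C *= conc_rng.lognormal(-0.5 * sigma**2, sigma, size=C.shape)

    tracers = scenario.tracers
    if scenario.dosing_cv > 0:
        sigma = np.sqrt(np.log1p(scenario.dosing_cv**2))
        factors = dose_rng.lognormal(-0.5 * sigma**2, sigma, size=len(tracers))
        tracers = tuple(
            TracerSpec(t.tracer_id, t.source_zone, t.dosing_rate * f, t.n_dosers)
            for t, f in zip(tracers, factors)
        )

    measurement = SurveyMeasurement(
        concentrations=ConcentrationMatrix(C=C, tracer_ids=clean.tracer_ids),
        tracers=tracers,
        zones=scenario.zones,
        day_label=scenario.day_label,
    )
    if not return_samplers:
        return measurement

    samplers = []
    for t, spec in enumerate(scenario.tracers):
        cal = scenario.calibrations[spec.tracer_id]
        for z in range(scenario.zones.n_zones):
            c_ugml = C[t, z] * 1e-6  # µg/m³ → µg/mL of air
            mass = c_ugml * cal.sampling_rate * scenario.sampling_duration * cal.recovery
            samplers.append(
                SamplerResult(
                    tracer_id=spec.tracer_id,
                    zone=z + 1,
                    extracted_mass=mass,
                    duration=scenario.sampling_duration,
                    calibration=cal,
                )
            )
    return measurement, samplers


def simulate_gravimetry(
    rate: float,
    interval_h: float = 48.0,
    n_points: int = 6,
    noise_sd_mg: float = 0.0,
    seed: int | None = None,
    *,
    w0_mg: float = 5000.0,
    temperature: float = 25.0,
) -> GravimetrySeries:
    """Doser weight series under constant emission: w(t) = w0 − rate·t + noise.

    Defaults give six points at 48-h intervals spanning 240 h.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.arange(n_points) * interval_h
    w = w0_mg - rate * t
    if noise_sd_mg > 0:
        w = w + np.random.default_rng(seed).normal(0.0, noise_sd_mg, size=n_points)
    return GravimetrySeries(times=t, weights=w, temperature=temperature)


def simulate_decay(
    rate: float,
    c0: float = 2000.0,
    background: float = 400.0,
    duration_h: float = 8.0,
    step_h: float = 1.0,
    noise_sd_ppm: float = 0.0,
    seed: int | None = None,
) -> DecaySeries:
    """CO₂ decay series: C(t) = background + (c0 − background)·e^(−rate·t) + noise."""
    if c0 <= background:
        raise ValueError("c0 must exceed background")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = np.arange(0.0, duration_h + 0.5 * step_h, step_h)
    c = background + (c0 - background) * np.exp(-rate * t)
    if noise_sd_ppm > 0:
        c = c + np.random.default_rng(seed).normal(0.0, noise_sd_ppm, size=t.size)
    return DecaySeries(times=t, concentrations=c, background=background)
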