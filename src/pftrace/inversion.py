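"""Constrained mass-balance inversion: airflows from measured concentrations.

With one tracer per indoor zone, the steady-state mass balances are linear
in the unknown airflows, so the inversion is a nonnegative linear
least-squares problem over the n² + n flows (for 3 zones: 12 unknowns,
9 tracer rows + 3 air-volume closure rows).  Two solver routes are
provided:

``nnls``
    Exact nonnegative least squares on the stacked design matrix
    (:func:`scipy.optimize.nnls`).  Default: deterministic, no starting
    point, exact minimiser of the convex problem.
``bounded_quasi_newton``
    L-BFGS-B on the same squared-residual objective with bounds Q ≥ 0 —
    the field-traditional route (spreadsheet solvers), kept as a
    cross-check.

Residual weighting: tracer rows carry units µg/h and air rows m³/h.  Mode
``"raw"`` sums raw squares across the mixed units (the traditional
formulation); mode ``"normalized"`` divides each tracer row by its
tracer's emission rate M and each air row by a total-exhaust estimate,
making all rows dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.optimize

from .model import (
    ConcentrationMatrix,
    FlowMatrix,
    TracerSpec,
    ZoneSystem,
)

__all__ = [
    "SurveyMeasurement",
    "FlowEstimate",
    "NonIdentifiableError",
    "DegenerateMeasurementError",
    "flow_index",
    "design_matrix",
    "estimate_flows",
    "room_air_exchange_rates",
    "aggregate_daily",
    "propagate_uncertainty",
]


class NonIdentifiableError(ValueError):
    """The stacked design matrix is rank-deficient: flows are not identifiable."""


class DegenerateMeasurementError(ValueError):
    """Measured concentrations cannot support an inversion (e.g. all zero)."""


@dataclass(frozen=True)
class SurveyMeasurement:
    """One day's measured survey: concentrations, tracer specs, zone system."""

    concentrations: ConcentrationMatrix
    tracers: tuple[TracerSpec, ...]
    zones: ZoneSystem
    day_label: str = "day1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracers", tuple(self.tracers))
        n = self.zones.n_zones
        if self.concentrations.n_zones != n:
            raise ValueError("concentration columns must match the zone count")
        if len(self.tracers) != n:
            raise ValueError(
                f"need exactly one tracer per zone: {len(self.tracers)} tracers "
                f"for {n} zones"
            )
        sources = sorted(t.source_zone for t in self.tracers)
        if sources != list(range(1, n + 1)):
            raise ValueError("each indoor zone must be the source of exactly one tracer")


@dataclass(frozen=True)
class FlowEstimate:
    """Inversion output: flows, objective, per-room rates, solver diagnostics."""

    flows: FlowMatrix
    objective: float
    per_room_outdoor_ach: np.ndarray
    per_room_interroom_ach: np.ndarray
    solver_info: dict = field(default_factory=dict)
    day_label: str = "day1"


def flow_index(n_zones: int) -> list[tuple[int, int]]:
    """Ordering of the unknown flows: exhausts Q[i,0], infiltrations Q[0,i],
    then inter-room flows Q[i,j] (row-major).  Length n² + n."""
    n = n_zones
    idx = [(i, 0) for i in range(1, n + 1)]
    idx += [(0, i) for i in range(1, n + 1)]
    idx += [(i, j) for i in range(1, n + 1) for j in range(1, n + 1) if i != j]
    return idx


def design_matrix(
    measurement: SurveyMeasurement,
    weighting: Literal["raw", "normalized"] = "raw",
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the n² tracer and n air mass-balance rows as G q = d.

    Tracer row (T, zone i):
        Σ_{j≠i} C[T,j]·Q[j,i] − C[T,i]·(Q[i,0] + Σ_{j≠i} Q[i,j]) = −M_T·[i=src]
    Air row (zone i):
        Q[0,i] + Σ_{j≠i} Q[j,i] − Q[i,0] − Σ_{j≠i} Q[i,j] = 0
    """
    n = measurement.zones.n_zones
    C = measurement.concentrations.C
    tracers = measurement.tracers
    idx = flow_index(n)
    col = {pair: k for k, pair in enumerate(idx)}
    n_rows = n * len(tracers) + n
    G = np.zeros((n_rows, len(idx)))
    d = np.zeros(n_rows)

    r = 0
    for t, spec in enumerate(tracers):
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                if j == i:
                    continue
                G[r, col[(j, i)]] += C[t, j - 1]   # inflow of tracer from zone j
                G[r, col[(i, j)]] -= C[t, i - 1]   # outflow of air carrying tracer
            G[r, col[(i, 0)]] -= C[t, i - 1]       # exhaust to outdoors
            if spec.source_zone == i:
                d[r] = -spec.dosing_rate
            r += 1
    for i in range(1, n + 1):
        G[r, col[(0, i)]] += 1.0
        G[r, col[(i, 0)]] -= 1.0
        for j in range(1, n + 1):
            if j == i:
                continue
            G[r, col[(j, i)]] += 1.0
            G[r, col[(i, j)]] -= 1.0
        r += 1

    if weighting == "normalized":
        w = np.ones(n_rows)
        r = 0
        for spec in tracers:
            w[r:r + n] = 1.0 / spec.dosing_rate
            r += n
        # total-exhaust scale from the single-zone heuristic M / C_source
        q_scale = sum(
            spec.dosing_rate / C[t, spec.source_zone - 1]
            for t, spec in enumerate(tracers)
            if C[t, spec.source_zone - 1] > 0
        )
        w[r:] = 1.0 / max(q_scale, np.finfo(float).tiny)
        G = G * w[:, None]
        d = d * w
    elif weighting != "raw":
        raise ValueError(f"unknown weighting {weighting!r}")
    return G, d


def _check_preconditions(measurement: SurveyMeasurement) -> None:
    C = measurement.concentrations.C
    if not np.any(C > 0):
        raise DegenerateMeasurementError("degenerate measurement: all "
                                         "concentrations are zero")
    for t, spec in enumerate(measurement.tracers):
        if C[t, spec.source_zone - 1] <= 0:
            raise DegenerateMeasurementError(
                f"tracer {spec.tracer_id}: concentration in its source zone "
                f"{spec.source_zone} must be > 0"
            )


def estimate_flows(
    measurement: SurveyMeasurement,
    method: Literal["nnls", "bounded_quasi_newton"] = "nnls",
    weighting: Literal["raw", "normalized"] = "raw",
    *,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
    maxiter: int = 20000,
) -> FlowEstimate:
    """Estimate all n² + n airflows from a survey measurement.

    Minimises the (optionally weighted) sum of squared mass-balance
    residuals subject to Q ≥ 0.

    Parameters
    ----------
    measurement
        Concentrations, tracer specs and zone system for one day.
    method
        ``"nnls"`` (exact, default) or ``"bounded_quasi_newton"``
        (L-BFGS-B cross-check).
    weighting
        ``"raw"`` sums squares across mixed units; ``"normalized"`` makes
        every row dimensionless.
    x0, tol, maxiter
        Quasi-Newton controls: starting point (default: all flows equal to
        the Σ M / Σ C_source heuristic), objective tolerance, iteration cap.

    Raises
    ------
    NonIdentifiableError
        If the design matrix is rank-deficient.
    DegenerateMeasurementError
        If concentrations cannot support an inversion.
    """
    _check_preconditions(measurement)
    n = measurement.zones.n_zones
    G, d = design_matrix(measurement, weighting)

    if np.linalg.matrix_rank(G) < G.shape[1]:
        raise NonIdentifiableError(
            "non-identifiable system: stacked design matrix is rank-deficient; "
            "the measured concentrations do not pin down all flows"
        )

    if method == "nnls":
        q, rnorm = scipy.optimize.nnls(G, d)
        objective = float(rnorm**2)
        info = {"method": "nnls", "iterations": None, "converged": True}
    elif method == "bounded_quasi_newton":
        if x0 is None:
            C = measurement.concentrations.C
            src = np.array([C[t, s.source_zone - 1]
                            for t, s in enumerate(measurement.tracers)])
            M = np.array([s.dosing_rate for s in measurement.tracers])
            x0 = np.full(G.shape[1], M.sum() / src.sum())
        # column scaling: the raw rows mix units (µg/h vs m³/h), which
        # ill-conditions the quadratic and stalls the line search; scaling
        # the variables leaves the objective and the Q >= 0 bounds intact
        scale = np.linalg.norm(G, axis=0)
        scale[scale == 0] = 1.0
        Gs = G / scale
        GtG = Gs.T @ Gs
        Gtd = Gs.T @ d
        dd = d @ d

        def fun(y: np.ndarray) -> tuple[float, np.ndarray]:
            Gy = GtG @ y
            f = y @ Gy - 2.0 * (Gtd @ y) + dd
            return f, 2.0 * (Gy - Gtd)

        res = scipy.optimize.minimize(
            fun,
            x0 * scale,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * G.shape[1],
            options={
                "ftol": tol,   # relative objective-reduction stopping rule
                "gtol": 1e-14,
                "maxiter": maxiter,
                "maxfun": maxiter,
                "maxcor": 30,
            },
        )
        q = np.maximum(res.x, 0.0) / scale
        objective = float(np.sum((G @ q - d) ** 2))
        info = {
            "method": "bounded_quasi_newton",
            "iterations": int(res.nit),
            "converged": bool(res.success),
            "message": str(res.message),
        }
        if not res.success:
            info["warning"] = "quasi-Newton did not report convergence"
    else:
        raise ValueError(f"unknown method {method!r}")

    Q = np.zeros((n + 1, n + 1))
    for k, (i, j) in enumerate(flow_index(n)):
        Q[i, j] = q[k]
    flows = FlowMatrix(Q=Q)
    outdoor, interroom = room_air_exchange_rates(flows, measurement.zones)
    info["weighting"] = weighting
    return FlowEstimate(
        flows=flows,
        objective=objective,
        per_room_outdoor_ach=outdoor,
        per_room_interroom_ach=interroom,
        solver_info=info,
        day_label=measurement.day_label,
    )


def room_air_exchange_rates(
    flows: FlowMatrix, zones: ZoneSystem
) -> tuple[np.ndarray, np.ndarray]:
    """Per-room air exchange rates (h⁻¹).

    Returns ``(outdoor, interroom)`` where ``outdoor[i] = Q[0, i+1] / V_i``
    (fresh-air rate into room i+1) and ``interroom[i] = Σ_j Q[j, i+1] / V_i``
    over indoor j (air arriving from the other rooms).
    """
    if flows.n_zones != zones.n_zones:
        raise ValueError(
            f"flow matrix has {flows.n_zones} zones but zone system has "
            f"{zones.n_zones}"
        )
    Q = flows.Q
    outdoor = Q[0, 1:] / zones.volumes
    interroom = Q[1:, 1:].sum(axis=0) / zones.volumes
    return outdoor, interroom


def aggregate_daily(estimates: Sequence[FlowEstimate]) -> dict:
    """Mean and sample SD (n−1 denominator) of each rate across days.

    With a single estimate the SD is undefined and reported as ``None``,
    never as zero.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    n = estimates[0].flows.n_zones
    for e in estimates[1:]:
        if e.flows.n_zones != n:
            raise ValueError("all estimates must share the same zone system")
    outdoor = np.array([e.per_room_outdoor_ach for e in estimates])
    interroom = np.array([e.per_room_interroom_ach for e in estimates])
    out = {
        "n_days": len(estimates),
        "outdoor_ach_mean": outdoor.mean(axis=0),
        "interroom_ach_mean": interroom.mean(axis=0),
    }
    if len(estimates) >= 2:
        out["outdoor_ach_sd"] = outdoor.std(axis=0, ddof=1)
        out["interroom_ach_sd"] = interroom.std(axis=0, ddof=1)
    else:
        out["outdoor_ach_sd"] = None
        out["interroom_ach_sd"] = None
    return out


def propagate_uncertainty(
    measurement: SurveyMeasurement,
    concentration_cv: float,
    dosing_cv: float,
    n_draws: int = 1000,
    seed: int | None = None,
    *,
    method: Literal["nnls", "bounded_quasi_newton"] = "nnls",
    weighting: Literal["raw", "normalized"] = "raw",
    max_failure_fraction: float = 0.2,
) -> dict:
    """Monte-Carlo uncertainty propagation by re-inversion of perturbed data.

    Concentrations and dosing rates are perturbed with mean-preserving
    multiplicative lognormal noise at the given coefficients of variation,
    then re-inverted; 2.5/50/97.5 percentiles of every flow and per-room
    rate are reported.  Draws whose inversion fails are counted and
    reported; if more than ``max_failure_fraction`` fail, an error is
    raised instead of a silently truncated answer.
    """
    if concentration_cv < 0 or dosing_cv < 0:
        raise ValueError("CVs must be >= 0")
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100 for stable percentiles")
    rng = np.random.default_rng(seed)
    n = measurement.zones.n_zones
    C0 = measurement.concentrations.C
    idx = flow_index(n)

    def _lognormal_factors(cv: float, shape: tuple[int, ...]) -> np.ndarray:
        if cv == 0:
            return np.ones(shape)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)

    flows_draws, outdoor_draws, interroom_draws = [], [], []
    n_failed = 0
    for _ in range(n_draws):
        C = C0 * _lognormal_factors(concentration_cv, C0.shape)
        tracers = tuple(
            TracerSpec(
                tracer_id=t.tracer_id,
                source_zone=t.source_zone,
                dosing_rate=t.dosing_rate
                * float(_lognormal_factors(dosing_cv, (1,))[0]),
                n_dosers=t.n_dosers,
            )
            for t in measurement.tracers
        )
        try:
            pert = SurveyMeasurement(
                concentrations=ConcentrationMatrix(
                    C=C, tracer_ids=measurement.concentrations.tracer_ids
                ),
                tracers=tracers,
                zones=measurement.zones,
                day_label=measurement.day_label,
            )
            est = estimate_flows(pert, method=method, weighting=weighting)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        flows_draws.append([est.flows.Q[i, j] for i, j in idx])
        outdoor_draws.append(est.per_room_outdoor_ach)
        interroom_draws.append(est.per_room_interroom_ach)

    if n_failed > max_failure_fraction * n_draws:
        raise RuntimeError(
            f"{n_failed}/{n_draws} Monte-Carlo draws failed inversion "
            f"(limit {max_failure_fraction:.0%})"
        )
    pct = [2.5, 50.0, 97.5]
    return {
        "n_draws": n_draws,
        "n_failed": n_failed,
        "percentiles": pct,
        "flow_index": idx,
        "flows": np.percentile(np.array(flows_draws), pct, axis=0),
        "outdoor_ach": np.percentile(np.array(outdoor_draws), pct, axis=0),
        "interroom_ach": np.percentile(np.array(interroom_draws), pct, axis=0),
    }
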