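"""Domain types and the forward steady-state multizone tracer-transport model.

Zone indexing convention (used everywhere in this package): index 0 is
outdoors; indoor zones are 1..n_zones.  Airflows are held in a square
matrix ``Q`` of shape ``(n_zones+1, n_zones+1)`` where ``Q[i, j]`` is the
airflow from zone i to zone j in m³/h and the diagonal is zero by
convention.  Internal units are fixed: flows m³/h, concentrations µg/m³,
dosing rates µg/h (mg/h is converted at the I/O boundary).

The model assumes steady state, perfect mixing within each zone, and zero
outdoor tracer concentration.  Under those assumptions the concentration
of each tracer satisfies a linear mass balance per indoor zone:

    M_T·[i = source(T)] + Σ_j C[T, j]·Q[j, i]
        − C[T, i]·(Q[i, 0] + Σ_j Q[i, j]) = 0

which is one dense linear system per tracer, all sharing the same
transport matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZoneSystem",
    "FlowMatrix",
    "TracerSpec",
    "ConcentrationMatrix",
    "IllPosedSystemError",
    "steady_state_concentrations",
    "closure_residuals",
]

#: condition-number ceiling beyond which the transport matrix is treated
#: as singular (a zone with no outflow, or a disconnected component with
#: no exhaust path)
_COND_MAX = 1e12


class IllPosedSystemError(ValueError):
    """The tracer-transport system is singular or non-identifiable."""


@dataclass(frozen=True)
class ZoneSystem:
    """Indoor zones of a dwelling: count, volumes (m³) and display labels."""

    volumes: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        if vols.ndim != 1 or vols.size < 1:
            raise ValueError("volumes must be a 1-D array with at least one zone")
        if np.any(vols <= 0) or not np.all(np.isfinite(vols)):
            raise ValueError("every zone volume must be finite and > 0")
        object.__setattr__(self, "volumes", vols)
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"zone{i}" for i in range(1, vols.size + 1))
            )
        elif len(self.labels) != vols.size:
            raise ValueError("labels must match the number of zones")

    @property
    def n_zones(self) -> int:
        return self.volumes.size


@dataclass(frozen=True)
class FlowMatrix:
    """All airflows Q[i, j] (m³/h) among indoor zones and outdoors (index 0)."""

    Q: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1] or Q.shape[0] < 2:
            raise ValueError("Q must be square of shape (n_zones+1, n_zones+1)")
        if np.any(Q < 0) or not np.all(np.isfinite(Q)):
            raise ValueError("all flows must be finite and >= 0")
        Q = Q.copy()
        np.fill_diagonal(Q, 0.0)
        Q.flags.writeable = False
        object.__setattr__(self, "Q", Q)

    @property
    def n_zones(self) -> int:
        return self.Q.shape[0] - 1

    def closure_residuals(self) -> np.ndarray:
        """Per indoor zone: total inflow minus total outflow (m³/h)."""
        return closure_residuals(self)

    def is_balanced(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.closure_residuals()) <= tol))


@dataclass(frozen=True)
class TracerSpec:
    """One tracer: its source zone and total emission rate.

    ``dosing_rate`` is the summed emission M over all dosers in the source
    room, in µg/h.
    """

    tracer_id: str
    source_zone: int
    dosing_rate: float
    n_dosers: int = 1

    def __post_init__(self) -> None:
        if self.dosing_rate <= 0:
            raise ValueError(f"dosing_rate must be > 0, got {self.dosing_rate}")
        if self.source_zone < 1:
            raise ValueError("source_zone is an indoor zone index (>= 1)")
        if self.n_dosers < 1:
            raise ValueError("n_dosers must be >= 1")


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Steady-state concentrations C[tracer, zone] in µg/m³ (indoor zones only).

    The outdoor concentration of every tracer is fixed at 0 by model
    assumption and is not stored.
    """

    C: np.ndarray
    tracer_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2:
            raise ValueError("C must be 2-D, indexed [tracer, indoor zone]")
        if np.any(C < 0) or not np.all(np.isfinite(C)):
            raise ValueError("all concentrations must be finite and >= 0")
        C = C.copy()
        C.flags.writeable = False
        object.__setattr__(self, "C", C)
        if not self.tracer_ids:
            object.__setattr__(
                self, "tracer_ids", tuple(f"tracer{k}" for k in range(C.shape[0]))
            )
        elif len(self.tracer_ids) != C.shape[0]:
            raise ValueError("tracer_ids must match the number of tracer rows")

    @property
    def n_tracers(self) -> int:
        return self.C.shape[0]

    @property
    def n_zones(self) -> int:
        return self.C.shape[1]


def closure_residuals(flows: FlowMatrix) -> np.ndarray:
    """Air-volume closure residual per indoor zone (m³/h).

    residual(i) = Q[0,i] + Σ_{j≠i} Q[j,i] − Q[i,0] − Σ_{j≠i} Q[i,j].
    A balanced flow field has every residual equal to zero.
    """
    Q = flows.Q
    inflow = Q.sum(axis=0)  # column sums: total inflow to each zone
    outflow = Q.sum(axis=1)  # row sums: total outflow from each zone
    return (inflow - outflow)[1:]


def _transport_matrix(Q: np.ndarray) -> np.ndarray:
    """Dense transport operator A with A c = −m, over indoor zones.

    A[i, i] = −(total outflow of zone i); A[i, j] = Q[j, i] for j ≠ i.
    Indoor indices shifted down by one (0-based over indoor zones).
    """
    n = Q.shape[0] - 1
    A = Q[1:, 1:].T.copy()  # A[i, j] = Q[j+1, i+1]
    total_outflow = Q[1:, :].sum(axis=1)
    A[np.diag_indices(n)] = -total_outflow
    return A


def steady_state_concentrations(
    flows: FlowMatrix,
    tracers: list[TracerSpec],
    *,
    balance_tol: float = 1e-6,
) -> ConcentrationMatrix:
    """Solve the forward problem: concentrations from flows and emissions.

    Parameters
    ----------
    flows
        Balanced airflow field (closure residual per zone within
        ``balance_tol`` m³/h).
    tracers
        One TracerSpec per tracer; each must be sourced in an indoor zone of
        ``flows``.

    Returns
    -------
    ConcentrationMatrix
        C[t, i] in µg/m³ for tracer t in indoor zone i+1.

    Raises
    ------
    IllPosedSystemError
        If the transport matrix is singular (e.g. a zone with zero total
        outflow), rather than returning NaNs.
    ValueError
        If the flow field is not balanced or a source zone is out of range.
    """
    n = flows.n_zones
    resid = closure_residuals(flows)
    if np.any(np.abs(resid) > balance_tol):
        raise ValueError(
            f"flow field is not balanced: max |closure residual| = "
            f"{np.max(np.abs(resid)):.3g} m³/h exceeds tol {balance_tol}"
        )
    for t in tracers:
        if t.source_zone > n:
            raise ValueError(f"tracer {t.tracer_id} sourced in zone {t.source_zone}, "
                             f"but the system has {n} indoor zones")

    A = _transport_matrix(flows.Q)
    if np.linalg.matrix_rank(A) < n or np.linalg.cond(A) > _COND_MAX:
        raise IllPosedSystemError(
            "non-identifiable/ill-posed transport system: singular transport "
            "matrix (check that every zone has a positive total outflow and "
            "every connected component an exhaust path)"
        )

    # one RHS column per tracer: A c = −m
    m = np.zeros((n, len(tracers)))
    for k, t in enumerate(tracers):
        m[t.source_zone - 1, k] = t.dosing_rate
    C = np.linalg.solve(A, -m).T  # shape (n_tracers, n_zones)
    # steady state of a balanced network is nonnegative; clip solver dust
    C = np.where(np.abs(C) < 1e-12 * max(1.0, np.abs(C).max()), np.abs(C), C)
    if np.any(C < 0):
        raise IllPosedSystemError("negative steady-state concentration: system "
                                  "is physically inconsistent")
    return ConcentrationMatrix(C=C, tracer_ids=tuple(t.tracer_id for t in tracers))
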