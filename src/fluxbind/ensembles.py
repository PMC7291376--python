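"""History-dependent split ensembles: basins, warping, and flux-based rates.

An equilibrium ensemble is split into two non-equilibrium ensembles by the
basin last visited: the *unbinding* ensemble (last visited bound) and the
*rebinding* ensemble (last visited unbound).  Each is simulated separately;
walkers reaching the destination basin record an "exit point" (their weight
and structure) and are warped back to the start structure with the weight
kept and velocities redrawn.  The time-averaged exit-weight flux gives

    k_off(t) = sum_i w_i / t            [1/ps -> 1/s]
    k_on(t)  = sum_i w_i / (C t)        [1/(M s)]

with t the ensemble clock time and C = 1/V_box the single-ligand
concentration.  Steady-state balance pi_b * phi_b->u = pi_u * phi_u->b turns
the two normalised fluxes into the ensemble probabilities pi_b, pi_u, and the
weight fraction actually inside each basin gives f_b and f_u.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError, UndefinedRatioError
from .toy_system import (
    SystemState,
    ToySystemParams,
    maxwell_boltzmann_velocities,
)
from .revo import Walker
from .units import PS_TO_S_RATE, concentration_from_volume

__all__ = [
    "BasinSpec",
    "ExitPoint",
    "FluxLedger",
    "EnsembleStats",
    "RateEstimate",
    "classify_basin",
    "classify_distances",
    "apply_warp",
    "rate_from_flux",
    "concentration_from_volume",
    "pi_ratio",
    "basin_fraction",
]


@dataclass(frozen=True)
class BasinSpec:
    """Geometric basin definitions.

    bound_cutoff: native distance (|r - a|) below which a structure is bound.
    unbound_cutoff: host-guest clearance (r - a) above which it is unbound.
    Strict inequalities on both sides; everything else is intermediate.
    """

    bound_cutoff: float = 0.1
    unbound_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.bound_cutoff < self.unbound_cutoff):
            raise InvalidInputError(
                f"need 0 < bound_cutoff < unbound_cutoff, got "
                f"{self.bound_cutoff}, {self.unbound_cutoff}"
            )

    def validate_against(self, params: ToySystemParams) -> None:
        half = float(np.min(params.box_lengths)) / 2.0
        if params.host_radius + self.unbound_cutoff >= half:
            raise InvalidInputError(
                "unbound region is empty: host_radius + unbound_cutoff must be "
                "< min(box_lengths)/2"
            )


@dataclass
class ExitPoint:
    """A recorded basin-crossing event."""

    weight: float
    cycle_index: int
    elapsed_time: float
    source_ensemble: str  # "unbinding" or "rebinding"
    snapshot: SystemState

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise InvalidInputError(f"exit weight must be in (0, 1], got {self.weight}")
        if not self.elapsed_time > 0:
            raise InvalidInputError("elapsed_time must be > 0")


@dataclass
class FluxLedger:
    """Accumulates exit points and the ensemble clock for one replicate."""

    ensemble: str  # "unbinding" or "rebinding"
    concentration: float | None = None  # mol/L; required for rebinding rates
    replicate_id: int = 0
    exit_points: list[ExitPoint] = field(default_factory=list)
    total_ensemble_time: float = 0.0  # ps

    def advance_clock(self, dt_ps: float) -> None:
        if dt_ps <= 0:
            raise InvalidInputError("clock increments must be positive")
        self.total_ensemble_time += dt_ps

    @property
    def total_exit_weight(self) -> float:
        return float(sum(ep.weight for ep in self.exit_points))

    def flux(self) -> float:
        """Time-averaged exit-weight flux, 1/ps."""
        if self.total_ensemble_time <= 0:
            raise InvalidInputError("total_ensemble_time must be > 0")
        return self.total_exit_weight / self.total_ensemble_time


@dataclass
class EnsembleStats:
    """Combined summary of a split-ensemble pair."""

    pi_b: float
    pi_u: float
    f_b: float
    f_u: float
    flux_u_to_b: float
    flux_b_to_u: float


def classify_basin(
    state: SystemState, basin_spec: BasinSpec, params: ToySystemParams
) -> str:
    """Classify a state as 'bound', 'unbound' or 'intermediate'.

    Bound: native distance strictly below bound_cutoff.  Unbound: clearance
    strictly above unbound_cutoff (a clearance exactly at the cutoff is
    intermediate).  The BasinSpec invariant makes the two exclusive.
    """
    from .toy_system import host_guest_distance

    r = host_guest_distance(state, params)
    return _classify_r(r, basin_spec, params)


def _classify_r(r: float, basin_spec: BasinSpec, params: ToySystemParams) -> str:
    if abs(r - params.native_radius) < basin_spec.bound_cutoff:
        return "bound"
    if r - params.host_radius > basin_spec.unbound_cutoff:
        return "unbound"
    return "intermediate"


def classify_distances(
    r: np.ndarray, basin_spec: BasinSpec, params: ToySystemParams
) -> np.ndarray:
    """Vectorised basin classification from host-guest distances.

    Returns an int array: 0 = bound, 1 = intermediate, 2 = unbound.
    """
    r = np.asarray(r, dtype=float)
    out = np.ones(r.shape, dtype=np.int8)
    out[np.abs(r - params.native_radius) < basin_spec.bound_cutoff] = 0
    out[r - params.host_radius > basin_spec.unbound_cutoff] = 2
    return out


BASIN_CODES = {"bound": 0, "intermediate": 1, "unbound": 2}


def apply_warp(
    walkers: Sequence[Walker],
    basin_spec: BasinSpec,
    start_state: SystemState,
    params: ToySystemParams,
    rng: np.random.Generator,
    ledger: FluxLedger,
    cycle_index: int = 0,
) -> tuple[list[Walker], list[ExitPoint]]:
    """Warp every walker that reached the destination basin back to the start.

    The destination basin is 'unbound' for the unbinding ensemble and 'bound'
    for the rebinding ensemble (taken from ``ledger.ensemble``).  For each
    crossing walker an ExitPoint (weight, cycle, snapshot) is appended to the
    ledger, the walker's coordinates are reset to ``start_state``, its
    velocities are redrawn from Maxwell-Boltzmann at T, and its weight is
    unchanged, so the ensemble's total weight is conserved exactly.
    """
    destination = "unbound" if ledger.ensemble == "unbinding" else "bound"
    new_points: list[ExitPoint] = []
    out: list[Walker] = []
    for w in walkers:
        if classify_basin(w.state, basin_spec, params) == destination:
            ep = ExitPoint(
                weight=w.weight,
                cycle_index=cycle_index,
                elapsed_time=ledger.total_ensemble_time,
                source_ensemble=ledger.ensemble,
                snapshot=w.state.copy(),
            )
            ledger.exit_points.append(ep)
            new_points.append(ep)
            vel = maxwell_boltzmann_velocities(1, params.guest_mass,
                                               params.temperature, rng)[0]
            state = SystemState(start_state.position.copy(), vel, w.state.time)
            out.append(Walker(state=state, weight=w.weight,
                              history_label=w.history_label,
                              lineage_id=w.lineage_id))
        else:
            out.append(w)
    return out, new_points


@dataclass
class RateEstimate:
    """Flux rate estimate: full k(t) series after each cycle plus the final value."""

    kind: str  # "k_off" (1/s) or "k_on" (1/(M s))
    times_ps: np.ndarray
    series: np.ndarray
    value: float
    zero_events: bool = False


def rate_from_flux(ledger: FluxLedger, burn_in_ps: float = 0.0) -> RateEstimate:
    """Rate constant from the accumulated exit-point flux.

    Unbinding ledgers yield k_off in 1/s; rebinding ledgers yield k_on in
    1/(M s), dividing the flux by the ledger's ligand concentration.  The
    returned series re-evaluates k(t) at each recorded exit time (a running
    sum over exit weights divided by the ensemble clock), which reproduces the
    saw-tooth flux traces: decaying between events, jumping upward when a
    high-weight exit point arrives.

    With ``burn_in_ps`` > 0 the final value counts only exits after the
    burn-in and divides by the post-burn-in time: the raw from-zero estimate
    carries a startup deficit of order MFPT/t because the ensemble needs one
    passage time before the warp renewal flux is established.  The series is
    always reported raw from t = 0.
    """
    if ledger.total_ensemble_time <= 0:
        raise InvalidInputError("total_ensemble_time must be > 0")
    if burn_in_ps >= ledger.total_ensemble_time:
        raise InvalidInputError("burn_in_ps must be below the total ensemble time")
    if ledger.ensemble == "rebinding":
        if ledger.concentration is None or ledger.concentration <= 0:
            raise InvalidInputError("rebinding ledger requires a positive concentration")
        denom = ledger.concentration
        kind = "k_on"
    else:
        denom = 1.0
        kind = "k_off"

    if not ledger.exit_points:
        return RateEstimate(kind=kind, times_ps=np.array([ledger.total_ensemble_time]),
                            series=np.array([0.0]), value=0.0, zero_events=True)

    times = np.array([ep.elapsed_time for ep in ledger.exit_points])
    weights = np.array([ep.weight for ep in ledger.exit_points])
    csum = np.cumsum(weights)
    series = csum / times / denom * PS_TO_S_RATE
    late = weights[times > burn_in_ps].sum()
    final = (late / (ledger.total_ensemble_time - burn_in_ps)
             / denom * PS_TO_S_RATE)
    times = np.append(times, ledger.total_ensemble_time)
    series = np.append(series, csum[-1] / ledger.total_ensemble_time / denom
                       * PS_TO_S_RATE)
    return RateEstimate(kind=kind, times_ps=times, series=series, value=float(final),
                        zero_events=bool(late == 0))


def pi_ratio(flux_u_to_b: float, flux_b_to_u: float) -> tuple[float, float]:
    """Ensemble probabilities (pi_b, pi_u) from the two normalised fluxes.

    Steady-state balance gives pi_b / pi_u = phi_u->b / phi_b->u, normalised
    so pi_b + pi_u = 1.
    """
    if flux_u_to_b < 0 or flux_b_to_u < 0:
        raise InvalidInputError("fluxes must be non-negative")
    total = flux_u_to_b + flux_b_to_u
    if total == 0:
        raise UndefinedRatioError("both fluxes are zero; pi ratio is undefined")
    pi_b = flux_u_to_b / total
    return pi_b, 1.0 - pi_b


def basin_fraction(weights: np.ndarray, in_basin: np.ndarray) -> float:
    """Weight fraction inside a basin: sum(w | in basin) / sum(w).

    ``in_basin`` is boolean per walker.  Invariant under uniform rescaling of
    the weights.
    """
    w = np.asarray(weights, dtype=float)
    m = np.asarray(in_basin, dtype=bool)
    if w.size == 0 or not np.sum(w) > 0:
        raise InvalidInputError("basin_fraction requires walkers with positive total weight")
    if m.shape != w.shape:
        raise InvalidInputError("weights and basin mask must have the same shape")
    return float(np.sum(w[m]) / np.sum(w))
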