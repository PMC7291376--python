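"""Split-ensemble weighted-ensemble simulation driver.

Runs the unbinding and rebinding ensembles of the toy host-guest system:
walkers are propagated with Langevin dynamics in cycles, warped (with exit
point recording) when they reach the destination basin, and resampled with
REVO between cycles.  Replicates differ only by seed; rates are averaged over
replicates with the standard error of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import propagate
from .ensembles import (
    BasinSpec,
    FluxLedger,
    ExitPoint,
    RateEstimate,
    apply_warp,
    basin_fraction,
    classify_distances,
    rate_from_flux,
)
from .exceptions import InvalidInputError
from .revo import (
    ResamplerConfig,
    Walker,
    make_rebinding_distance,
    make_unbinding_distance,
    resample,
)
from .toy_system import (
    SystemState,
    ToySystemParams,
    maxwell_boltzmann_velocities,
    minimum_image_displacement,
)
from .units import concentration_from_volume

__all__ = ["EnsembleRunResult", "ReplicateSummary", "SplitEnsembleSimulation",
           "run_paired_replicates"]


@dataclass
class EnsembleRunResult:
    """Everything one replicate of one ensemble produced."""

    ensemble: str
    replicate_id: int
    ledger: FluxLedger
    rate: RateEstimate  # raw from t = 0, as the flux traces are plotted
    rate_steady: RateEstimate  # burn-in excluded; used for free energies
    cycle_times_ps: np.ndarray
    rate_series_per_cycle: np.ndarray  # k(t) re-evaluated after every cycle
    basin_fraction_series: np.ndarray  # f_b (unbinding) or f_u (rebinding) per cycle
    total_weight_series: np.ndarray  # sum of walker weights after every cycle
    burn_in_cycles: int
    eint_samples: np.ndarray  # (n, 2): energy kcal/mol, weight; rebinding only
    decisions: list = field(default_factory=list)
    final_walkers: list = field(default_factory=list)

    @property
    def basin_fraction_mean(self) -> float:
        """Post-burn-in average of the per-cycle basin weight fraction."""
        tail = self.basin_fraction_series[self.burn_in_cycles:]
        if tail.size == 0:
            raise InvalidInputError("no post-burn-in cycles")
        return float(np.mean(tail))


@dataclass
class ReplicateSummary:
    """Replicate-averaged quantity with its standard error."""

    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        n = len(self.values)
        if n < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1) / np.sqrt(n))


class SplitEnsembleSimulation:
    """Driver for paired unbinding/rebinding weighted-ensemble runs.

    Defaults mirror the study conditions: 48 walkers, 20 ps cycles for
    unbinding and 200 ps cycles for rebinding; all overridable.
    """

    def __init__(
        self,
        params: ToySystemParams,
        basin_spec: BasinSpec,
        resampler_config: ResamplerConfig | None = None,
        n_walkers: int = 48,
    ):
        basin_spec.validate_against(params)
        if n_walkers < 2:
            raise InvalidInputError("need at least 2 walkers")
        self.params = params
        self.basin = basin_spec
        self.resampler = resampler_config or ResamplerConfig()
        self.n_walkers = n_walkers

    # -- internals ----------------------------------------------------------

    def _distances(self, pos: np.ndarray) -> np.ndarray:
        _, r = minimum_image_displacement(pos, self.params.host_position,
                                          self.params.box_lengths)
        return np.atleast_1d(r)

    def _as_walkers(self, pos, vel, weights, time_ps, label) -> list[Walker]:
        return [
            Walker(state=SystemState(pos[i].copy(), vel[i].copy(), time_ps),
                   weight=float(weights[i]), history_label=label, lineage_id=i)
            for i in range(len(weights))
        ]

    def _run(
        self,
        ensemble: str,
        start_state: SystemState,
        n_cycles: int,
        cycle_steps: int,
        rng: np.random.Generator,
        burn_in_cycles: int,
        replicate_id: int,
        collect_eint: bool,
    ) -> EnsembleRunResult:
        p = self.params
        n = self.n_walkers
        label = "from_bound" if ensemble == "unbinding" else "from_unbound"
        conc = concentration_from_volume(p.volume) if ensemble == "rebinding" else None
        ledger = FluxLedger(ensemble=ensemble, concentration=conc,
                            replicate_id=replicate_id)
        dist_fn = (make_unbinding_distance(p) if ensemble == "unbinding"
                   else make_rebinding_distance(p))
        source_code = 0 if ensemble == "unbinding" else 2  # bound / unbound

        pos = np.tile(start_state.position, (n, 1))
        vel = maxwell_boltzmann_velocities(n, p.guest_mass, p.temperature, rng)
        weights = np.full(n, 1.0 / n)
        time_ps = 0.0
        cycle_dt = cycle_steps * p.timestep

        destination = "unbound" if ensemble == "unbinding" else "bound"
        absorb = (destination, self.basin.bound_cutoff, self.basin.unbound_cutoff)
        f_series = np.empty(n_cycles)
        cycle_times = np.empty(n_cycles)
        cum_exit_weight = np.empty(n_cycles)
        weight_totals = np.empty(n_cycles)
        eint: list[tuple[float, float]] = []
        decisions = []

        for cyc in range(n_cycles):
            # basin entry is checked after every dynamics step: walkers are
            # frozen at the crossing, warped there, and continue from the
            # start structure for the remainder of the cycle
            _, cross = propagate(pos, vel, p, cycle_steps, rng, absorb=absorb)
            for i in np.nonzero(cross >= 0)[0]:
                off = int(cross[i])
                while True:
                    ledger.exit_points.append(ExitPoint(
                        weight=float(weights[i]),
                        cycle_index=cyc,
                        elapsed_time=time_ps + (off + 1) * p.timestep,
                        source_ensemble=ensemble,
                        snapshot=SystemState(pos[i].copy(), vel[i].copy(),
                                             time_ps + (off + 1) * p.timestep),
                    ))
                    pos[i] = start_state.position
                    vel[i] = maxwell_boltzmann_velocities(
                        1, p.guest_mass, p.temperature, rng)[0]
                    rem = cycle_steps - (off + 1)
                    if rem <= 0:
                        break
                    _, c_again = propagate(pos[i:i + 1], vel[i:i + 1], p, rem,
                                           rng, absorb=absorb)
                    if c_again[0] < 0:
                        break
                    off = cycle_steps - rem + int(c_again[0])
            time_ps += cycle_dt
            ledger.advance_clock(cycle_dt)

            # safety sweep; a no-op given per-step crossing checks above
            walkers = self._as_walkers(pos, vel, weights, time_ps, label)
            walkers, _ = apply_warp(walkers, self.basin, start_state, p, rng,
                                    ledger, cycle_index=cyc)

            pos = np.array([w.state.position for w in walkers])
            vel = np.array([w.state.velocity for w in walkers])
            weights = np.array([w.weight for w in walkers])

            codes = classify_distances(self._distances(pos), self.basin, p)
            f_series[cyc] = basin_fraction(weights, codes == source_code)
            cycle_times[cyc] = time_ps
            cum_exit_weight[cyc] = ledger.total_exit_weight

            if collect_eint:
                unbound = codes == 2
                if np.any(unbound):
                    r_unb = self._distances(pos)[unbound]
                    e = p.coulomb_prefactor / r_unb
                    eint.extend(zip(e.tolist(), weights[unbound].tolist()))

            walkers, decision = resample(walkers, self.resampler, dist_fn, rng)
            if not decision.is_identity:
                decisions.append((cyc, decision))
            pos = np.array([w.state.position for w in walkers])
            vel = np.array([w.state.velocity for w in walkers])
            weights = np.array([w.weight for w in walkers])
            weight_totals[cyc] = float(np.sum(weights))

        rate = rate_from_flux(ledger)
        rate_steady = rate_from_flux(ledger,
                                     burn_in_ps=burn_in_cycles * cycle_dt)
        from .units import PS_TO_S_RATE

        denom = conc if conc is not None else 1.0
        k_series = cum_exit_weight / cycle_times / denom * PS_TO_S_RATE
        return EnsembleRunResult(
            ensemble=ensemble,
            replicate_id=replicate_id,
            ledger=ledger,
            rate=rate,
            rate_steady=rate_steady,
            cycle_times_ps=cycle_times,
            rate_series_per_cycle=k_series,
            basin_fraction_series=f_series,
            total_weight_series=weight_totals,
            burn_in_cycles=burn_in_cycles,
            eint_samples=np.array(eint) if eint else np.empty((0, 2)),
            decisions=decisions,
            final_walkers=self._as_walkers(pos, vel, weights, time_ps, label),
        )

    # -- public entry points ------------------------------------------------

    def run_unbinding(
        self,
        n_cycles: int,
        cycle_steps: int,
        rng: np.random.Generator,
        burn_in_cycles: int = 0,
        replicate_id: int = 0,
    ) -> EnsembleRunResult:
        """One unbinding replicate: walkers start in the bound pose; exits into
        the unbound basin are recorded and warped back."""
        return self._run("unbinding", self.params.bound_start_state(), n_cycles,
                         cycle_steps, rng, burn_in_cycles, replicate_id,
                         collect_eint=False)

    def run_rebinding(
        self,
        n_cycles: int,
        cycle_steps: int,
        rng: np.random.Generator,
        unbinding_exit_points: list[ExitPoint] | None = None,
        start_state: SystemState | None = None,
        burn_in_cycles: int = 0,
        replicate_id: int = 0,
    ) -> EnsembleRunResult:
        """One rebinding replicate.

        The start structure is drawn (weight-proportionally) from the supplied
        unbinding exit points, or given explicitly via ``start_state``.
        Interaction energies of unbound walkers are collected every cycle for
        the electrostatic correction.
        """
        if start_state is None:
            if not unbinding_exit_points:
                raise InvalidInputError(
                    "rebinding requires unbinding exit points (or an explicit "
                    "start_state); run the unbinding ensemble first"
                )
            w = np.array([ep.weight for ep in unbinding_exit_points])
            idx = rng.choice(len(w), p=w / w.sum())
            start_state = unbinding_exit_points[int(idx)].snapshot.copy()
        return self._run("rebinding", start_state, n_cycles, cycle_steps, rng,
                         burn_in_cycles, replicate_id, collect_eint=True)


def run_paired_replicates(
    params: ToySystemParams,
    basin_spec: BasinSpec,
    resampler_config: ResamplerConfig | None = None,
    seed: int = 0,
    n_walkers: int = 48,
    n_unbinding_replicates: int = 4,
    n_rebinding_replicates: int = 4,
    n_cycles_unbinding: int = 200,
    cycle_steps_unbinding: int = 2000,
    n_cycles_rebinding: int = 80,
    cycle_steps_rebinding: int = 5000,
    burn_in_unbinding: int = 40,
    burn_in_rebinding: int = 15,
) -> tuple[list[EnsembleRunResult], list[EnsembleRunResult]]:
    """Run the full unbinding-then-rebinding replicate protocol.

    Replicates get independent, order-insensitive RNG streams derived from
    ``seed``; each rebinding replicate draws its start structure from the
    pooled unbinding exit points.
    """
    sim = SplitEnsembleSimulation(params, basin_spec, resampler_config,
                                  n_walkers=n_walkers)
    unb = [
        sim.run_unbinding(n_cycles_unbinding, cycle_steps_unbinding,
                          np.random.default_rng([seed, 0, i]),
                          burn_in_cycles=burn_in_unbinding, replicate_id=i)
        for i in range(n_unbinding_replicates)
    ]
    pool = [ep for r in unb for ep in r.ledger.exit_points]
    reb = [
        sim.run_rebinding(n_cycles_rebinding, cycle_steps_rebinding,
                          np.random.default_rng([seed, 1, i]),
                          unbinding_exit_points=pool,
                          burn_in_cycles=burn_in_rebinding, replicate_id=i)
        for i in range(n_rebinding_replicates)
    ]
    return unb, reb
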