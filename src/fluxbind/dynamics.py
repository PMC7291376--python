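"""Langevin dynamics via BAOAB splitting.

The continuous Langevin equation  m dv = -grad U dt - m gamma v dt +
sqrt(2 m gamma kT) dW  is discretised with the BAOAB scheme (half kick,
half drift, exact Ornstein-Uhlenbeck update, half drift, half kick):

    v <- v + (dt/2) F(x)/m
    x <- x + (dt/2) v
    v <- c1 v + c2 xi,   c1 = exp(-gamma dt),  c2 = sqrt((1 - c1^2) kT/m)
    x <- x + (dt/2) v
    v <- v + (dt/2) F(x)/m

with xi a standard normal vector.  BAOAB gives very accurate configurational
averages at practical timesteps and reduces to velocity Verlet as gamma -> 0.

Two implementations are provided: a generic NumPy step (`baoab_step`) that
accepts any force callback, and a fused toy-system propagator (`propagate`)
whose inner loop is JIT-compiled with numba when available.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .exceptions import IntegrationError
from .toy_system import SystemState, ToySystemParams, force as toy_force, wrap_positions
from .units import KB_INTERNAL, KCAL_TO_INTERNAL

__all__ = ["baoab_step", "step_langevin", "propagate", "TrajectoryRecord"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


def baoab_step(
    positions: np.ndarray,
    velocities: np.ndarray,
    force_fn: Callable[[np.ndarray], np.ndarray],
    mass: float,
    dt: float,
    gamma: float,
    temperature: float,
    rng: np.random.Generator,
    box_lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One BAOAB step for an arbitrary (vectorised) force field.

    ``force_fn`` maps positions (..., 3) to forces in kcal/(mol nm); masses in
    amu, dt in ps, gamma in 1/ps.  Returns new (positions, velocities).  With
    gamma = 0 the noise term vanishes and the update is velocity Verlet.
    """
    f_scale = KCAL_TO_INTERNAL / mass
    kT_int = KB_INTERNAL * temperature
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1)) * kT_int / mass)

    v = velocities + 0.5 * dt * force_fn(positions) * f_scale
    x = positions + 0.5 * dt * v
    if c2 > 0:
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    else:
        v = c1 * v
    x = x + 0.5 * dt * v
    if box_lengths is not None:
        x = wrap_positions(x, box_lengths)
    v = v + 0.5 * dt * force_fn(x) * f_scale
    return x, v


def step_langevin(
    state: SystemState, params: ToySystemParams, rng: np.random.Generator
) -> SystemState:
    """Advance one toy-system state by one timestep tau."""

    def _f(x: np.ndarray) -> np.ndarray:
        return toy_force(SystemState(x, np.zeros(3), state.time), params)

    x, v = baoab_step(
        state.position,
        state.velocity,
        _f,
        params.guest_mass,
        params.timestep,
        params.friction,
        params.temperature,
        rng,
        params.box_lengths,
    )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise IntegrationError(
            f"non-finite state after step from position {state.position}, "
            f"velocity {state.velocity}"
        )
    return SystemState(x, v, state.time + params.timestep)


@njit(cache=True)
def _baoab_toy_kernel(
    pos, vel, frc, noise, box, host,
    a, depth, sigma, kwall, cpre, mass, c1, c2, dt, stride, rec_r, rec_v2, rec_off,
    dest_mode, bound_cut, unbound_cut, cross_step, step_offset,
):  # pragma: no cover - compiled
    # dest_mode: 0 none, 1 absorb on unbound entry (r - a > unbound_cut),
    # 2 absorb on bound entry (|r - a| < bound_cut).  cross_step[i] >= 0
    # freezes walker i (it is skipped until reset by the caller).
    n_steps = noise.shape[0]
    n = pos.shape[0]
    fs = 4.184 / mass  # kcal/(mol nm) -> nm/ps^2
    half = 0.5 * dt
    two_s2 = 2.0 * sigma * sigma
    nrec = rec_off
    for s in range(n_steps):
        for i in range(n):
            if dest_mode != 0 and cross_step[i] >= 0:
                continue
            # B (half kick with cached force) + A (half drift)
            for k in range(3):
                vel[i, k] += half * frc[i, k] * fs
                pos[i, k] += half * vel[i, k]
            # O (exact OU update)
            for k in range(3):
                vel[i, k] = c1 * vel[i, k] + c2 * noise[s, i, k]
            # A (half drift) + wrap
            for k in range(3):
                pos[i, k] += half * vel[i, k]
                pos[i, k] -= box[k] * np.floor(pos[i, k] / box[k])
            # force at the new position
            r2 = 0.0
            dx = 0.0
            dy = 0.0
            dz = 0.0
            for k in range(3):
                d = pos[i, k] - host[k]
                d -= box[k] * np.floor(d / box[k] + 0.5)
                if k == 0:
                    dx = d
                elif k == 1:
                    dy = d
                else:
                    dz = d
                r2 += d * d
            r = np.sqrt(r2)
            if r < 1e-12:
                r = 1e-12
            dr = r - a
            dudr = depth * dr / (sigma * sigma) * np.exp(-dr * dr / two_s2)
            if r < a:
                dudr += 2.0 * kwall * dr
            dudr -= cpre / r2
            g = -dudr / r
            frc[i, 0] = g * dx
            frc[i, 1] = g * dy
            frc[i, 2] = g * dz
            # B (half kick with new force)
            for k in range(3):
                vel[i, k] += half * frc[i, k] * fs
            if dest_mode == 1 and r - a > unbound_cut:
                cross_step[i] = step_offset + s
            elif dest_mode == 2 and np.abs(r - a) < bound_cut:
                cross_step[i] = step_offset + s
        if stride > 0 and (s + 1) % stride == 0:
            for i in range(n):
                rr = 0.0
                vv = 0.0
                for k in range(3):
                    d = pos[i, k] - host[k]
                    d -= box[k] * np.floor(d / box[k] + 0.5)
                    rr += d * d
                    vv += vel[i, k] * vel[i, k]
                rec_r[nrec, i] = np.sqrt(rr)
                rec_v2[nrec, i] = vv
            nrec += 1
    return nrec


class TrajectoryRecord:
    """Per-stride observations from `propagate`: host-guest distances ``r``
    and squared speeds ``v2``, each with shape (n_records, n_walkers)."""

    def __init__(self, r: np.ndarray, v2: np.ndarray, dt_record: float):
        self.r = r
        self.v2 = v2
        self.dt_record = dt_record


def _initial_forces(pos: np.ndarray, params: ToySystemParams) -> np.ndarray:
    from .toy_system import minimum_image_displacement, radial_potential_derivative

    disp, dist = minimum_image_displacement(pos, params.host_position, params.box_lengths)
    dist = np.atleast_1d(dist)
    dudr = radial_potential_derivative(dist, params)
    return -(dudr / dist)[:, None] * disp


def propagate(
    positions: np.ndarray,
    velocities: np.ndarray,
    params: ToySystemParams,
    n_steps: int,
    rng: np.random.Generator,
    record_stride: int = 0,
    chunk: int = 20000,
    absorb: tuple[str, float, float] | None = None,
):
    """Propagate an array of independent toy-system walkers in place.

    ``positions`` and ``velocities`` are (N, 3) arrays updated in place.
    Noise is drawn from ``rng`` in chunks so arbitrarily long runs use bounded
    memory.  If ``record_stride`` > 0, the host-guest distance and squared
    speed of every walker are recorded every ``record_stride`` steps and
    returned as a `TrajectoryRecord`.

    With ``absorb = (destination, bound_cutoff, unbound_cutoff)`` the basin
    entry condition is checked after every dynamics step; a walker that
    enters the destination basin is frozen at the crossing configuration.
    The return value is then ``(record, cross_step)`` where cross_step[i] is
    the 0-based step index of walker i's crossing, or -1 if it never crossed.

    Raises
    ------
    IntegrationError
        If any coordinate or velocity becomes non-finite.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    vel = np.ascontiguousarray(velocities, dtype=np.float64)
    n = pos.shape[0]
    dt = params.timestep
    c1 = float(np.exp(-params.friction * dt))
    kT_int = KB_INTERNAL * params.temperature
    c2 = float(np.sqrt(max(0.0, 1.0 - c1 * c1) * kT_int / params.guest_mass))
    frc = _initial_forces(pos, params)

    if record_stride > 0:
        n_rec_total = n_steps // record_stride
    else:
        n_rec_total = 0
    rec_r = np.empty((max(n_rec_total, 1), n))
    rec_v2 = np.empty((max(n_rec_total, 1), n))

    if record_stride > 0 and chunk % record_stride != 0:
        chunk = (chunk // record_stride) * record_stride or record_stride

    if absorb is None:
        dest_mode, b_cut, u_cut = 0, 0.0, 0.0
    else:
        dest, b_cut, u_cut = absorb
        dest_mode = 1 if dest == "unbound" else 2
    cross_step = np.full(n, -1, dtype=np.int64)

    done = 0
    rec_off = 0
    while done < n_steps:
        this = min(chunk, n_steps - done)
        if record_stride > 0:
            this = min(this, (n_rec_total * record_stride) - done) or this
        noise = rng.standard_normal((this, n, 3))
        rec_off = _baoab_toy_kernel(
            pos, vel, frc, noise,
            np.ascontiguousarray(params.box_lengths),
            np.ascontiguousarray(params.host_position),
            params.host_radius, params.well_depth, params.well_width,
            params.wall_strength, params.coulomb_prefactor, params.guest_mass,
            c1, c2, dt, record_stride, rec_r, rec_v2, rec_off,
            dest_mode, b_cut, u_cut, cross_step, done,
        )
        done += this
        if dest_mode != 0 and np.all(cross_step >= 0):
            break
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
            bad = np.where(~np.all(np.isfinite(pos), axis=1))[0]
            raise IntegrationError(
                f"non-finite coordinates for walker(s) {bad.tolist()} after "
                f"{done} steps (dt={dt} ps); reduce the timestep"
            )

    positions[...] = pos
    velocities[...] = vel
    rec = None
    if record_stride > 0:
        rec = TrajectoryRecord(rec_r[:rec_off], rec_v2[:rec_off],
                               dt_record=record_stride * dt)
    if absorb is not None:
        return rec, cross_step
    return rec
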