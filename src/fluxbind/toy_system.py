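"""Synthetic host-guest system.

A single point guest with charge Q_g diffuses in a periodic box around a fixed
charged host (a sphere of radius ``host_radius`` at the box centre).  The
interaction potential has three radial parts, all functions of the
minimum-image host-guest distance r:

* a short-range binding well  -D * exp(-(r - a)^2 / (2 sigma^2)),
  producing a single metastable bound state on the shell r = a;
* a soft harmonic core wall  k_w * (r - a)^2  for r < a (zero value and zero
  slope at r = a, so the total is C^1 everywhere); the wall is deliberately
  soft enough that its vibrational period is well resolved at 10 fs
  timesteps -- a stiff power-law core pumps heat into weakly thermostatted
  (low gamma) dynamics through unresolved bounces;
* a screened Coulomb term  k_C * Q_h * Q_g / (eps_r * r)  with the solvent
  treated as a uniform dielectric of permittivity ``epsilon_w``.

With like-signed charges (the study case) the Coulomb term is repulsive
everywhere, so the finite-at-origin wall cannot be overwhelmed; strongly
attractive opposite charges would need a harder core.

All energies are kcal/mol, lengths nm, times ps, masses amu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .exceptions import InvalidInputError, SingularityError
from .units import COULOMB_KCAL_NM, EPSILON_0, KB_INTERNAL, KB_KCAL

__all__ = [
    "ToySystemParams",
    "SystemState",
    "minimum_image_displacement",
    "coulomb_interaction_energy",
    "potential_energy",
    "force",
    "kinetic_temperature",
    "maxwell_boltzmann_velocities",
    "wrap_positions",
]

#: Guests closer to the host centre than this fraction of the core radius are
#: treated as singular configurations.
_CORE_GUARD = 1.0e-3


@dataclass(frozen=True)
class ToySystemParams:
    """Geometry, charges, well shape and thermostat parameters of the toy system.

    Parameters
    ----------
    box_lengths : (3,) array, nm
        Periodic box edges.
    host_radius : float, nm
        Radius ``a`` of the host core; the binding well minimum sits on the
        shell r = a (the "native" radius).
    guest_mass : float, amu
    guest_charge, host_charge : float, e
        Like signs give a repulsive residual interaction, mirroring an
        anionic guest binding a negatively charged host cavity.
    well_depth : float, kcal/mol (> 0 means attractive)
    well_width : float, nm
        Gaussian width ``sigma`` of the binding well.
    wall_strength : float, kcal/mol
        Prefactor of the repulsive core wall.
    epsilon_w : float, F/m
        Solvent permittivity (water at 300 K by default).
    temperature : float, K
    friction : float, 1/ps
        Langevin friction coefficient gamma.
    timestep : float, ps
    """

    box_lengths: np.ndarray = field(
        default_factory=lambda: np.array([4.28, 4.33, 4.33])
    )
    host_position: np.ndarray | None = None
    host_radius: float = 0.3
    guest_mass: float = 116.0
    guest_charge: float = -1.0
    host_charge: float = -1.0
    well_depth: float = 4.0
    # a wide binding funnel relative to the 0.1 nm bound-basin cutoff, so the
    # basin boundary lies deep inside the attraction zone and entries commit,
    # mirroring the geometry of a real host cavity
    well_width: float = 0.2
    # harmonic core stiffness, kcal/(mol nm^2); ~11 kcal/mol of exclusion at
    # half the core radius while omega*tau stays < 0.1 at 10 fs steps
    wall_strength: float = 500.0
    epsilon_w: float = 6.88e-10
    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 0.002

    def __post_init__(self) -> None:
        box = np.asarray(self.box_lengths, dtype=float)
        object.__setattr__(self, "box_lengths", box)
        host = self.host_position
        if host is None:
            host = box / 2.0
        object.__setattr__(self, "host_position", np.asarray(host, dtype=float))
        problems = []
        if box.shape != (3,) or not np.all(box > 0):
            problems.append(f"box_lengths must be 3 positive values, got {box}")
        if not self.well_width > 0:
            problems.append("well_width must be > 0")
        if not self.timestep > 0:
            problems.append("timestep must be > 0")
        if self.friction < 0:
            problems.append("friction must be >= 0")
        if not self.temperature > 0:
            problems.append("temperature must be > 0")
        if not self.host_radius > 0:
            problems.append("host_radius must be > 0")
        if not self.guest_mass > 0:
            problems.append("guest_mass must be > 0")
        if not self.epsilon_w > 0:
            problems.append("epsilon_w must be > 0")
        if not self.wall_strength >= 0:
            problems.append("wall_strength must be >= 0")
        if box.shape == (3,) and np.all(box > 0):
            if self.host_radius + self.well_width >= float(np.min(box)) / 2.0:
                problems.append(
                    "host_radius + well_width must be < min(box_lengths)/2 "
                    "for minimum-image validity"
                )
        if problems:
            raise InvalidInputError("; ".join(problems))

    @property
    def epsilon_r(self) -> float:
        """Relative permittivity eps_w / eps_0 (about 77.7 for water at 300 K)."""
        return self.epsilon_w / EPSILON_0

    @property
    def coulomb_prefactor(self) -> float:
        """k_C * Q_h * Q_g / eps_r in kcal nm / mol; E_coul(r) = prefactor / r."""
        return COULOMB_KCAL_NM * self.host_charge * self.guest_charge / self.epsilon_r

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def native_radius(self) -> float:
        """Host-guest distance of the bound (native) pose: the well minimum."""
        return self.host_radius

    @property
    def volume(self) -> float:
        return float(np.prod(self.box_lengths))

    def bound_start_state(self) -> "SystemState":
        """Canonical bound starting structure: guest on the native shell, +x."""
        pos = self.host_position + np.array([self.native_radius, 0.0, 0.0])
        return SystemState(position=wrap_positions(pos, self.box_lengths),
                           velocity=np.zeros(3), time=0.0)

    def with_(self, **kw) -> "ToySystemParams":
        return replace(self, **kw)


@dataclass
class SystemState:
    """Instantaneous guest state: position (nm, wrapped into the primary box
    image), velocity (nm/ps) and simulation time (ps)."""

    position: np.ndarray
    velocity: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time < 0:
            raise InvalidInputError(f"time must be >= 0, got {self.time}")

    def copy(self) -> "SystemState":
        return SystemState(self.position.copy(), self.velocity.copy(), self.time)


def wrap_positions(positions: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary image [0, L)."""
    box = np.asarray(box_lengths, dtype=float)
    return np.mod(positions, box)


def minimum_image_displacement(
    r_i: np.ndarray, r_j: np.ndarray, box_lengths: np.ndarray
) -> tuple[np.ndarray, float]:
    """Displacement r_i - r_j to the nearest periodic image, and its norm.

    Each component of the returned displacement lies in [-L/2, L/2).
    Broadcasts over leading axes; the distance is the Euclidean norm taken
    over the final axis.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    box = np.asarray(box_lengths, dtype=float)
    if not (np.all(np.isfinite(r_i)) and np.all(np.isfinite(r_j))):
        raise InvalidInputError("non-finite coordinates in minimum_image_displacement")
    if not np.all(box > 0):
        raise InvalidInputError(f"box_lengths must be positive, got {box}")
    disp = r_i - r_j
    disp = disp - box * np.floor(disp / box + 0.5)
    dist = np.linalg.norm(disp, axis=-1)
    return disp, float(dist) if np.ndim(dist) == 0 else dist


def coulomb_interaction_energy(
    positions_pair: Iterable[np.ndarray],
    charges_pair: Iterable[float],
    epsilon_w: float,
    box_lengths: np.ndarray,
) -> float:
    """Screened Coulomb energy between two point charges, kcal/mol.

    E = k_C Q_i Q_j / (eps_r r) with the distance taken under the minimum
    image convention and eps_r = epsilon_w / epsilon_0.
    """
    r_i, r_j = positions_pair
    q_i, q_j = charges_pair
    _, dist = minimum_image_displacement(r_i, r_j, box_lengths)
    if dist <= 0:
        raise SingularityError("Coulomb energy diverges at zero separation")
    eps_r = epsilon_w / EPSILON_0
    return COULOMB_KCAL_NM * q_i * q_j / (eps_r * dist)


# -- radial potential pieces (vectorised over r) -----------------------------

def _well_energy(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    a, s = params.host_radius, params.well_width
    return -params.well_depth * np.exp(-((r - a) ** 2) / (2.0 * s * s))


def _well_derivative(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    a, s = params.host_radius, params.well_width
    return params.well_depth * (r - a) / (s * s) * np.exp(-((r - a) ** 2) / (2.0 * s * s))


def _wall_energy(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    a = params.host_radius
    dr = np.minimum(r - a, 0.0)
    return params.wall_strength * dr * dr


def _wall_derivative(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    a = params.host_radius
    dr = np.minimum(r - a, 0.0)
    return 2.0 * params.wall_strength * dr


def radial_potential(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    """Total potential U(r) in kcal/mol as a function of host-guest distance."""
    r = np.asarray(r, dtype=float)
    coul = params.coulomb_prefactor / np.maximum(r, 1e-12)
    return _well_energy(r, params) + _wall_energy(r, params) + coul


def radial_potential_derivative(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    """dU/dr in kcal/(mol nm)."""
    r = np.asarray(r, dtype=float)
    coul = -params.coulomb_prefactor / np.maximum(r, 1e-12) ** 2
    return _well_derivative(r, params) + _wall_derivative(r, params) + coul


def radial_potential_no_coulomb(r: np.ndarray, params: ToySystemParams) -> np.ndarray:
    """U*(r): the potential with host-guest electrostatics removed."""
    r = np.asarray(r, dtype=float)
    return _well_energy(r, params) + _wall_energy(r, params)


def _guard_distance(dist: float, params: ToySystemParams) -> None:
    if dist < params.host_radius * _CORE_GUARD:
        raise SingularityError(
            f"guest at r = {dist:.3g} nm is inside the host core guard radius"
        )


def host_guest_distance(state: SystemState, params: ToySystemParams) -> float:
    """Minimum-image distance between guest and host centre, nm."""
    _, dist = minimum_image_displacement(state.position, params.host_position,
                                         params.box_lengths)
    return float(dist)


def native_distance(state: SystemState, params: ToySystemParams) -> float:
    """Radial deviation from the native (well-minimum) shell: |r - a|, nm."""
    return abs(host_guest_distance(state, params) - params.native_radius)


def clearance(state: SystemState, params: ToySystemParams) -> float:
    """Host-guest surface clearance r - a, nm (negative inside the core)."""
    return host_guest_distance(state, params) - params.host_radius


def potential_energy(state: SystemState, params: ToySystemParams) -> float:
    """Total potential energy of the guest, kcal/mol."""
    dist = host_guest_distance(state, params)
    _guard_distance(dist, params)
    return float(radial_potential(dist, params))


def interaction_energy(state: SystemState, params: ToySystemParams) -> float:
    """Host-guest electrostatic energy E_int = U - U*, kcal/mol."""
    dist = host_guest_distance(state, params)
    _guard_distance(dist, params)
    return params.coulomb_prefactor / dist


def force(state: SystemState, params: ToySystemParams) -> np.ndarray:
    """Force on the guest, -grad U, in kcal/(mol nm)."""
    disp, dist = minimum_image_displacement(state.position, params.host_position,
                                            params.box_lengths)
    _guard_distance(dist, params)
    dudr = float(radial_potential_derivative(dist, params))
    return -dudr * disp / dist


def kinetic_temperature(velocity_samples: np.ndarray, mass: float) -> float:
    """Instantaneous/ensemble kinetic temperature in K.

    T = m <|v|^2> / (3 k_B) with v in nm/ps and m in amu, using k_B in the
    internal (kJ/mol) energy unit so the amu nm^2/ps^2 kinetic energy needs no
    further conversion.
    """
    v = np.asarray(velocity_samples, dtype=float)
    if v.size == 0:
        raise InvalidInputError("kinetic_temperature requires at least one sample")
    v = v.reshape(-1, 3)
    mean_v2 = float(np.mean(np.sum(v * v, axis=1)))
    return mass * mean_v2 / (3.0 * KB_INTERNAL)


def maxwell_boltzmann_velocities(
    n: int, mass: float, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n velocity vectors (nm/ps) from the Maxwell-Boltzmann distribution."""
    sigma = np.sqrt(KB_INTERNAL * temperature / mass)
    return rng.normal(0.0, sigma, size=(n, 3))


def equilibrium_positions(
    params: ToySystemParams, n: int, rng: np.random.Generator,
    max_batches: int = 2000,
) -> np.ndarray:
    """Draw n guest positions from the Boltzmann distribution e^{-beta U}.

    Rejection sampling against a uniform proposal over the box; exact for the
    radial toy potential.  Useful for starting simulations in configurational
    equilibrium (e.g. thermostat checks, where a non-equilibrium start would
    exchange heat with the thermostat for many relaxation times).
    """
    beta = 1.0 / (KB_KCAL * params.temperature)
    # envelope: the global minimum of U over sampleable radii
    rr = np.linspace(params.host_radius * 1e-2, float(np.min(params.box_lengths)),
                     20000)
    log_env = -beta * float(np.min(radial_potential(rr, params)))
    out = np.empty((n, 3))
    have = 0
    for _ in range(max_batches):
        m = max(4 * n, 1000)
        pts = rng.uniform(0.0, 1.0, (m, 3)) * params.box_lengths
        disp = pts - params.host_position
        disp -= params.box_lengths * np.floor(disp / params.box_lengths + 0.5)
        r = np.linalg.norm(disp, axis=1)
        r = np.maximum(r, params.host_radius * 1e-2)
        log_w = -beta * radial_potential(r, params) - log_env
        keep = np.log(rng.random(m)) < log_w
        take = min(int(np.sum(keep)), n - have)
        out[have:have + take] = pts[keep][:take]
        have += take
        if have == n:
            return out
    raise InvalidInputError("rejection sampling failed to converge")
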