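"""Independent brute-force references for everything the pipeline estimates.

For the point-guest toy system the configurational integrals reduce to three
dimensions, so equilibrium populations, the binding constant, the exponential
(FEP) average and the unbound volume can all be computed by deterministic
quadrature, and rates by direct unresampled simulation.  These references
never share code paths with the flux/correction estimators they check.

Geometry handling: integrals over regions inside the inscribed sphere use
plain radial quadrature with the 4 pi r^2 shell weight.  Regions reaching the
box corners use an exact angular decomposition: for each direction the ray
from the host exits the box at R(omega) = min_k (L_k/2)/|n_k|, so

    int_box g(|x|) d^3x = int dOmega int_0^{R(omega)} g(r) r^2 dr

which is evaluated with a midpoint grid over one octant of (cos theta, phi)
and an interpolated radial primitive G(r) = int g r^2 dr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .ensembles import BasinSpec
from .exceptions import InvalidInputError
from .toy_system import (
    ToySystemParams,
    radial_potential,
    radial_potential_no_coulomb,
)
from .units import NM3_PER_MOLECULE_AT_1M, PS_TO_S_RATE, UnitsContext, concentration_from_volume

__all__ = [
    "QuadratureSpec",
    "ReferenceResult",
    "equilibrium_quadrature",
    "fep_term_quadrature",
    "v_unbound_quadrature",
    "brute_force_rates",
    "box_restricted_integral",
]


@dataclass(frozen=True)
class QuadratureSpec:
    """Grid resolution for the quadrature references.

    radial_resolution: radial step, nm (results must be converged: halving it
    changes outputs by < 0.1%).  n_angle: midpoint-grid points per angular
    dimension on the octant.  max_radius: upper radial cut for the purely
    radial integrals (defaults to the inscribed-sphere radius).
    """

    radial_resolution: float = 5.0e-4
    n_angle: int = 160
    max_radius: float | None = None
    scheme: str = "trapezoid"

    def __post_init__(self) -> None:
        if not self.radial_resolution > 0:
            raise InvalidInputError("radial_resolution must be > 0")
        if self.n_angle < 4:
            raise InvalidInputError("n_angle must be >= 4")

    def refined(self) -> "QuadratureSpec":
        return QuadratureSpec(self.radial_resolution / 2.0, self.n_angle * 2,
                              self.max_radius, self.scheme)


@dataclass
class ReferenceResult:
    """Quadrature reference values for one parameterisation."""

    p_bound: float
    p_unbound: float
    keq_nm3: float
    dg_ref: float
    fep_ratio: float
    v_ratio_ref: float
    convergence: dict = field(default_factory=dict)


def _radial_table(
    g_of_r: Callable[[np.ndarray], np.ndarray],
    r_max: float,
    h: float,
    r_min: float = 1.0e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial grid and primitive G(r) = int_0^r g(r') r'^2 dr'."""
    n = max(int(np.ceil((r_max - r_min) / h)), 16)
    r = np.linspace(r_min, r_max, n + 1)
    g = g_of_r(r) * r * r
    big = np.concatenate([[0.0], cumulative_trapezoid(g, r)])
    return r, big


def _octant_exit_radii(box: np.ndarray, n_angle: int) -> tuple[np.ndarray, float]:
    """Per-direction box-exit radii R(omega) on a midpoint octant grid, and
    the solid-angle weight of each direction."""
    u = (np.arange(n_angle) + 0.5) / n_angle  # cos(theta) in (0, 1)
    phi = (np.arange(n_angle) + 0.5) / n_angle * (np.pi / 2.0)
    uu, pp = np.meshgrid(u, phi, indexing="ij")
    st = np.sqrt(1.0 - uu * uu)
    n_x = st * np.cos(pp)
    n_y = st * np.sin(pp)
    n_z = uu
    half = box / 2.0
    with np.errstate(divide="ignore"):
        r_exit = np.minimum.reduce([
            np.where(n_x > 0, half[0] / n_x, np.inf),
            np.where(n_y > 0, half[1] / n_y, np.inf),
            np.where(n_z > 0, half[2] / n_z, np.inf),
        ])
    # octant weight: full solid angle = 8 * (pi/2) * 1, midpoint cells
    w = 8.0 * (np.pi / 2.0) / (n_angle * n_angle)
    return r_exit.ravel(), w


def box_restricted_integral(
    g_of_r: Callable[[np.ndarray], np.ndarray],
    box_lengths: np.ndarray,
    r_lower: float = 0.0,
    spec: QuadratureSpec | None = None,
) -> float:
    """int over the box (host at centre) of g(|x|) d^3x, restricted to
    |x| > r_lower.  Exact in the box geometry up to grid resolution."""
    spec = spec or QuadratureSpec()
    box = np.asarray(box_lengths, dtype=float)
    r_diag = float(np.linalg.norm(box / 2.0))
    r, big = _radial_table(g_of_r, r_diag, spec.radial_resolution)
    r_exit, w = _octant_exit_radii(box, spec.n_angle)
    upper = np.interp(r_exit, r, big)
    lower = np.interp(r_lower, r, big) if r_lower > 0 else 0.0
    vals = np.maximum(upper - lower, 0.0)
    return float(np.sum(vals) * w)


def _shell_integral(
    g_of_r: Callable[[np.ndarray], np.ndarray],
    r_lo: float,
    r_hi: float,
    h: float,
) -> float:
    """4 pi int_{r_lo}^{r_hi} g(r) r^2 dr (must lie inside the inscribed sphere)."""
    n = max(int(np.ceil((r_hi - r_lo) / h)), 64)
    r = np.linspace(r_lo, r_hi, n + 1)
    return float(4.0 * np.pi * np.trapezoid(g_of_r(r) * r * r, r))


def _check_geometry(params: ToySystemParams, basin: BasinSpec) -> tuple[float, float, float]:
    box = params.box_lengths
    r_half = float(np.min(box)) / 2.0
    r_ex = params.host_radius + basin.unbound_cutoff
    r_b_hi = params.native_radius + basin.bound_cutoff
    if r_b_hi >= r_half:
        raise InvalidInputError("bound basin must lie inside the inscribed sphere")
    if r_ex >= r_half:
        raise InvalidInputError(
            "unbound boundary must lie inside the inscribed sphere"
        )
    return r_half, r_ex, r_b_hi


def _core_results(
    params: ToySystemParams, basin: BasinSpec, spec: QuadratureSpec
) -> dict:
    _, r_ex, r_b_hi = _check_geometry(params, basin)
    h = spec.radial_resolution
    units = UnitsContext(temperature=params.temperature)
    beta = units.beta

    def g(r):
        return np.exp(-beta * radial_potential(r, params))

    def g_star(r):
        return np.exp(-beta * radial_potential_no_coulomb(r, params))

    r_b_lo = max(params.native_radius - basin.bound_cutoff, 1e-4)
    i_bound = _shell_integral(g, r_b_lo, r_b_hi, h)
    i_total = box_restricted_integral(g, params.box_lengths, 0.0, spec)
    i_unb = box_restricted_integral(g, params.box_lengths, r_ex, spec)
    i_unb_star = box_restricted_integral(g_star, params.box_lengths, r_ex, spec)

    v_box = params.volume
    v_unb = v_box - (4.0 * np.pi / 3.0) * r_ex**3  # exclusion sphere fits the box

    keq = i_bound  # bulk reference: non-interacting point guest, e^{-beta U_G} = 1
    dg_ref = -units.kT * np.log(keq / NM3_PER_MOLECULE_AT_1M * units.C0)
    return {
        "p_bound": i_bound / i_total,
        "p_unbound": i_unb / i_total,
        "keq_nm3": keq,
        "dg_ref": float(dg_ref),
        "fep_ratio": i_unb_star / i_unb,
        "v_ratio_ref": v_unb / v_box,
        "i_unb_star": i_unb_star,
        "v_unb": v_unb,
    }


def equilibrium_quadrature(
    params: ToySystemParams,
    basin_spec: BasinSpec,
    quad_spec: QuadratureSpec | None = None,
    check_convergence: bool = False,
) -> ReferenceResult:
    """Equilibrium populations, K_eq and the reference dG by quadrature.

    K_eq follows the dilute-solution expression: the numerator integrates
    e^{-beta U} over the bound basin; the denominator fixes the guest at a
    bulk (non-interacting) position, where e^{-beta U_G} = 1 for the point
    guest, so the choice of bulk position is immaterial.
    """
    spec = quad_spec or QuadratureSpec()
    res = _core_results(params, basin_spec, spec)
    conv = {}
    if check_convergence:
        fine = _core_results(params, basin_spec, spec.refined())
        conv = {
            "dg_ref_delta": abs(fine["dg_ref"] - res["dg_ref"]),
            "p_ratio_rel_delta": abs(
                fine["p_bound"] / fine["p_unbound"]
                / (res["p_bound"] / res["p_unbound"]) - 1.0
            ),
        }
    return ReferenceResult(
        p_bound=res["p_bound"],
        p_unbound=res["p_unbound"],
        keq_nm3=res["keq_nm3"],
        dg_ref=res["dg_ref"],
        fep_ratio=res["fep_ratio"],
        v_ratio_ref=res["v_ratio_ref"],
        convergence=conv,
    )


def fep_term_quadrature(
    params: ToySystemParams,
    basin_spec: BasinSpec,
    quad_spec: QuadratureSpec | None = None,
) -> float:
    """<e^{beta E_int}>_unb by quadrature: the ratio of unbound-region
    configurational integrals with (U) and without (U*) the host-guest
    Coulomb term.  Equals 1 exactly for zero charges."""
    res = _core_results(params, basin_spec, quad_spec or QuadratureSpec())
    return float(res["fep_ratio"])


def v_unbound_quadrature(
    params: ToySystemParams,
    basin_spec: BasinSpec,
    quad_spec: QuadratureSpec | None = None,
) -> float:
    """Exact geometric V_unbound/V_box for the point guest.

    Closed form (box minus exclusion sphere) when the exclusion sphere fits
    inside the inscribed sphere; angular-decomposition quadrature otherwise.
    """
    box = params.box_lengths
    r_ex = params.host_radius + basin_spec.unbound_cutoff
    v_box = params.volume
    if r_ex <= float(np.min(box)) / 2.0:
        return float((v_box - (4.0 * np.pi / 3.0) * r_ex**3) / v_box)
    spec = quad_spec or QuadratureSpec()
    v_unb = box_restricted_integral(lambda r: np.ones_like(r), box, r_ex, spec)
    return float(v_unb / v_box)


def brute_force_rates(
    params: ToySystemParams,
    basin_spec: BasinSpec,
    n_events: int,
    rng: np.random.Generator,
    n_walkers: int = 16,
    round_time_ps: float = 2000.0,
    max_rounds: int = 50,
    record_stride: int = 5,
) -> dict:
    """Rates from unresampled long trajectories via first-passage counting.

    Walkers start in the bound pose and run plain Langevin dynamics; each
    trajectory's history label (last basin visited) is tracked, and the mean
    first passage times bound->unbound and unbound->bound give
    k_off = 1/MFPT_off and k_on = 1/(MFPT_on * C) with C the box
    concentration.  Runs in rounds until both directions have at least
    ``n_events`` completed passages (or ``max_rounds`` is exhausted).

    The same trajectories also yield the label-conditioned basin fractions
    f_b (time inside the bound basin / time labeled bound) and f_u, plus the
    equilibrium basin-probability ratio p_b/p_u = (T_b f_b)/(T_u f_u), an
    exact identity for history-labeled equilibrium trajectories that can be
    checked directly against quadrature.

    Returns a dict with k_off, k_on (1/s, 1/(M s)), their SEMs, event counts,
    the MFPTs (ps), f_b_labeled, f_u_labeled, and p_ratio (+ SEM over
    walkers).
    """
    from .dynamics import propagate
    from .ensembles import classify_distances
    from .toy_system import maxwell_boltzmann_velocities

    basin_spec.validate_against(params)
    start = params.bound_start_state()
    pos = np.tile(start.position, (n_walkers, 1))
    vel = maxwell_boltzmann_velocities(n_walkers, params.guest_mass,
                                       params.temperature, rng)
    dt_rec = record_stride * params.timestep
    steps_per_round = int(round(round_time_ps / params.timestep))

    dur_off: list[float] = []
    dur_on: list[float] = []
    # per-walker label state carried across rounds: label code (0 bound, 2
    # unbound) and time since the label was last (re)entered
    label = np.zeros(n_walkers, dtype=np.int8)
    t_in_label = np.zeros(n_walkers)
    # per-walker occupation bookkeeping: [T_bound_label, T_b_in_basin,
    # T_unbound_label, T_u_in_basin]
    occ = np.zeros((n_walkers, 4))

    for _ in range(max_rounds):
        rec = propagate(pos, vel, params, steps_per_round, rng,
                        record_stride=record_stride)
        codes = classify_distances(rec.r, basin_spec, params)  # (n_rec, n_walkers)
        for i in range(n_walkers):
            c = codes[:, i]
            lab = label[i]
            t_acc = t_in_label[i]
            for code in c:
                t_acc += dt_rec
                if lab == 0:
                    occ[i, 0] += dt_rec
                    if code == 0:
                        occ[i, 1] += dt_rec
                else:
                    occ[i, 2] += dt_rec
                    if code == 2:
                        occ[i, 3] += dt_rec
                if code == 1 or code == lab:
                    continue
                if lab == 0 and code == 2:
                    dur_off.append(t_acc)
                elif lab == 2 and code == 0:
                    dur_on.append(t_acc)
                lab = code
                t_acc = 0.0
            label[i] = lab
            t_in_label[i] = t_acc
        if len(dur_off) >= n_events and len(dur_on) >= n_events:
            break

    conc = concentration_from_volume(params.volume)
    out = {"n_off_events": len(dur_off), "n_on_events": len(dur_on),
           "concentration_M": conc}
    tot = occ.sum(axis=0)
    out["f_b_labeled"] = tot[1] / tot[0] if tot[0] > 0 else float("nan")
    out["f_u_labeled"] = tot[3] / tot[2] if tot[2] > 0 else float("nan")
    if tot[3] > 0:
        out["p_ratio"] = float(tot[1] / tot[3])
        # jackknife over walkers of the pooled ratio
        if n_walkers >= 2:
            jk = np.array([
                (tot[1] - occ[i, 1]) / (tot[3] - occ[i, 3])
                for i in range(n_walkers)
                if tot[3] - occ[i, 3] > 0
            ])
            nj = len(jk)
            out["p_ratio_sem"] = float(
                np.sqrt((nj - 1) / nj * np.sum((jk - np.mean(jk)) ** 2))
            ) if nj >= 2 else float("nan")
        else:
            out["p_ratio_sem"] = float("nan")
    else:
        out["p_ratio"] = float("nan")
        out["p_ratio_sem"] = float("nan")
    for name, durs, div in (("off", dur_off, 1.0), ("on", dur_on, conc)):
        if durs:
            m = float(np.mean(durs))
            sem_m = float(np.std(durs, ddof=1) / np.sqrt(len(durs))) if len(durs) > 1 else float("nan")
            k = 1.0 / m / div * PS_TO_S_RATE
            out[f"k_{name}"] = k
            out[f"k_{name}_sem"] = k * sem_m / m if m > 0 else float("nan")
            out[f"mfpt_{name}_ps"] = m
        else:
            out[f"k_{name}"] = 0.0
            out[f"k_{name}_sem"] = float("nan")
            out[f"mfpt_{name}_ps"] = float("inf")
    return out


def first_passage_mfpt(
    params: ToySystemParams,
    basin_spec: BasinSpec,
    start_state,
    destination: str,
    n_passages: int,
    rng: np.random.Generator,
    n_walkers: int = 16,
    chunk_time_ps: float = 500.0,
    max_chunks: int = 400,
    record_stride: int = 5,
) -> tuple[float, float, int]:
    """Mean first passage time (ps) from a fixed start state to a basin.

    Unresampled renewal simulation: walkers start at ``start_state`` (with
    Maxwell-Boltzmann velocities) and are reset there whenever they first
    reach ``destination`` ('bound' or 'unbound'), with the basin entry
    condition checked after every dynamics step.  This matches the warp
    protocol of the weighted-ensemble runs, so 1/MFPT is the direct
    resampling-free reference for the corresponding flux rate (Hill
    relation).

    Each walker contributes a fixed quota of completed passages, so sampling
    stops only at passage boundaries: a wall-clock deadline would drop the
    in-flight passages, which are length-biased (inspection paradox) and
    their exclusion would bias the MFPT low.

    Returns (mfpt_ps, sem_ps, n_passages_observed).
    """
    from .dynamics import propagate
    from .toy_system import maxwell_boltzmann_velocities

    del record_stride  # crossing detection is exact (per step)
    basin_spec.validate_against(params)
    absorb = (destination, basin_spec.bound_cutoff, basin_spec.unbound_cutoff)
    pos = np.tile(np.asarray(start_state.position, dtype=float), (n_walkers, 1))
    vel = maxwell_boltzmann_velocities(n_walkers, params.guest_mass,
                                       params.temperature, rng)
    steps = int(round(chunk_time_ps / params.timestep))
    quota = -(-n_passages // n_walkers)  # completed passages per walker
    remaining = np.full(n_walkers, quota)
    pending = np.zeros(n_walkers)
    durations: list[float] = []
    for _ in range(max_chunks):
        active = remaining > 0
        if not np.any(active):
            break
        idx = np.nonzero(active)[0]
        sub_pos = np.ascontiguousarray(pos[idx])
        sub_vel = np.ascontiguousarray(vel[idx])
        _, cross = propagate(sub_pos, sub_vel, params, steps, rng, absorb=absorb)
        pos[idx] = sub_pos
        vel[idx] = sub_vel
        for j, i in enumerate(idx):
            if cross[j] >= 0:
                durations.append(pending[i] + (cross[j] + 1) * params.timestep)
                remaining[i] -= 1
                pending[i] = 0.0
                pos[i] = start_state.position
                vel[i] = maxwell_boltzmann_velocities(
                    1, params.guest_mass, params.temperature, rng)[0]
            else:
                pending[i] += steps * params.timestep
    if not durations:
        return float("inf"), float("nan"), 0
    m = float(np.mean(durations))
    sem = (float(np.std(durations, ddof=1) / np.sqrt(len(durations)))
           if len(durations) > 1 else float("nan"))
    return m, sem, len(durations)
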