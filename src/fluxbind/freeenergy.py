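"""Standard-state binding free energies from rates, with correction terms.

The raw rate-ratio free energy is

    dG0 = -kT ln(C0 k_on / k_off) = -kT ln(K_eq0 C0),   K_eq0 = (pi_b/pi_u) V_box

which ignores three features of a finite periodic simulation.  The corrected
free energy adds three terms:

    dG = dG0 - kT ln(f_b/f_u) + kT ln<e^{beta E_int}>_unb - kT ln(V_unb/V_box)

* basin term: f_b and f_u are the weight fractions actually inside the bound
  and unbound basins within their history-dependent ensembles; it vanishes
  when the basins capture their ensembles entirely.
* electrostatic term: an exponential (Zwanzig) average of the residual
  host-guest interaction energy over the unbound ensemble; it decouples the
  charges that a finite box cannot separate, and vanishes for neutral pairs.
* volume term: V_unbound/V_box, the fraction of the box satisfying the
  unbound condition, estimated by Monte Carlo placement; it vanishes for
  large boxes.

Equivalently dG = -kT ln(K_eq C0) with
K_eq = (pi_b f_b)/(pi_u f_u) <e^{beta E_int}>^-1 V_unbound; both routes are
computed and checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import InvalidInputError
from .units import NM3_PER_MOLECULE_AT_1M, UnitsContext, kT
from .toy_system import ToySystemParams

__all__ = [
    "CorrectionInputs",
    "FreeEnergyReport",
    "kT",
    "dg_from_rates",
    "dg0_from_pi",
    "term_basin",
    "term_electrostatic",
    "estimate_v_unbound",
    "term_volume",
    "corrected_free_energy",
    "BindingFreeEnergyModel",
    "BindingFreeEnergyResults",
]


def dg_from_rates(k_on: float, k_off: float, units: UnitsContext) -> float:
    """dG0 = -kT ln(C0 k_on / k_off); k_on in 1/(M s), k_off in 1/s."""
    if not (k_on > 0 and k_off > 0):
        raise InvalidInputError("rates must be positive to take the log ratio")
    return -units.kT * np.log(units.C0 * k_on / k_off)


def dg0_from_pi(pi_b: float, pi_u: float, v_box_nm3: float, units: UnitsContext) -> float:
    """dG0 from ensemble probabilities: K_eq0 = (pi_b/pi_u) V_box.

    V_box is in nm^3; K_eq0*C0 is made dimensionless with the 1 M molecular
    volume (1.66054 nm^3).  Algebraically identical to `dg_from_rates` applied
    to the fluxes behind pi_b and pi_u.
    """
    if not (0 <= pi_b <= 1 and 0 <= pi_u <= 1):
        raise InvalidInputError("pi values must be probabilities")
    if pi_u <= 0 or pi_b <= 0:
        raise InvalidInputError("pi_b and pi_u must be positive to take the log")
    if not v_box_nm3 > 0:
        raise InvalidInputError("box volume must be positive")
    keq0_c0 = (pi_b / pi_u) * v_box_nm3 * units.C0 / NM3_PER_MOLECULE_AT_1M
    return -units.kT * np.log(keq0_c0)


def term_basin(f_b: float, f_u: float, units: UnitsContext) -> float:
    """-kT ln(f_b / f_u): positive when the bound basin captures less of its
    ensemble than the unbound basin does."""
    if not (0.0 < f_b <= 1.0 and 0.0 < f_u <= 1.0):
        raise InvalidInputError("f_b and f_u must be in (0, 1]")
    return -units.kT * np.log(f_b / f_u)


def term_electrostatic(
    eint_samples: np.ndarray, units: UnitsContext
) -> tuple[float, float]:
    """+kT ln<e^{beta E_int}>_unb from weighted samples, with its SEM.

    ``eint_samples`` is (n, 2): interaction energy (kcal/mol) and weight.
    The exponential average is evaluated in log space (log-sum-exp) so large
    beta*E cannot overflow.  The SEM comes from the weighted delta method:
    sd(<x>_w) / <x>_w with x = e^{beta E}.
    """
    s = np.asarray(eint_samples, dtype=float)
    if s.size == 0:
        raise InvalidInputError("term_electrostatic requires at least one sample")
    s = s.reshape(-1, 2)
    e, w = s[:, 0], s[:, 1]
    if not np.all(w > 0):
        raise InvalidInputError("sample weights must be positive")
    beta = units.beta
    log_mean = logsumexp(beta * e, b=w) - np.log(np.sum(w))
    value = units.kT * float(log_mean)

    # delta method on shifted exponentials (shift cancels in the ratio)
    shift = np.max(beta * e)
    x = np.exp(beta * e - shift)
    wn = w / np.sum(w)
    m = np.sum(wn * x)
    var_mean = np.sum(wn**2 * (x - m) ** 2)
    sem = units.kT * float(np.sqrt(var_mean) / m)
    return value, sem


def estimate_v_unbound(
    params: ToySystemParams,
    basin_spec,
    rng: np.random.Generator,
    n_trials: int = 10000,
    n_batches: int = 5,
) -> tuple[float, float]:
    """Monte Carlo estimate of V_unbound / V_box with its batch-mean SEM.

    Guest centres are placed uniformly in the box (the point guest has no
    orientational degrees of freedom); a placement counts as unbound when its
    minimum-image clearance from the host exceeds the unbound cutoff.
    Defaults follow the five-batches-of-10,000-trials protocol.
    """
    if n_trials < 1 or n_batches < 1:
        raise InvalidInputError("n_trials and n_batches must be >= 1")
    box = params.box_lengths
    r_cut = params.host_radius + basin_spec.unbound_cutoff
    means = np.empty(n_batches)
    for b in range(n_batches):
        pts = rng.uniform(0.0, 1.0, size=(n_trials, 3)) * box
        disp = pts - params.host_position
        disp -= box * np.floor(disp / box + 0.5)
        r = np.linalg.norm(disp, axis=1)
        means[b] = np.mean(r > r_cut)
    ratio = float(np.mean(means))
    sem = float(np.std(means, ddof=1) / np.sqrt(n_batches)) if n_batches > 1 else float("nan")
    return ratio, sem


def term_volume(v_ratio: float, units: UnitsContext) -> float:
    """-kT ln(V_unbound / V_box) >= 0."""
    if not (0.0 < v_ratio <= 1.0):
        raise InvalidInputError(
            f"V_unbound/V_box must be in (0, 1], got {v_ratio}"
        )
    return -units.kT * np.log(v_ratio)


@dataclass
class CorrectionInputs:
    """Everything the corrected free energy consumes beyond dG0.

    f_b, f_u: basin weight fractions within the unbinding/rebinding ensembles.
    eint_samples: (n, 2) array of (interaction energy kcal/mol, weight).
    v_ratio (+ SEM): V_unbound / V_box.
    Optional SEMs for f_b/f_u come from replicate spread; `replicates` carries
    provenance tags.
    """

    f_b: float
    f_u: float
    eint_samples: np.ndarray
    v_ratio: float
    v_ratio_sem: float = 0.0
    f_b_sem: float = 0.0
    f_u_sem: float = 0.0
    replicates: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        problems = []
        if not (0.0 < self.f_b <= 1.0):
            problems.append(f"f_b must be in (0, 1], got {self.f_b}")
        if not (0.0 < self.f_u <= 1.0):
            problems.append(f"f_u must be in (0, 1], got {self.f_u}")
        if not (0.0 < self.v_ratio <= 1.0):
            problems.append(f"v_ratio must be in (0, 1], got {self.v_ratio}")
        self.eint_samples = np.asarray(self.eint_samples, dtype=float).reshape(-1, 2)
        if self.eint_samples.size and not np.all(self.eint_samples[:, 1] > 0):
            problems.append("eint sample weights must be positive")
        if problems:
            raise InvalidInputError("; ".join(problems))


@dataclass
class FreeEnergyReport:
    """dG0, the three correction terms, their sum, and uncertainties (kcal/mol)."""

    dg0: float
    term_basin: float
    term_elec: float
    term_volume: float
    dg_corrected: float
    dg0_sem: float
    term_basin_sem: float
    term_elec_sem: float
    term_volume_sem: float
    dg_corrected_sem: float
    keq_c0: float
    inputs: CorrectionInputs | None = None

    @property
    def total_correction(self) -> float:
        return self.term_basin + self.term_elec + self.term_volume

    def to_dict(self) -> dict:
        return {
            "dg0_kcal_mol": self.dg0,
            "dg0_sem": self.dg0_sem,
            "term_basin_kcal_mol": self.term_basin,
            "term_basin_sem": self.term_basin_sem,
            "term_elec_kcal_mol": self.term_elec,
            "term_elec_sem": self.term_elec_sem,
            "term_volume_kcal_mol": self.term_volume,
            "term_volume_sem": self.term_volume_sem,
            "total_correction_kcal_mol": self.total_correction,
            "dg_corrected_kcal_mol": self.dg_corrected,
            "dg_corrected_sem": self.dg_corrected_sem,
            "keq_c0": self.keq_c0,
        }


def corrected_free_energy(
    dg0: float,
    corrections: CorrectionInputs,
    units: UnitsContext,
    dg0_sem: float = 0.0,
    elec_term_override: tuple[float, float] | None = None,
) -> FreeEnergyReport:
    """Assemble the corrected free energy dG = dG0 + three terms.

    Uncertainties are combined in quadrature across terms, treating them as
    independent (an approximation: the terms come from separate protocols).
    The equivalent equilibrium-constant route
    K_eq C0 = e^{-beta dG0} (f_b/f_u) <e^{beta E_int}>^-1 (V_unb/V_box)
    is evaluated alongside and must agree with the sum-of-terms route to
    1e-10 kcal/mol; ``keq_c0`` is exposed on the report.
    """
    tb = term_basin(corrections.f_b, corrections.f_u, units)
    if elec_term_override is not None:
        te, te_sem = elec_term_override
    else:
        te, te_sem = term_electrostatic(corrections.eint_samples, units)
    tv = term_volume(corrections.v_ratio, units)

    dg_corr = dg0 + tb + te + tv

    # route 2: through the corrected equilibrium constant
    keq_c0 = float(np.exp(-units.beta * dg_corr))
    dg_route2 = -units.kT * np.log(
        np.exp(-units.beta * dg0)
        * (corrections.f_b / corrections.f_u)
        * np.exp(-units.beta * te)
        * corrections.v_ratio
    )
    if abs(dg_route2 - dg_corr) > 1e-10:
        raise AssertionError(
            f"free-energy routes disagree: {dg_corr} vs {dg_route2}"
        )

    tb_sem = units.kT * np.sqrt(
        (corrections.f_b_sem / corrections.f_b) ** 2
        + (corrections.f_u_sem / corrections.f_u) ** 2
    )
    tv_sem = units.kT * corrections.v_ratio_sem / corrections.v_ratio
    total_sem = float(np.sqrt(dg0_sem**2 + tb_sem**2 + te_sem**2 + tv_sem**2))

    return FreeEnergyReport(
        dg0=float(dg0),
        term_basin=float(tb),
        term_elec=float(te),
        term_volume=float(tv),
        dg_corrected=float(dg_corr),
        dg0_sem=float(dg0_sem),
        term_basin_sem=float(tb_sem),
        term_elec_sem=float(te_sem),
        term_volume_sem=float(tv_sem),
        dg_corrected_sem=total_sem,
        keq_c0=keq_c0,
        inputs=corrections,
    )


class BindingFreeEnergyModel:
    """Binding free energy estimated from split-ensemble rates plus corrections.

    Parameters
    ----------
    k_on, k_off : float
        Association (1/(M s)) and dissociation (1/s) rate constants.
    corrections : CorrectionInputs
    units : UnitsContext
    k_on_sem, k_off_sem : float, optional
        Replicate SEMs, propagated into dG0 via the log derivative.

    Use :meth:`from_simulation` to build the model from
    `SplitEnsembleSimulation` replicate results, or :meth:`from_tables` from
    the delimited-text exit-point/energy interchange format.
    """

    def __init__(
        self,
        k_on: float,
        k_off: float,
        corrections: CorrectionInputs,
        units: UnitsContext | None = None,
        k_on_sem: float = 0.0,
        k_off_sem: float = 0.0,
        elec_term_override: tuple[float, float] | None = None,
    ):
        self.k_on = k_on
        self.k_off = k_off
        self.corrections = corrections
        self.units = units or UnitsContext()
        self.k_on_sem = k_on_sem
        self.k_off_sem = k_off_sem
        self._elec_override = elec_term_override

    @classmethod
    def from_simulation(
        cls,
        unbinding_results: Sequence,
        rebinding_results: Sequence,
        params: ToySystemParams,
        basin_spec,
        rng: np.random.Generator,
        units: UnitsContext | None = None,
        n_volume_trials: int = 10000,
        n_volume_batches: int = 5,
    ) -> "BindingFreeEnergyModel":
        """Build from replicate `EnsembleRunResult` lists.

        Rates and basin fractions are averaged over replicates (SEM over
        replicates); interaction-energy samples are pooled; the volume ratio
        is estimated by Monte Carlo placement.
        """
        from .simulate import ReplicateSummary

        koff = ReplicateSummary(
            np.array([r.rate_steady.value for r in unbinding_results]))
        kon = ReplicateSummary(
            np.array([r.rate_steady.value for r in rebinding_results]))
        fb = ReplicateSummary(
            np.array([r.basin_fraction_mean for r in unbinding_results])
        )
        fu = ReplicateSummary(
            np.array([r.basin_fraction_mean for r in rebinding_results])
        )
        eint = (
            np.vstack([r.eint_samples for r in rebinding_results
                       if r.eint_samples.size])
            if any(r.eint_samples.size for r in rebinding_results)
            else np.empty((0, 2))
        )
        v_ratio, v_sem = estimate_v_unbound(
            params, basin_spec, rng, n_trials=n_volume_trials,
            n_batches=n_volume_batches,
        )
        corrections = CorrectionInputs(
            f_b=fb.mean, f_u=fu.mean, eint_samples=eint,
            v_ratio=v_ratio, v_ratio_sem=v_sem,
            f_b_sem=0.0 if np.isnan(fb.sem) else fb.sem,
            f_u_sem=0.0 if np.isnan(fu.sem) else fu.sem,
            replicates=tuple(
                f"{r.ensemble}/{r.replicate_id}"
                for r in list(unbinding_results) + list(rebinding_results)
            ),
        )
        return cls(
            k_on=kon.mean, k_off=koff.mean, corrections=corrections,
            units=units or UnitsContext(temperature=params.temperature),
            k_on_sem=0.0 if np.isnan(kon.sem) else kon.sem,
            k_off_sem=0.0 if np.isnan(koff.sem) else koff.sem,
        )

    @classmethod
    def from_tables(
        cls,
        k_on: float,
        k_off: float,
        f_b: float,
        f_u: float,
        energies: np.ndarray,
        v_ratio: float,
        units: UnitsContext | None = None,
        v_ratio_sem: float = 0.0,
        f_b_sem: float = 0.0,
        f_u_sem: float = 0.0,
        k_on_sem: float = 0.0,
        k_off_sem: float = 0.0,
        elec_term: tuple[float, float] | None = None,
    ) -> "BindingFreeEnergyModel":
        """Build from externally supplied tables/values (corrections-only
        workflow).  ``energies`` is (n, 2) = (E_int kcal/mol, weight); pass
        ``elec_term`` = (value, sem) instead to use a precomputed term."""
        corrections = CorrectionInputs(
            f_b=f_b, f_u=f_u,
            eint_samples=np.asarray(energies, dtype=float).reshape(-1, 2)
            if np.size(energies) else np.empty((0, 2)),
            v_ratio=v_ratio, v_ratio_sem=v_ratio_sem,
            f_b_sem=f_b_sem, f_u_sem=f_u_sem,
        )
        return cls(k_on=k_on, k_off=k_off, corrections=corrections,
                   units=units, k_on_sem=k_on_sem, k_off_sem=k_off_sem,
                   elec_term_override=elec_term)

    def fit(self) -> "BindingFreeEnergyResults":
        """Compute dG0, the three corrections and dG_corrected."""
        dg0 = dg_from_rates(self.k_on, self.k_off, self.units)
        rel_on = self.k_on_sem / self.k_on if self.k_on > 0 else 0.0
        rel_off = self.k_off_sem / self.k_off if self.k_off > 0 else 0.0
        dg0_sem = self.units.kT * float(np.sqrt(rel_on**2 + rel_off**2))
        report = corrected_free_energy(
            dg0, self.corrections, self.units, dg0_sem=dg0_sem,
            elec_term_override=self._elec_override,
        )
        return BindingFreeEnergyResults(self, report)


class BindingFreeEnergyResults:
    """Fitted free-energy estimates with uncertainties.

    Attributes
    ----------
    params : dict
        dG0, the three terms and dG_corrected (kcal/mol).
    bse : dict
        Matching standard errors.
    report : FreeEnergyReport
    """

    def __init__(self, model: BindingFreeEnergyModel, report: FreeEnergyReport):
        self.model = model
        self.report = report
        self.params = {
            "dG0": report.dg0,
            "basin": report.term_basin,
            "electrostatic": report.term_elec,
            "volume": report.term_volume,
            "dG_corrected": report.dg_corrected,
        }
        self.bse = {
            "dG0": report.dg0_sem,
            "basin": report.term_basin_sem,
            "electrostatic": report.term_elec_sem,
            "volume": report.term_volume_sem,
            "dG_corrected": report.dg_corrected_sem,
        }

    @property
    def dg_corrected(self) -> float:
        return self.report.dg_corrected

    @property
    def total_correction(self) -> float:
        return self.report.total_correction

    def summary(self) -> str:
        """Human-readable table mirroring the dG0 / dG_corr report layout."""
        u = self.model.units
        lines = [
            "Binding free energy from trajectory fluxes",
            "=" * 58,
            f"T = {u.temperature:.1f} K    kT = {u.kT:.5f} kcal/mol    C0 = {u.C0:g} M",
            f"k_on  = {self.model.k_on:.4g} 1/(M s)   k_off = {self.model.k_off:.4g} 1/s",
            "-" * 58,
            f"{'quantity':<28}{'kcal/mol':>12}{'sem':>12}",
            "-" * 58,
        ]
        for key, label in [
            ("dG0", "dG0 (rate ratio)"),
            ("basin", "basin term -kT ln(fb/fu)"),
            ("electrostatic", "elec term +kT ln<e^bE>"),
            ("volume", "volume term -kT ln(Vu/Vb)"),
            ("dG_corrected", "dG corrected"),
        ]:
            lines.append(
                f"{label:<28}{self.params[key]:>12.3f}{self.bse[key]:>12.3f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.report.to_dict()
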