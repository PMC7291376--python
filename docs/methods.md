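# Methods

## Model and estimators

### Rates from split history-dependent ensembles

An equilibrium trajectory ensemble is partitioned by the basin last visited:
the *unbinding* ensemble (last visited bound) and the *rebinding* ensemble
(last visited unbound).  Each is simulated separately with all walkers
normalised to total weight 1.  When a walker enters the destination basin its
weight and structure are recorded (an *exit point*) and the walker is
*warped*: coordinates reset to the run's start structure, velocities redrawn
from Maxwell–Boltzmann at T, weight kept.  The entry condition is checked
after every dynamics step, so exit points sit on the basin boundary rather
than wherever the walker has drifted by the end of a cycle — with 20–200 ps
cycles and sub-nanosecond passage times, cycle-granularity detection would
displace rebinding start structures far into the unbound region and bias
k_on noticeably.

The time-averaged exit flux gives k_off = Σw/t (1/s) and
k_on = Σw/(C·t) (1/(M·s)) with C = 1/V_box the single-ligand concentration
(1.66054 nm³ ↔ 1 mol/L; the 80.2 nm³ default box is 0.0207 M).  Rates are
reported two ways: the raw series from t = 0 (as flux traces are
conventionally plotted; it jumps upward whenever an exit point with
higher-than-previously-seen weight arrives) and a steady estimate that
excludes a configurable burn-in from both numerator and denominator.  The
raw estimate is depressed by order MFPT/t because the renewal flux needs
about one passage time to establish itself; free energies therefore use the
steady estimate.

Steady-state balance π_b·φ̂_b→u = π_u·φ̂_u→b turns the two normalised fluxes
into ensemble probabilities, and ΔG⁰ = −kT ln(C⁰k_on/k_off) =
−kT ln((π_b/π_u)·V_box·C⁰) — the two routes are algebraically identical and
both are implemented and cross-checked.

### Correction terms

The corrected free energy is

ΔG = ΔG⁰ − kT ln(f_b/f_u) + kT ln⟨e^{βE_int}⟩_unb − kT ln(V_unb/V_box).

* **Basin term.**  f_b (f_u) is the weight fraction actually inside the
  bound (unbound) basin within its ensemble, averaged over post-burn-in
  cycles; its SEM comes from replicate spread.  The term vanishes when the
  basins capture their ensembles entirely.
* **Electrostatic term.**  A weighted exponential average of the residual
  host–guest Coulomb energy over unbound frames of the rebinding ensemble
  (every cycle, importance-weighted by walker weight), evaluated in log space
  (log-sum-exp) so large βE cannot overflow; SEM by the weighted delta
  method.  It vanishes for neutral pairs and for very distant unbound
  definitions.
* **Volume term.**  V_unb/V_box estimated by uniform Monte Carlo placement of
  the guest centre (the point guest has no orientational degrees of
  freedom), five batches of 10,000 trials by default, SEM from batch means.
  It vanishes as the box grows.

Term uncertainties are combined in quadrature; the terms come from separate
protocols, so independence is a stated approximation.  The equivalent
equilibrium-constant route K_eq = (π_b f_b)/(π_u f_u)·⟨e^{βE}⟩⁻¹·V_unb is
evaluated alongside and must agree with the sum of terms to 10⁻¹⁰ kcal/mol.

### REVO resampling

Between cycles, walkers are cloned and merged to maximise the trajectory
variation V = Σᵢⱼ (dᵢⱼ/d₀)^α φᵢφⱼ with novelty φᵢ = ln wᵢ − C.  Choices made
where the formulation leaves freedom:

* natural logarithm and C = ln p_min, so φ ≥ 0 over the admissible weight
  range and V is a genuine non-negative spread measure (any other base or
  constant rescales V without changing argmax decisions);
* greedy proposals: clone the highest-Vᵢ walker (weight split in half) while
  merging the eligible pair (within `merge_distance`, combined weight
  ≤ p_max) with the lowest Vᵢ sum, up to `max_clone_merge_per_cycle` times;
* a proposal is accepted only if the variation increases for **both**
  possible merge survivors; the survivor is then drawn with probability
  proportional to weight.  Conditioning acceptance on the realised survivor
  would skew the survivor distribution among accepted moves away from
  weight-proportional and bias every weighted expectation, including the
  exit flux.  Requiring both variants keeps the accept decision
  survivor-independent *and* makes the realised variation strictly
  monotone;
* ties break toward the lowest walker index (determinism under a fixed
  seed); native distances are floored at 10⁻³ nm before inversion in the
  rebinding metric.

Distance metrics: unbinding uses the minimum-image separation of guest
positions (the host frame is fixed, so no alignment is needed); rebinding
uses |1/d_native,i − 1/d_native,j|, which concentrates resolution among
nearly-bound walkers.  Both are exposed as pluggable callables, which is
where a symmetry-reduced RMSD for a real host would plug in.

Defaults: 48 walkers, p_min = 10⁻¹², p_max = 0.1, α = 4, d₀ = 0.5 nm,
merge distance 0.25 nm, at most 4 coupled operations per cycle.  α and d₀
shape how strongly structural spread is rewarded; they affect efficiency,
not correctness, and are config-exposed.

## The synthetic host–guest system

A single point guest (mass 116 amu, charge −1e) diffuses in a periodic
4.28×4.33×4.33 nm box around a fixed host (charge −1e) at the box centre.
The potential is radial: a Gaussian binding well of depth 4 kcal/mol and
width σ = 0.2 nm centred on the host-surface shell r = a = 0.3 nm; a soft
harmonic core wall k_w(r−a)² for r < a with k_w = 500 kcal/(mol·nm²); and a
screened Coulomb term with ε_w = 6.88×10⁻¹⁰ F/m (water at 300 K, ε_r ≈
77.7).  Units are nm, ps, amu, kcal/mol, e, K with
k_B = 0.0019872041 kcal/(mol·K) and the Coulomb constant
332.0637 kcal·Å/(mol·e²).

Design rationale:

* **Wide funnel.**  σ = 0.2 nm keeps the bound-basin boundary deep inside
  the attraction zone, mirroring how a real cavitand's RMSD-defined bound
  state sits deep inside its binding funnel.  This matters for estimator
  validity (below).
* **Soft wall.**  A steep power-law core has a vibrational frequency that a
  10 fs timestep cannot resolve; the resulting shadow-dynamics heating is
  invisible at strong friction but biases the kinetic temperature by
  percents at γ ≤ 0.1 ps⁻¹.  The harmonic wall keeps ωτ ≲ 0.1 everywhere a
  walker can reach.  Its force is bounded, so with like charges the
  dynamics cannot blow up; strongly attractive opposite charges would need
  a harder core.
* **NVT, fixed volume.**  The box volume enters the concentration and the
  volume correction as a constant.

Dynamics is BAOAB Langevin splitting (half kick, half drift, exact
Ornstein–Uhlenbeck velocity update with e^{−γτ}, half drift, half kick),
which gives accurate configurational averages at practical timesteps and
reduces to velocity Verlet at γ = 0.  The inner loop over steps and walkers
is JIT-compiled (numba) with per-step basin-entry detection; a pure-NumPy
step exists for arbitrary force fields and for environments without a JIT.

Basins: bound = native distance |r − a| below the bound cutoff; unbound =
clearance r − a strictly above 1 nm.  Everything else is intermediate.

## Validity regime of the warp protocol, and the recovery study

Warping to a *fixed* start structure with *reinitialised* velocities is an
approximation to the true history-conditioned ensembles, which are fed by
the arrival flux at the basin boundaries.  Two error sources follow, both
negligible for systems whose passage times dwarf their local relaxation
times (ms–s for a real host–guest pair) but visible on a toy whose MFPTs are
fractions of a nanosecond:

1. **Missing recross legs.**  Arrival-fed unbinding legs include a fraction
   q of short legs that touch the basin edge and immediately recross; a
   fixed interior start cannot produce them, overestimating the mean
   bound-leg duration by 1/(1−q).  q is the outward committor at the basin
   edge; it does not shrink with well depth (the deficit saturates at 1−q)
   but does shrink as the edge moves deeper into the funnel.
2. **Velocity memory at the unbound boundary.**  True arrivals into the
   unbound basin move outward with flux-weighted speeds; Maxwell–Boltzmann
   reinitialisation is isotropic, halving the initial outward drift and
   shortening rebinding legs by a few percent when the velocity relaxation
   time 1/γ is not utterly negligible against the passage time.

The end-to-end recovery study therefore runs where the protocol's own
premises hold: bound cutoff 0.05 nm (basin edge at 0.25 σ, entries
committed, q ≈ 0.05) and γ = 3 ps⁻¹ (velocity memory ≈ 0.3 ps against
≈ 0.7–2 ns passage times).  Study sizes: 4 unbinding replicates × 300 cycles
× 20 ps and 4 rebinding replicates × 100 cycles × 50 ps, 48 walkers,
burn-ins of 80 and 20 cycles, replicates differing only by seed
(order-insensitive streams spawned from one integer).  At these sizes one
study takes about a minute on one CPU and recovers the quadrature reference
within its ~0.03–0.07 kcal/mol replicate error, while ΔG⁰ is offset by
about −1 kcal/mol, the negative of the correction total.  Protocol-matched
checks that are exact by construction (flux vs 1/MFPT from the same start;
the labeled occupation identity) use the gentler γ = 1, cutoff 0.1
parameterisation where they remain valid.

## Reference oracle

Everything the pipeline estimates has an independent answer:

* **Equilibrium populations and ΔG** by quadrature.  The radial integrand
  e^{−βU(r)}r² is tabulated once; integrals over regions reaching the box
  corners use an exact angular decomposition (for each direction on a
  midpoint octant grid the ray exits the box at R(ω) = min_k(L_k/2)/|n_k|,
  and the interpolated radial primitive is evaluated there).  The
  dilute-solution binding constant takes the bulk reference as a
  non-interacting guest, for which e^{−βU_G} ≡ 1 — for the point guest the
  choice of bulk position is immaterial.  Grid refinement (halving the
  radial step, doubling the angular grid) changes ΔG_ref by < 10⁻³
  kcal/mol at the defaults.
* **FEP term** as the ratio of unbound-region integrals with and without
  the Coulomb term; **V_unbound** in closed form (box minus exclusion
  sphere) whenever the sphere fits inside the inscribed sphere.
* **Rates** from unresampled dynamics: renewal MFPTs from a fixed start
  (each walker contributes a fixed quota of completed passages — stopping
  on a wall-clock deadline would drop the in-flight, length-biased passages
  and bias the MFPT low by the inspection paradox), and history-labeled
  long trajectories whose occupation identity
  (T_b·f_b)/(T_u·f_u) = p_bound/p_unbound is exact and is tested against
  quadrature.
* **Exact configurational sampling** by rejection from a uniform proposal
  over the box, used to start thermostat and equilibrium checks in
  configurational equilibrium — a non-equilibrium start exchanges heat with
  a weakly coupled thermostat for many 1/γ and would measure that transient
  rather than the thermostat.

## Numerical choices and degenerate inputs

* Half-open minimum-image convention: displacement components in
  [−L/2, L/2); positions stored wrapped to [0, L).
* Strict basin inequalities (a clearance exactly at the cutoff is
  intermediate).
* Zero distances raise singularity errors in the Coulomb energy; a guest
  inside 10⁻³ of the core radius is treated as singular.
* Weight conservation is asserted to 10⁻¹² absolute after every resampling
  call; walker count never changes.
* Empty exit-point ledgers yield rate 0 with a zero-events flag; both-zero
  fluxes make the ensemble-probability ratio an explicit error.
* All floating-point CSV output uses 17 significant digits, so files
  round-trip bit-exactly; every output file is listed with a SHA-256 hash in
  the run manifest, and reruns under the same seed are bit-identical.

## What the synthetic system does and does not show

The toy reproduces the *structure* of the real problem — metastable binding,
rare unbinding, residual electrostatics of a like-charged pair, an unbound
state clipped by the box — with a radial potential, a point guest and an
implicit solvent, so exact references exist and the full pipeline can be
validated end-to-end.  It does not emulate molecular detail: no internal or
orientational guest degrees of freedom (the rotational factors in the
volume-correction derivation are trivially separable here by construction),
no explicit solvent or barostat, no rugged binding pathway, and absolute
rates live on nanosecond rather than second scales.  Passing tests therefore
demonstrate correctness of the estimators and corrections, not force-field
realism; the corrections-only workflow accepts externally produced
exit-point and energy tables precisely so the same arithmetic can be applied
to real simulation output.

## Known limitations

* The fixed-start/velocity-reinitialisation warp protocol carries the
  intrinsic biases quantified above; outside the committed-basin,
  velocity-memoryless regime they appear at the few-percent level in K_eq.
* SEMs from 4 replicates are themselves uncertain by ~40%; replicates share
  the pooled unbinding exit points, so rebinding replicate spread slightly
  understates start-structure sensitivity.
* The delta-method SEM of the electrostatic term ignores frame
  autocorrelation within a replicate (frames one cycle apart are nearly
  independent at the default cycle lengths).
* Opposite-charge parameterisations need a harder core wall than the
  default harmonic one.
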