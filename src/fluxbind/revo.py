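"""REVO resampling: Resampling Ensembles by Variation Optimization.

A weighted ensemble of walkers is periodically resampled by cloning walkers
in sparse, novel regions and merging nearby low-novelty walkers.  Coupled
clone/merge proposals are accepted only when they increase the trajectory
variation

    V = sum_i V_i = sum_i sum_j (d_ij / d0)^alpha * phi_i * phi_j

where d_ij is a pairwise distance between walker structures and
phi_i = log w_i - C is the novelty of walker i, a function of its statistical
weight only.  With C = log(p_min) every admissible walker has phi >= 0, so V
is a genuine non-negative spread measure.

The proposal schedule is greedy: clone the highest-V_i walker (splitting its
weight in half) while merging the eligible pair with the lowest combined V_i
(summing weights; the surviving structure is drawn with probability
proportional to the merged weights, which keeps all weighted expectations
unbiased).  Moves must respect the weight window [p_min, p_max] and the merge
distance, and walker count and total weight are always conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import InvalidInputError
from .toy_system import SystemState, ToySystemParams, minimum_image_displacement

__all__ = [
    "Walker",
    "ResamplerConfig",
    "ResamplingDecision",
    "novelty",
    "trajectory_variation",
    "resample",
    "unbinding_distance",
    "rebinding_distance",
    "make_unbinding_distance",
    "make_rebinding_distance",
]

#: Floor applied to native distances before inversion in the rebinding metric.
D_NATIVE_FLOOR = 1.0e-3


@dataclass
class Walker:
    """A trajectory replica: state, statistical weight, and the basin it last
    visited (its history "color")."""

    state: SystemState
    weight: float
    history_label: str = "from_bound"
    lineage_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise InvalidInputError(f"walker weight must be in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class ResamplerConfig:
    """REVO knobs.

    alpha and d0 shape the distance contribution to the variation; p_min and
    p_max bound walker weights (defaults 1e-12 and 0.1); merge_distance is
    the maximum structural distance between merge partners, in the units of
    the active distance metric.
    """

    alpha: float = 4.0
    d0: float = 0.5
    novelty_constant: float | None = None  # default: log(p_min)
    p_min: float = 1.0e-12
    p_max: float = 0.1
    merge_distance: float = 0.25
    max_clone_merge_per_cycle: int = 4

    def __post_init__(self) -> None:
        problems = []
        if not self.alpha > 0:
            problems.append("alpha must be > 0")
        if not self.d0 > 0:
            problems.append("d0 must be > 0")
        if not (0.0 < self.p_min < self.p_max <= 1.0):
            problems.append("need 0 < p_min < p_max <= 1")
        if not self.merge_distance > 0:
            problems.append("merge_distance must be > 0")
        if self.max_clone_merge_per_cycle < 0:
            problems.append("max_clone_merge_per_cycle must be >= 0")
        if problems:
            raise InvalidInputError("; ".join(problems))

    @property
    def C(self) -> float:
        return np.log(self.p_min) if self.novelty_constant is None else self.novelty_constant


@dataclass
class ResamplingDecision:
    """Record of one resampling call: which walkers were cloned/merged and the
    variation before and after."""

    cloned: list[tuple[int, int]] = field(default_factory=list)
    merged: list[tuple[int, int]] = field(default_factory=list)
    variation_before: float = 0.0
    variation_after: float = 0.0

    @property
    def is_identity(self) -> bool:
        return not self.cloned and not self.merged


def novelty(weight: float, C: float) -> float:
    """phi = log(w) - C for a walker of weight w."""
    if not weight > 0:
        raise InvalidInputError(f"weight must be > 0, got {weight}")
    return float(np.log(weight) - C)


def trajectory_variation(
    distance_matrix: np.ndarray,
    novelties: np.ndarray,
    alpha: float,
    d0: float,
) -> tuple[float, np.ndarray]:
    """Trajectory variation V and its per-walker contributions V_i.

    V_i = sum_j (d_ij/d0)^alpha phi_i phi_j, V = sum_i V_i.  The distance
    matrix must be symmetric with zero diagonal.
    """
    d = np.asarray(distance_matrix, dtype=float)
    phi = np.asarray(novelties, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise InvalidInputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise InvalidInputError("distance matrix must have a zero diagonal")
    if not np.all(np.isfinite(phi)):
        raise InvalidInputError("novelties must be finite")
    w = (d / d0) ** alpha
    v_i = phi * (w @ phi)
    return float(np.sum(v_i)), v_i


def _variation_from_arrays(
    dmat: np.ndarray, weights: np.ndarray, cfg: ResamplerConfig
) -> tuple[float, np.ndarray]:
    phi = np.log(weights) - cfg.C
    w = (dmat / cfg.d0) ** cfg.alpha
    v_i = phi * (w @ phi)
    return float(np.sum(v_i)), v_i


def resample(
    walkers: Sequence[Walker],
    config: ResamplerConfig,
    distance_fn: Callable[[SystemState, SystemState], float],
    rng: np.random.Generator,
) -> tuple[list[Walker], ResamplingDecision]:
    """One REVO resampling pass.

    Returns a new walker list (same length, same total weight to 1e-12) and a
    `ResamplingDecision`.  When no admissible move increases the variation the
    decision is the identity and the input walkers are returned unchanged (as
    copies of the same objects).
    """
    n = len(walkers)
    decision = ResamplingDecision()
    if n < 2 or config.max_clone_merge_per_cycle == 0:
        return list(walkers), decision

    states = [w.state for w in walkers]
    weights = np.array([w.weight for w in walkers], dtype=float)
    lineages = [w.lineage_id for w in walkers]
    labels = [w.history_label for w in walkers]

    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = distance_fn(states[i], states[j])

    v0, _ = _variation_from_arrays(dmat, weights, config)
    decision.variation_before = v0
    decision.variation_after = v0
    v_cur = v0

    for _ in range(config.max_clone_merge_per_cycle):
        _, v_i = _variation_from_arrays(dmat, weights, config)

        clone_ok = weights / 2.0 >= config.p_min
        if not np.any(clone_ok):
            break
        # ties broken toward the lowest index via stable ordering
        order = np.argsort(-v_i, kind="stable")
        c = next((int(i) for i in order if clone_ok[i]), None)
        if c is None:
            break

        best_pair = None
        best_score = np.inf
        for i in range(n):
            if i == c:
                continue
            for j in range(i + 1, n):
                if j == c:
                    continue
                if dmat[i, j] > config.merge_distance:
                    continue
                if weights[i] + weights[j] > config.p_max:
                    continue
                score = v_i[i] + v_i[j]
                if score < best_score - 1e-15:
                    best_score = score
                    best_pair = (i, j)
        if best_pair is None:
            break
        i, j = best_pair

        # trial move: merge one slot of (i, j) away, clone c into the freed
        # slot.  The accept decision must not depend on which of i, j
        # survives: conditioning acceptance on the survivor draw would skew
        # the survivor distribution away from weight-proportional among
        # accepted moves and bias every weighted expectation (including the
        # exit-point flux).  Accept only if the variation increases for BOTH
        # survivor choices, then draw the survivor independently.
        def _trial(keep: int, absorbed: int):
            w_try = weights.copy()
            w_try[keep] = weights[i] + weights[j]
            w_try[c] = weights[c] / 2.0
            w_try[absorbed] = weights[c] / 2.0
            d_try = dmat.copy()
            d_try[absorbed, :] = dmat[c, :]
            d_try[:, absorbed] = dmat[:, c]
            d_try[absorbed, absorbed] = 0.0
            d_try[absorbed, c] = d_try[c, absorbed] = 0.0
            v_new, _ = _variation_from_arrays(d_try, w_try, config)
            return v_new, w_try, d_try

        v_keep_i, w_i_, d_i_ = _trial(i, j)
        v_keep_j, w_j_, d_j_ = _trial(j, i)
        if not min(v_keep_i, v_keep_j) > v_cur:
            break

        keep = i if rng.random() < weights[i] / (weights[i] + weights[j]) else j
        absorbed = j if keep == i else i
        v_new, w_try, d_try = (v_keep_i, w_i_, d_i_) if keep == i else (v_keep_j, w_j_, d_j_)

        # accept
        states[keep] = states[keep]  # surviving structure already in place
        states[absorbed] = states[c].copy()
        labels[absorbed] = labels[c]
        lineages[absorbed] = lineages[c]
        weights = w_try
        dmat = d_try
        v_cur = v_new
        decision.cloned.append((c, 2))
        decision.merged.append((keep, absorbed))
        decision.variation_after = v_cur

    total_before = sum(w.weight for w in walkers)
    assert abs(np.sum(weights) - total_before) < 1e-12
    out = [
        Walker(state=states[k], weight=float(weights[k]),
               history_label=labels[k], lineage_id=lineages[k])
        for k in range(n)
    ]
    return out, decision


def unbinding_distance(
    state_i: SystemState, state_j: SystemState, params: ToySystemParams
) -> float:
    """Distance metric for unbinding runs: minimum-image separation of the two
    guest positions (the host frame is fixed, so no alignment is needed)."""
    _, dist = minimum_image_displacement(state_i.position, state_j.position,
                                         params.box_lengths)
    return float(dist)


def rebinding_distance(d_native_i: float, d_native_j: float) -> float:
    """Distance metric for rebinding runs: |1/d_i - 1/d_j| over native
    distances, emphasising differences among nearly-bound walkers.  Native
    distances are floored at 1e-3 nm before inversion."""
    if d_native_i < 0 or d_native_j < 0:
        raise InvalidInputError("native distances must be non-negative")
    di = max(d_native_i, D_NATIVE_FLOOR)
    dj = max(d_native_j, D_NATIVE_FLOOR)
    return abs(1.0 / di - 1.0 / dj)


def make_unbinding_distance(params: ToySystemParams):
    """Bind the unbinding metric to a parameter set for use with `resample`."""

    def _d(si: SystemState, sj: SystemState) -> float:
        return unbinding_distance(si, sj, params)

    return _d


def make_rebinding_distance(params: ToySystemParams):
    """Bind the rebinding metric (inverse native-distance difference)."""
    from .toy_system import native_distance

    def _d(si: SystemState, sj: SystemState) -> float:
        return rebinding_distance(native_distance(si, params),
                                  native_distance(sj, params))

    return _d
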