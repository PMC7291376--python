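"""Basin classification, warping, flux rates and ensemble probabilities."""

import numpy as np
import pytest

from fluxbind.ensembles import (
    BasinSpec,
    ExitPoint,
    FluxLedger,
    apply_warp,
    basin_fraction,
    classify_basin,
    concentration_from_volume,
    pi_ratio,
    rate_from_flux,
)
from fluxbind.exceptions import InvalidInputError, UndefinedRatioError
from fluxbind.revo import Walker
from fluxbind.toy_system import SystemState


def _state_at(params, r, direction=np.array([1.0, 0, 0])):
    return SystemState(params.host_position + r * direction, np.zeros(3))


class TestClassifyBasin:
    def test_native_pose_is_bound(self, fast_params, basin):
        assert classify_basin(fast_params.bound_start_state(), basin, fast_params) == "bound"

    def test_cutoff_exactly_is_intermediate(self):
        # strict inequality: clearance exactly 1 nm is not yet unbound
        # (geometry chosen so the clearance is exact in floating point)
        from fluxbind.toy_system import ToySystemParams

        p = ToySystemParams(box_lengths=np.array([4.0] * 3),
                            host_position=np.array([2.0] * 3), host_radius=0.25)
        b = BasinSpec(bound_cutoff=0.1, unbound_cutoff=1.0)
        s = SystemState(np.array([3.25, 2.0, 2.0]), np.zeros(3))
        assert classify_basin(s, b, p) == "intermediate"
        s_beyond = SystemState(np.array([3.25 + 1e-9, 2.0, 2.0]), np.zeros(3))
        assert classify_basin(s_beyond, b, p) == "unbound"

    def test_radial_scan_is_monotone(self, fast_params, basin):
        seen = [classify_basin(_state_at(fast_params, r), basin, fast_params)
                for r in np.linspace(0.25, 1.6, 200)]
        # once a later class appears the earlier one never recurs
        order = {"bound": 0, "intermediate": 1, "unbound": 2}
        codes = [order[s] for s in seen]
        assert codes == sorted(codes)
        assert set(seen) == {"bound", "intermediate", "unbound"}

    def test_invariants(self):
        with pytest.raises(InvalidInputError):
            BasinSpec(bound_cutoff=1.0, unbound_cutoff=0.5)
        with pytest.raises(InvalidInputError):
            BasinSpec(bound_cutoff=0.0, unbound_cutoff=1.0)


class TestApplyWarp:
    def _walkers(self, params, radii, weights):
        return [Walker(_state_at(params, r), w, lineage_id=i)
                for i, (r, w) in enumerate(zip(radii, weights))]

    def test_no_crossing_is_noop(self, fast_params, basin, rng):
        ledger = FluxLedger(ensemble="unbinding")
        ledger.advance_clock(20.0)
        walkers = self._walkers(fast_params, [0.3, 0.7], [0.5, 0.5])
        out, points = apply_warp(walkers, basin, fast_params.bound_start_state(),
                                 fast_params, rng, ledger)
        assert points == [] and ledger.exit_points == []
        assert np.allclose(out[1].state.position, walkers[1].state.position)

    def test_single_crossing_bookkeeping(self, fast_params, basin, rng):
        ledger = FluxLedger(ensemble="unbinding")
        ledger.advance_clock(20.0)
        start = fast_params.bound_start_state()
        walkers = self._walkers(fast_params, [0.3, 1.5], [1 - 3e-5, 3e-5])
        total = sum(w.weight for w in walkers)
        out, points = apply_warp(walkers, basin, start, fast_params, rng, ledger,
                                 cycle_index=7)
        assert len(points) == 1
        assert points[0].weight == pytest.approx(3e-5)
        assert points[0].cycle_index == 7
        assert np.allclose(out[1].state.position, start.position)
        assert out[1].weight == pytest.approx(3e-5)  # weight unchanged by warp
        assert sum(w.weight for w in out) == pytest.approx(total, abs=1e-15)

    def test_two_crossings_same_cycle(self, fast_params, basin, rng):
        ledger = FluxLedger(ensemble="unbinding")
        ledger.advance_clock(20.0)
        walkers = self._walkers(fast_params, [1.6, 1.7, 0.3], [0.2, 0.3, 0.5])
        _, points = apply_warp(walkers, basin, fast_params.bound_start_state(),
                               fast_params, rng, ledger, cycle_index=3)
        assert len(points) == 2
        assert all(p.cycle_index == 3 for p in points)


class TestRateFromFlux:
    def _ledger(self, weights, t_total, ensemble="unbinding", conc=None):
        ledger = FluxLedger(ensemble=ensemble, concentration=conc)
        snap = SystemState(np.zeros(3), np.zeros(3))
        for i, w in enumerate(weights):
            ledger.exit_points.append(ExitPoint(
                weight=w, cycle_index=i, elapsed_time=(i + 1) * t_total / (len(weights) + 1),
                source_ensemble=ensemble, snapshot=snap))
        ledger.total_ensemble_time = t_total
        return ledger

    def test_koff_arithmetic(self):
        est = rate_from_flux(self._ledger([2e-6, 1e-6], 1e6))
        assert est.value == pytest.approx(3.0)  # 3e-12 / ps = 3 / s
        assert est.kind == "k_off"

    def test_kon_divides_by_concentration(self):
        c = concentration_from_volume(80.2)
        est = rate_from_flux(self._ledger([2e-6, 1e-6], 1e6, "rebinding", c))
        assert est.value == pytest.approx(3.0 / c)
        assert est.kind == "k_on"

    def test_empty_ledger_flags_zero_events(self):
        ledger = FluxLedger(ensemble="unbinding")
        ledger.advance_clock(100.0)
        est = rate_from_flux(ledger)
        assert est.value == 0.0 and est.zero_events

    def test_series_jumps_only_at_new_exits(self):
        est = rate_from_flux(self._ledger([1e-8, 5e-6, 1e-8], 1e6))
        # k(t) decays between events; the high-weight event dominates the max
        assert est.series[1] > est.series[0]
        assert np.argmax(est.series) == 1
        assert est.series[-1] == pytest.approx(est.value)


class TestConcentration:
    def test_paper_box(self):
        assert round(concentration_from_volume(80.2), 4) == 0.0207

    def test_one_molar_volume(self):
        # the standard-state volume per molecule is 1.66054 nm^3
        assert concentration_from_volume(1.66054) == pytest.approx(1.0, rel=1e-5)

    def test_scaling_and_errors(self):
        assert concentration_from_volume(40.0) == pytest.approx(
            2 * concentration_from_volume(80.0))
        with pytest.raises(InvalidInputError):
            concentration_from_volume(0.0)


class TestPiRatio:
    def test_equal_fluxes(self):
        assert pi_ratio(1e-6, 1e-6) == (0.5, 0.5)

    def test_three_to_one(self):
        pi_b, pi_u = pi_ratio(3e-6, 1e-6)
        assert (pi_b, pi_u) == (pytest.approx(0.75), pytest.approx(0.25))

    def test_absorbing_limit(self):
        assert pi_ratio(0.0, 1e-9) == (0.0, 1.0)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedRatioError):
            pi_ratio(0.0, 0.0)


class TestBasinFraction:
    def test_all_in_basin(self):
        assert basin_fraction(np.array([0.2, 0.8]), np.array([True, True])) == 1.0

    def test_paper_format_example(self):
        f = basin_fraction(np.array([0.157, 0.843]), np.array([True, False]))
        assert f == pytest.approx(0.157)

    def test_rescaling_invariance(self, rng):
        w = rng.uniform(0, 1, 20)
        m = rng.random(20) < 0.4
        assert basin_fraction(w, m) == pytest.approx(basin_fraction(10 * w, m))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            basin_fraction(np.array([]), np.array([], dtype=bool))
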