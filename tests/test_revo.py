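"""REVO resampler: novelty, trajectory variation, clone/merge proposals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxbind.exceptions import InvalidInputError
from fluxbind.revo import (
    ResamplerConfig,
    Walker,
    make_unbinding_distance,
    novelty,
    rebinding_distance,
    resample,
    trajectory_variation,
    unbinding_distance,
)
from fluxbind.toy_system import SystemState, ToySystemParams


class TestNovelty:
    def test_boundary_and_trivial(self):
        assert novelty(1e-12, np.log(1e-12)) == pytest.approx(0.0)
        assert novelty(1.0, 0.0) == pytest.approx(0.0)

    def test_half_weight_against_pmin_constant(self):
        expected = np.log(0.5) - np.log(1e-12)
        phi = novelty(0.5, np.log(1e-12))
        assert phi == pytest.approx(expected)
        assert phi == pytest.approx(26.938, abs=1e-3)

    def test_nonpositive_weight(self):
        with pytest.raises(InvalidInputError):
            novelty(0.0, 0.0)


class TestTrajectoryVariation:
    def test_coincident_walkers(self):
        d = np.zeros((3, 3))
        v, v_i = trajectory_variation(d, np.ones(3), alpha=2.0, d0=1.0)
        assert v == 0.0 and np.all(v_i == 0.0)

    def test_two_walker_hand_computation(self):
        phi = np.log(0.5) - np.log(1e-12)
        d0 = 0.7
        d = np.array([[0.0, 2 * d0], [2 * d0, 0.0]])
        v, v_i = trajectory_variation(d, np.array([phi, phi]), alpha=2.0, d0=d0)
        expected_vi = 4.0 * phi * phi
        assert np.allclose(v_i, expected_vi)
        assert v == pytest.approx(2 * expected_vi)
        assert v_i[0] == pytest.approx(2902.6, abs=0.5)

    @given(alpha=st.floats(0.5, 6.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_in_distance(self, alpha, scale):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (5, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        phi = rng.uniform(0.5, 30.0, 5)
        v1, _ = trajectory_variation(d, phi, alpha, 1.0)
        v2, _ = trajectory_variation(2.0 * d, phi, alpha, 1.0)
        assert v2 == pytest.approx(2.0**alpha * v1, rel=1e-9 * max(1, scale))

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InvalidInputError):
            trajectory_variation(d, np.ones(2), 2.0, 1.0)


class TestDistanceMetrics:
    def test_unbinding_metric(self, fast_params):
        s1 = SystemState(np.array([1.0, 0, 0]), np.zeros(3))
        s2 = SystemState(np.array([2.0, 0, 0]), np.zeros(3))
        assert unbinding_distance(s1, s1, fast_params) == 0.0
        assert unbinding_distance(s1, s2, fast_params) == pytest.approx(1.0)

    def test_unbinding_triangle_inequality(self, fast_params, rng):
        for _ in range(100):
            a, b, c = (SystemState(rng.uniform(0, 1, 3) * fast_params.box_lengths,
                                   np.zeros(3)) for _ in range(3))
            dab = unbinding_distance(a, b, fast_params)
            dbc = unbinding_distance(b, c, fast_params)
            dac = unbinding_distance(a, c, fast_params)
            assert dac <= dab + dbc + 1e-12

    def test_rebinding_metric(self):
        assert rebinding_distance(0.7, 0.7) == 0.0
        assert rebinding_distance(0.5, 2.0) == pytest.approx(1.5)

    def test_rebinding_prioritises_small_native_distances(self):
        near = rebinding_distance(1.0, 1.0001)
        far = rebinding_distance(10.0, 10.0001)
        assert near / far == pytest.approx(100.0, rel=1e-2)

    def test_rebinding_floor(self):
        # native distances below the 1e-3 nm floor are clamped before inversion
        assert np.isfinite(rebinding_distance(0.0, 1.0))
        assert rebinding_distance(1e-9, 1.0) == rebinding_distance(1e-3, 1.0)
        with pytest.raises(InvalidInputError):
            rebinding_distance(-0.1, 1.0)


def _walker(pos, w, i=0):
    return Walker(SystemState(np.asarray(pos, dtype=float), np.zeros(3)), w,
                  lineage_id=i)


class TestResample:
    def test_identity_when_clone_would_breach_pmin(self, fast_params, rng):
        cfg = ResamplerConfig(p_min=1e-3, p_max=0.9, merge_distance=0.5)
        walkers = [_walker([1.0, 1, 1], 1.5e-3, 0), _walker([3.0, 1, 1], 1.5e-3, 1)]
        out, dec = resample(walkers, cfg, make_unbinding_distance(fast_params), rng)
        assert dec.is_identity
        assert [w.weight for w in out] == [1.5e-3, 1.5e-3]

    def test_merge_and_clone_increase_variation(self, fast_params, rng):
        cfg = ResamplerConfig(alpha=2.0, d0=0.5, merge_distance=0.3,
                              max_clone_merge_per_cycle=1)
        # two coincident low-weight walkers, one distant heavy walker
        walkers = [
            _walker([1.0, 1.0, 1.0], 0.01, 0),
            _walker([1.0, 1.0, 1.0], 0.01, 1),
            _walker([3.0, 3.0, 3.0], 0.08, 2),
        ]
        out, dec = resample(walkers, cfg, make_unbinding_distance(fast_params), rng)
        assert len(dec.cloned) == 1 and len(dec.merged) == 1
        assert dec.variation_after > dec.variation_before
        assert len(out) == 3
        assert sum(w.weight for w in out) == pytest.approx(0.1, abs=1e-14)

    def test_expectation_preserved_over_seeds(self, fast_params):
        """Resampling is unbiased: the weighted mean of an observable is
        preserved in expectation over merge-survivor randomness."""
        cfg = ResamplerConfig(alpha=2.0, d0=0.5, merge_distance=1.0,
                              max_clone_merge_per_cycle=3)
        base = np.random.default_rng(5)
        positions = np.array([
            [1.0, 1.0, 1.0], [1.2, 1.0, 1.0], [1.0, 1.3, 1.0],
            [2.6, 2.0, 2.0], [1.1, 1.1, 1.4], [3.4, 3.0, 1.0],
        ])
        weights = np.array([0.05, 0.02, 0.08, 0.01, 0.03, 0.06])
        walkers = [_walker(p, w, i) for i, (p, w) in enumerate(zip(positions, weights))]
        f = lambda s: s.position[0]
        before = sum(w.weight * f(w.state) for w in walkers)
        n_rep = 4000
        after = np.empty(n_rep)
        dist = make_unbinding_distance(fast_params)
        for k in range(n_rep):
            out, _ = resample(walkers, cfg, dist, np.random.default_rng([5, k]))
            after[k] = sum(w.weight * f(w.state) for w in out)
        bias = after.mean() - before
        se = after.std(ddof=1) / np.sqrt(n_rep)
        assert abs(bias) < 3 * max(se, 1e-15)
        del base

    def test_conservation_and_window_properties(self, fast_params):
        """Every resampling call conserves total weight to 1e-12, keeps counts,
        never worsens weight-window violations, and never decreases V."""
        dist = make_unbinding_distance(fast_params)
        cfg = ResamplerConfig()
        for trial in range(40):
            rng = np.random.default_rng([7, trial])
            n = int(rng.integers(4, 12))
            cluster = rng.uniform(1.0, 1.2, (n, 3))
            spread = rng.uniform(0, 1, (n, 3)) * fast_params.box_lengths
            mix = np.where(rng.random((n, 1)) < 0.5, cluster, spread)
            w = rng.dirichlet(np.ones(n))
            walkers = [_walker(mix[i], max(w[i], 1e-11), i) for i in range(n)]
            total = sum(wk.weight for wk in walkers)
            lo = min(wk.weight for wk in walkers)
            hi = max(wk.weight for wk in walkers)
            out, dec = resample(walkers, cfg, dist, rng)
            assert len(out) == n
            assert abs(sum(wk.weight for wk in out) - total) < 1e-12
            assert min(wk.weight for wk in out) >= min(lo, cfg.p_min) - 1e-15
            assert max(wk.weight for wk in out) <= max(hi, cfg.p_max) + 1e-15
            assert dec.variation_after >= dec.variation_before


def test_resampler_config_validation():
    with pytest.raises(InvalidInputError):
        ResamplerConfig(p_min=0.5, p_max=0.1)
    with pytest.raises(InvalidInputError):
        ResamplerConfig(alpha=-1.0)
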