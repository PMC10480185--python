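"""Unit and property tests for the elementary dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcmedia import (
    MediaLandscape,
    ModelConfig,
    OpinionState,
    heterogeneous_pair_update,
    media_update,
    opinion_distance,
    pair_update,
    selection_weights,
    simulation_step,
)
from bcmedia.core import IsolatedNodeError, _step_inplace
from bcmedia.graphs import InteractionGraph

unit = st.floats(0.0, 1.0)


class TestOpinionDistance:
    @pytest.mark.parametrize(
        "a, b, expected", [(0.7, 0.4, 0.3), (0.5, 0.5, 0.0), (0.0, 1.0, 1.0)]
    )
    def test_examples(self, a, b, expected):
        assert opinion_distance(a, b) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            opinion_distance(1.2, 0.5)

    @given(unit, unit)
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_zero_iff_equal(self, a, b):
        d = opinion_distance(a, b)
        assert d == opinion_distance(b, a) >= 0.0
        assert (d == 0.0) == (a == b)


class TestSelectionWeights:
    def test_biased_example(self):
        w = selection_weights(0.5, (0.4, 0.3), gamma=1.0)
        assert w == pytest.approx([2 / 3, 1 / 3])

    def test_gamma_zero_exactly_uniform(self):
        w = selection_weights(0.9, (0.1, 0.2, 0.3, 0.4), gamma=0.0)
        assert np.all(w == 0.25)

    def test_floored_distance_dominates(self):
        # one candidate at the focal opinion: distance clamps to 1e-4 vs 0.4
        w = selection_weights(0.5, (0.5, 0.9), gamma=1.0, distance_floor=1e-4)
        expected0 = (1e-4) ** -1 / ((1e-4) ** -1 + 0.4**-1)
        assert w[0] == pytest.approx(expected0, abs=1e-9)
        assert w[0] == pytest.approx(0.99975, abs=1e-5)
        assert w[1] == pytest.approx(0.00025, abs=1e-5)

    def test_empty_candidates_and_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            selection_weights(0.5, (), gamma=1.0)
        with pytest.raises(ValueError):
            selection_weights(0.5, (0.4,), gamma=-0.5)

    @given(
        unit,
        st.lists(unit, min_size=1, max_size=30),
        st.floats(0.0, 3.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_normalized_and_monotone_in_distance(self, focal, cands, gamma):
        w = selection_weights(focal, cands, gamma)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0.0)
        if gamma > 0:
            d = np.maximum(np.abs(np.asarray(cands) - focal), 1e-4)
            order = np.argsort(d)
            assert np.all(np.diff(w[order]) <= 1e-12)


class TestPairUpdates:
    @pytest.mark.parametrize(
        "xi, xj, eps, expected",
        [
            (0.2, 0.4, 0.3, (0.3, 0.3)),
            (0.1, 0.9, 0.3, (0.1, 0.9)),
            (0.2, 0.5, 0.3, (0.35, 0.35)),  # distance == epsilon still updates
        ],
    )
    def test_homogeneous_examples(self, xi, xj, eps, expected):
        assert pair_update(xi, xj, eps, 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ei, ej, expected",
        [
            (0.5, 0.1, (0.4, 0.6)),  # only i's bound covers the distance
            (0.1, 0.1, (0.2, 0.6)),
            (0.5, 0.5, (0.4, 0.4)),
        ],
    )
    def test_heterogeneous_examples(self, ei, ej, expected):
        assert heterogeneous_pair_update(0.2, 0.6, ei, ej, 0.5) == pytest.approx(expected)

    def test_heterogeneous_gate_is_strict(self):
        # distance exactly equal to the bound does not persuade (values chosen
        # to be exact in binary so the boundary is actually hit)
        assert heterogeneous_pair_update(0.25, 0.75, 0.5, 0.5, 0.5) == (0.25, 0.75)
        # the homogeneous gate accepts the same boundary
        assert pair_update(0.25, 0.75, 0.5, 0.5) == (0.5, 0.5)

    @given(unit, unit, unit, st.floats(0.01, 0.5))
    @settings(max_examples=100, derandomize=True)
    def test_outputs_stay_in_unit_interval_and_conserve_sum(self, xi, xj, eps, mu):
        a, b = pair_update(xi, xj, eps, mu)
        assert 0.0 <= a <= 1.0 and 0.0 <= b <= 1.0
        assert a + b == pytest.approx(xi + xj, abs=1e-12)


class TestMediaUpdate:
    @pytest.mark.parametrize(
        "xi, xm, expected",
        [(0.4, 0.5, 0.45), (0.9, 0.0, 0.9), (0.0, 0.0, 0.0)],
    )
    def test_examples(self, xi, xm, expected):
        assert media_update(xi, xm, 0.3, 0.5) == pytest.approx(expected)

    def test_strict_gate_excludes_boundary(self):
        assert media_update(0.2, 0.5, 0.3, 0.5, strict=True) == 0.2
        assert media_update(0.2, 0.5, 0.3, 0.5, strict=False) == pytest.approx(0.35)


class TestSimulationStep:
    def test_pm_zero_matches_naive_dw_trajectory(self):
        """With gamma=0 and no media the step is one Deffuant-Weisbuch event."""
        from conftest import naive_dw_step

        seed = 99
        x = np.random.default_rng(seed).random(10)
        state = OpinionState(x.copy())
        cfg = ModelConfig(epsilon=0.3, gamma=0.0, p_m=0.0, mu=0.5)
        rng_model = np.random.default_rng(7)
        rng_oracle = np.random.default_rng(7)
        ref = x.copy()
        for _ in range(200):
            state = simulation_step(state, None, MediaLandscape(()), cfg, rng_model)
            naive_dw_step(ref, 0.3, 0.5, rng_oracle)
        assert state.time == 200
        np.testing.assert_array_equal(state.opinions, ref)

    def test_replay_oracle_biased_step(self):
        """A gamma>0 step is reproduced by hand-replaying the documented
        random-stream order with selection_weights over the peers of i."""
        x0 = np.array([0.1, 0.2, 0.9])
        cfg = ModelConfig(epsilon=0.3, gamma=1.0, p_m=0.0, mu=0.5)
        state = simulation_step(
            OpinionState(x0.copy()), None, MediaLandscape(()), cfg,
            np.random.default_rng(3),
        )
        # replay with an identically seeded generator
        rng = np.random.default_rng(3)
        i = int(rng.integers(3))
        peers = [k for k in range(3) if k != i]
        w = np.maximum(np.abs(x0[peers] - x0[i]), 1e-4) ** -1.0
        r = rng.random() * w.sum()
        j = peers[int(np.searchsorted(np.cumsum(w), r, side="right"))]
        expected = x0.copy()
        if abs(x0[i] - x0[j]) <= 0.3:
            expected[i], expected[j] = (
                x0[i] + 0.5 * (x0[j] - x0[i]),
                x0[j] + 0.5 * (x0[i] - x0[j]),
            )
        np.testing.assert_array_equal(state.opinions, expected)

    def test_media_replay_single_medium(self):
        """With M=1 the medium is chosen with probability one (no extra draw)."""
        x0 = np.array([0.4, 0.8])
        cfg = ModelConfig(epsilon=1.0, gamma=0.0, p_m=1.0, mu=0.5)
        state = simulation_step(
            OpinionState(x0.copy()), None, MediaLandscape((0.0,)), cfg,
            np.random.default_rng(11),
        )
        rng = np.random.default_rng(11)
        i = int(rng.integers(2))
        k = int(rng.integers(1))
        j = k if k < i else k + 1
        expected = x0.copy()
        expected[i], expected[j] = (
            x0[i] + 0.5 * (x0[j] - x0[i]),
            x0[j] + 0.5 * (x0[i] - x0[j]),
        )
        assert rng.random() < 1.0  # the p_m draw
        expected[i] = expected[i] + 0.5 * (0.0 - expected[i])
        np.testing.assert_array_equal(state.opinions, expected)

    def test_opinions_remain_in_unit_interval(self):
        cfg = ModelConfig(epsilon=0.8, gamma=1.5, p_m=0.4, mu=0.5)
        rng = np.random.default_rng(0)
        state = OpinionState(rng.random(20))
        media = MediaLandscape((0.0, 1.0))
        for _ in range(2000):
            state = simulation_step(state, None, media, cfg, rng)
        assert state.opinions.min() >= 0.0 and state.opinions.max() <= 1.0

    def test_sum_conserved_without_media(self):
        cfg = ModelConfig(epsilon=0.4, gamma=1.0, p_m=0.0, mu=0.5)
        rng = np.random.default_rng(5)
        x = rng.random(50)
        total = x.sum()
        for _ in range(10_000):
            _step_inplace(x, 0.4, False, 1.0, 0.5, 0.0, 1e-4, np.array([]), rng)
        assert abs(x.sum() - total) < 1e-9

    def test_isolated_agent_is_named(self):
        graph = InteractionGraph.from_edges(2, [])
        cfg = ModelConfig(epsilon=0.5)
        with pytest.raises(IsolatedNodeError, match="agent [01]"):
            simulation_step(
                OpinionState(np.array([0.2, 0.8])), graph.accessor(),
                MediaLandscape(()), cfg, np.random.default_rng(1),
            )


class TestConfigValidation:
    def test_parameter_ranges(self):
        with pytest.raises(ValueError):
            ModelConfig(epsilon=1.2)
        with pytest.raises(ValueError):
            ModelConfig(epsilon=0.5, gamma=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(epsilon=0.5, mu=0.0)
        with pytest.raises(ValueError):
            ModelConfig(epsilon=0.5, p_m=1.5)
        with pytest.raises(ValueError):
            ModelConfig(epsilon=0.5, distance_floor=0.0)

    def test_heterogeneous_epsilon_length_checked(self):
        cfg = ModelConfig(epsilon=[0.2, 0.3, 0.4])
        assert cfg.heterogeneous
        with pytest.raises(ValueError):
            cfg.epsilon_array(5)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            OpinionState(np.array([0.5]))
        with pytest.raises(ValueError):
            OpinionState(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            MediaLandscape((0.5, -0.1))
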