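import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs
from hypothesis.extra.numpy import arrays

from streamtg import (
    InputError,
    VertexTuple,
    assemble_tensor,
    delta_entropy,
    entropy,
    global_matrix,
    local_transition_matrix,
    stationary_distribution,
    transition_counts,
)


class TestLocalTransitionMatrix:
    def test_constant_sequence_puts_all_mass_on_diagonal(self):
        ids = [5, 5, 5, 5, 5]  # tau = 5
        tm = local_transition_matrix(
            list(zip(ids, ids[1:])), k=3, pseudocount_mode=False
        )
        assert tm.raw[5, 5] == 4
        assert tm.n_transitions == 4  # = tau - 1

    def test_hand_counted_two_state_sequence(self):
        ids = [0, 1, 1, 0]
        tm = local_transition_matrix(
            list(zip(ids, ids[1:])), k=2, pseudocount_mode=False
        )
        expected = np.array([[0, 1], [1, 1]], dtype=float)
        np.testing.assert_array_equal(tm.raw, expected)

    def test_pseudocount_adds_one_over_state_count(self):
        tm = local_transition_matrix([(0, 1)], k=3, pseudocount_mode=True)
        assert tm.pseudocount == pytest.approx(1 / 8)
        assert tm.counts[7, 7] == pytest.approx(1 / 8)
        assert tm.counts[0, 1] == pytest.approx(1 + 1 / 8)
        assert tm.raw.sum() == pytest.approx(1.0)

    def test_out_of_range_id_rejected(self):
        with pytest.raises(InputError):
            local_transition_matrix([(0, 9)], k=2)


class TestAssembleTensor:
    def _matrix(self, verts, pairs, pseudo=False):
        return local_transition_matrix(
            pairs, k=len(verts), pseudocount_mode=pseudo,
            vertex_tuple=VertexTuple(verts),
        )

    def test_single_slice_totals_are_row_sums(self):
        m = self._matrix([0, 1, 2], [(0, 1), (1, 1), (1, 0)])
        tensor = assemble_tensor(0, [m])
        assert tensor.state_totals.shape == (8, 1)
        np.testing.assert_array_equal(tensor.state_totals[:, 0], m.raw.sum(axis=1))

    def test_anchored_enumeration_slice_count(self):
        """|V|=4, k=3: k * P(3, 2) = 18 ordered tuples contain vertex 0
        (vertex 0 may occupy any of the k positions)."""
        from streamtg import enumerate_tuples

        tuples = list(enumerate_tuples(4, 3, anchor=0))
        assert len(tuples) == 18
        mats = [self._matrix(t, [(0, 0)]) for t in tuples]
        tensor = assemble_tensor(0, mats)
        assert len(tensor.slices) == 18

    def test_zero_transition_state_has_zero_total(self):
        m = self._matrix([0, 1], [(0, 0)])
        tensor = assemble_tensor(0, [m])
        assert tensor.state_totals[1, 0] == 0

    def test_tuple_missing_anchor_rejected(self):
        m = self._matrix([1, 2], [(0, 0)])
        with pytest.raises(InputError):
            assemble_tensor(0, [m])


class TestGlobalMatrix:
    def _slice(self, verts, counts):
        from streamtg import TransitionMatrix

        return TransitionMatrix(
            counts=np.asarray(counts, dtype=float),
            k=len(verts),
            vertex_tuple=VertexTuple(verts),
        )

    def test_single_slice_is_row_normalized(self):
        m = self._slice([0, 1], [[3, 1], [2, 2]])
        model = global_matrix(assemble_tensor(0, [m]))
        np.testing.assert_allclose(
            model.matrix, [[0.75, 0.25], [0.5, 0.5]], atol=1e-12
        )

    def test_identical_slices_are_idempotent(self):
        m1 = self._slice([0, 1], [[3, 1], [2, 2]])
        m2 = self._slice([0, 2], [[3, 1], [2, 2]])
        single = global_matrix(assemble_tensor(0, [m1]))
        double = global_matrix(assemble_tensor(0, [m1, m2]))
        np.testing.assert_allclose(single.matrix, double.matrix, atol=1e-12)

    def test_pooling_equals_explicit_weighted_sum(self):
        """Pooled-count normalization reproduces the per-state weighted sum of
        row-conditional slice probabilities, with weights = each slice's share
        of transitions leaving the state."""
        c1 = np.array([[6.0, 2.0], [1.0, 1.0]])
        c2 = np.array([[1.0, 1.0], [4.0, 4.0]])
        m1, m2 = self._slice([0, 1], c1), self._slice([0, 2], c2)
        model = global_matrix(assemble_tensor(0, [m1, m2]))
        expected = np.zeros((2, 2))
        for i in range(2):
            totals = np.array([c1[i].sum(), c2[i].sum()])
            weights = totals / totals.sum()
            expected[i] = weights[0] * c1[i] / totals[0] + weights[1] * c2[i] / totals[1]
        np.testing.assert_allclose(model.matrix, expected, atol=1e-12)

    def test_empty_row_becomes_uniform(self):
        m = self._slice([0, 1], [[2, 2], [0, 0]])
        model = global_matrix(assemble_tensor(0, [m]))
        np.testing.assert_allclose(model.matrix[1], [0.5, 0.5])


class TestStationaryDistribution:
    def test_doubly_stochastic_two_state(self):
        pi = stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_analytic_two_state(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.5, 0.5]]))
        np.testing.assert_allclose(pi, [5 / 6, 1 / 6], atol=1e-9)

    def test_identity_warns_but_is_deterministic(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            pi1 = stationary_distribution(np.eye(3))
        with pytest.warns(RuntimeWarning):
            pi2 = stationary_distribution(np.eye(3))
        np.testing.assert_array_equal(pi1, pi2)
        assert pi1.sum() == pytest.approx(1.0)

    def test_non_stochastic_rejected(self):
        with pytest.raises(InputError):
            stationary_distribution(np.array([[0.9, 0.3], [0.5, 0.5]]))
        with pytest.raises(InputError):
            stationary_distribution(np.array([[1.5, -0.5], [0.5, 0.5]]))

    def test_power_iteration_path_matches_dense(self, rng):
        n = 100  # beyond the dense limit of 64
        T = rng.random((n, n)) + 0.01
        T /= T.sum(axis=1, keepdims=True)
        pi_power = stationary_distribution(T)
        pi_dense = stationary_distribution(T, dense_limit=n)
        np.testing.assert_allclose(pi_power, pi_dense, atol=1e-9)
        assert np.abs(pi_power @ T - pi_power).max() < 1e-8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        raw=arrays(
            np.float64,
            (6, 6),
            elements=hs.floats(0.01, 10.0, allow_nan=False),
        )
    )
    def test_fixed_point_property(self, raw):
        T = raw / raw.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
        assert np.abs(pi @ T - pi).max() < 1e-8
        assert pi.min() >= 0 and pi.sum() == pytest.approx(1.0)


class TestEntropy:
    def test_uniform_eight_states_is_three_bits(self):
        assert entropy(np.full(8, 1 / 8)) == pytest.approx(3.0, abs=1e-12)

    def test_point_mass_is_zero_bits(self):
        assert entropy(np.array([0.0, 1.0, 0.0])) == 0.0

    def test_half_quarter_quarter(self):
        assert entropy(np.array([0.5, 0.25, 0.25])) == pytest.approx(1.5, abs=1e-12)

    def test_invalid_vectors_rejected(self):
        with pytest.raises(InputError):
            entropy(np.array([0.7, 0.7]))
        with pytest.raises(InputError):
            entropy(np.array([1.5, -0.5]))

    def test_delta_entropy_sign_convention(self):
        # positive = entropy loss in the second (complex) run
        assert delta_entropy(3.0, 1.0) == 2.0
        assert delta_entropy(1.0, 3.0) == -2.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        raw=arrays(
            np.float64, (8,), elements=hs.floats(0.0, 10.0, allow_nan=False)
        ).filter(lambda a: a.sum() > 0.1)
    )
    def test_entropy_bounds(self, raw):
        p = raw / raw.sum()
        h = entropy(p)
        assert 0.0 <= h <= np.log2(len(p)) + 1e-12


def _birth_death_chain(up=0.3, down=0.2, n=4):
    """Birth-death chain with closed-form stationary pi_i ~ (up/down)^i."""
    T = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            T[i, i + 1] = up
        if i > 0:
            T[i, i - 1] = down
        T[i, i] = 1.0 - T[i].sum()
    ratio = up / down
    pi = ratio ** np.arange(n)
    return T, pi / pi.sum()


def _sample_chain(T, length, rng):
    states = np.arange(T.shape[0])
    seq = np.empty(length, dtype=int)
    seq[0] = 0
    for t in range(1, length):
        seq[t] = rng.choice(states, p=T[seq[t - 1]])
    return seq


class TestParameterRecovery:
    def test_four_state_chain_recovery(self):
        T, pi_true = _birth_death_chain()
        rng = np.random.default_rng(2024)
        seq = _sample_chain(T, 10_000, rng)
        counts = transition_counts(zip(seq, seq[1:]), n=4, pseudocount=0.25)
        est = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(est - T).max() < 0.05
        pi_est = stationary_distribution(est)
        assert np.abs(pi_est - pi_true).max() < 0.02

    def test_pseudocount_effect_vanishes_with_length(self):
        T, pi_true = _birth_death_chain()
        errs = []
        for length in (100, 10_000):
            seq = _sample_chain(T, length, np.random.default_rng(7))
            with_pc = transition_counts(zip(seq, seq[1:]), n=4, pseudocount=0.25)
            without = transition_counts(zip(seq, seq[1:]), n=4, pseudocount=0.0)
            pi_pc = stationary_distribution(
                with_pc / with_pc.sum(axis=1, keepdims=True)
            )
            pi_raw = stationary_distribution(
                without / without.sum(axis=1, keepdims=True)
            )
            errs.append(np.abs(pi_pc - pi_raw).max())
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3
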