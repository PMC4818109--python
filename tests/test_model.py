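import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import condorcet as cc
from oracles import loglik_brute_force, tree_category_probs

T, F, D, M = cc.TRUE, cc.FALSE, cc.DONT_KNOW, cc.MISSING

probs = st.floats(0.0, 1.0)
unit_open = st.floats(0.01, 0.99)


class TestLogisticPieces:
    def test_inverse_logit_values(self):
        assert cc.inverse_logit(0.0) == 0.5
        assert round(float(cc.inverse_logit(2.0)), 4) == 0.8808

    @given(st.floats(-30, 30))
    @settings(derandomize=True)
    def test_inverse_logit_symmetry(self, x):
        assert cc.inverse_logit(x) + cc.inverse_logit(-x) == pytest.approx(1.0)

    def test_knowledge_probability_matched_is_half(self):
        assert cc.knowledge_probability(1.3, 1.3) == 0.5

    def test_knowledge_probability_dominance(self):
        assert round(float(cc.knowledge_probability(1.0, -1.0)), 4) == 0.8808
        assert cc.knowledge_probability(40.0, 0.0) == pytest.approx(1.0)


class TestResponseProbabilities:
    @pytest.mark.parametrize(
        "z, d, b, g, expected",
        [
            (1, 1.0, 0.3, 0.9, (1.0, 0.0, 0.0)),  # perfect knowledge
            (0, 0.0, 1.0, 0.3, (0.3, 0.7, 0.0)),  # pure guessing
            (1, 0.5, 0.0, 0.8, (0.5, 0.0, 0.5)),  # never guesses; g irrelevant
        ],
    )
    def test_branch_products(self, z, d, b, g, expected):
        np.testing.assert_allclose(cc.response_probabilities(z, d, b, g), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cc.response_probabilities(1, 1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            cc.response_probabilities(2, 0.5, 0.5, 0.5)

    @given(z=st.integers(0, 1), d=probs, b=probs, g=probs)
    @settings(derandomize=True, max_examples=200)
    def test_sums_to_one(self, z, d, b, g):
        p = cc.response_probabilities(z, d, b, g)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    @given(z=st.integers(0, 1), d=probs, b=probs, g1=probs, g2=probs)
    @settings(derandomize=True)
    def test_dont_know_independent_of_key_and_bias(self, z, d, b, g1, g2):
        p1 = cc.response_probabilities(z, d, b, g1)[2]
        p2 = cc.response_probabilities(1 - z, d, b, g2)[2]
        assert p1 == pytest.approx(p2)

    @given(z=st.integers(0, 1), b=probs, g=probs, d1=probs, d2=probs)
    @settings(derandomize=True)
    def test_dont_know_decreasing_in_knowledge(self, z, b, g, d1, d2):
        lo, hi = sorted([d1, d2])
        assert (
            cc.response_probabilities(z, hi, b, g)[2]
            <= cc.response_probabilities(z, lo, b, g)[2] + 1e-12
        )

    @given(z=st.integers(0, 1), d=probs, g=probs, b1=probs, b2=probs)
    @settings(derandomize=True)
    def test_dont_know_decreasing_in_willingness(self, z, d, g, b1, b2):
        lo, hi = sorted([b1, b2])
        assert (
            cc.response_probabilities(z, d, hi, g)[2]
            <= cc.response_probabilities(z, d, lo, g)[2] + 1e-12
        )

    @given(z=st.integers(0, 1), d=probs, b=probs, g=probs)
    @settings(derandomize=True, max_examples=100)
    def test_matches_tree_path_enumeration(self, z, d, b, g):
        p = cc.response_probabilities(z, d, b, g)
        oracle = tree_category_probs(z, d, b, g)
        np.testing.assert_allclose(p, [oracle[T], oracle[F], oracle[D]], atol=1e-12)


def _random_instance(rng, n, m):
    values = rng.choice([T, F, D, M], size=(n, m), p=[0.4, 0.35, 0.15, 0.1])
    # keep every respondent partially observed
    values[:, 0] = rng.choice([T, F, D], size=n)
    key = rng.integers(0, 2, m)
    theta = rng.normal(0, 1.5, n)
    delta = rng.normal(0, 1.5, m)
    delta -= delta.mean()
    b = rng.uniform(0.05, 0.95, n)
    g = rng.uniform(0.05, 0.95, n)
    data = cc.ResponseMatrix(
        values, [f"r{i}" for i in range(n)], [f"i{k}" for k in range(m)]
    )
    params = cc.EcmParameters(key, theta, delta, b, g)
    return data, params


class TestLogLikelihood:
    def test_certain_cell_contributes_zero(self):
        values = np.array([[T, M], [M, T]], dtype=np.int8)
        data = cc.ResponseMatrix(values, ["a", "b"], ["i1", "i2"])
        params = cc.EcmParameters(
            [1, 1], [800.0, 800.0], [0.0, 0.0], [0.5, 0.5], [0.5, 0.5]
        )
        assert cc.log_likelihood(data, params) == 0.0

    def test_impossible_observation_is_minus_inf(self):
        values = np.array([[F, T], [T, T]], dtype=np.int8)
        data = cc.ResponseMatrix(values, ["a", "b"], ["i1", "i2"])
        params = cc.EcmParameters(
            [1, 1], [800.0, 800.0], [0.0, 0.0], [0.5, 0.5], [0.5, 0.5]
        )
        with pytest.warns(UserWarning, match="zero probability"):
            assert cc.log_likelihood(data, params) == -np.inf

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n, m = rng.integers(2, 6, 2)
            data, params = _random_instance(rng, n, m)
            expected = loglik_brute_force(
                data.values,
                params.consensus_key,
                params.ability,
                params.difficulty,
                params.willingness,
                params.guess_bias,
            )
            assert cc.log_likelihood(data, params) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_joint_item_permutation(self):
        rng = np.random.default_rng(7)
        data, params = _random_instance(rng, 5, 5)
        perm = rng.permutation(5)
        data_p = cc.ResponseMatrix(
            data.values[:, perm], data.respondent_ids, [data.item_ids[k] for k in perm]
        )
        params_p = cc.EcmParameters(
            params.consensus_key[perm],
            params.ability,
            params.difficulty[perm],  # permutation preserves the sum-to-zero constraint
            params.willingness,
            params.guess_bias,
        )
        assert cc.log_likelihood(data, params) == pytest.approx(
            cc.log_likelihood(data_p, params_p)
        )

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        data, params = _random_instance(rng, 4, 3)
        other, _ = _random_instance(rng, 4, 4)
        with pytest.raises(ValueError, match="dimensions"):
            cc.log_likelihood(other, params)


class TestConsensusConditional:
    def test_all_dont_know_returns_prior(self):
        y = np.full(5, D)
        d = np.full(5, 0.7)
        b = np.full(5, 0.6)
        g = np.full(5, 0.4)
        assert cc.consensus_conditional(y, d, b, g, 0.3) == pytest.approx(0.3)

    def test_single_true_response_hand_computed(self):
        # P(True|Z=1) = 0.8 + 0.2*0.25 = 0.85; P(True|Z=0) = 0.05
        p = cc.consensus_conditional(np.array([T]), [0.8], [0.5], [0.5], 0.5)
        assert p == pytest.approx(0.85 / 0.90)

    def test_balanced_evidence_is_half(self):
        y = np.array([T, F])
        d = np.full(2, 0.7)
        b = np.full(2, 0.5)
        g = np.full(2, 0.5)
        assert cc.consensus_conditional(y, d, b, g, 0.5) == pytest.approx(0.5)

    def test_monotone_in_number_of_true_responses(self):
        n = 8
        d = np.full(n, 0.6)
        b = np.full(n, 0.7)
        g = np.full(n, 0.4)
        previous = -1.0
        for k in range(n + 1):
            y = np.array([T] * k + [F] * (n - k))
            p = cc.consensus_conditional(y, d, b, g, 0.5)
            assert p > previous
            previous = p

    @given(prior=unit_open)
    @settings(derandomize=True)
    def test_prior_respected_under_no_information(self, prior):
        y = np.full(3, D)
        arr = np.full(3, 0.5)
        assert cc.consensus_conditional(y, arr, arr, arr, prior) == pytest.approx(prior)


class TestEcmParameters:
    def test_rejects_unbalanced_difficulty(self):
        with pytest.raises(ValueError, match="sum to 0"):
            cc.EcmParameters([1, 0], [0.0, 0.0], [1.0, 0.5], [0.5, 0.5], [0.5, 0.5])

    def test_rejects_boundary_probabilities(self):
        with pytest.raises(ValueError, match="strictly"):
            cc.EcmParameters([1, 0], [0.0, 0.0], [0.5, -0.5], [1.0, 0.5], [0.5, 0.5])
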