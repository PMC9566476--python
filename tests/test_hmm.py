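"""HMM estimation, training and decoding, checked against independent
oracles: brute-force path enumeration, hand-counted frequencies, and the
hmmlearn reference implementation."""

import itertools

import numpy as np
import pytest

from depthact import (
    HmmModel,
    LabeledDescriptors,
    MeanTemplateAssigner,
    StateTemplates,
    assign_symbol_mean,
    baum_welch,
    compute_state_templates,
    estimate_emissions,
    estimate_transitions,
    path_log_probability,
    sample,
    train_knn,
    train_svm,
    uniform_pi,
    viterbi,
)
from depthact.actions import N_STATES, N_SYMBOLS


def _random_model(rng, diag=0.0):
    A = rng.uniform(0.1, 1.0, (5, 5)) + diag * np.eye(5)
    B = rng.uniform(0.1, 1.0, (5, 5)) + diag * np.eye(5)
    return HmmModel(A=A / A.sum(1, keepdims=True), B=B / B.sum(1, keepdims=True), pi=uniform_pi())


def _identity_emission_model(A=None):
    if A is None:
        A = np.full((5, 5), 0.2)
    B = np.eye(5) * 0.95 + 0.01  # diag 0.96, off-diag 0.01
    return HmmModel(A=A, B=B, pi=uniform_pi())


class _FixedAssigner:
    """Stub symbol assigner replaying a fixed label vector (row order)."""

    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype=np.int64)

    def assign(self, descriptor):
        raise NotImplementedError

    def assign_many(self, X):
        assert X.shape[0] == self.labels.size
        return self.labels


class TestUniformPi:
    def test_five_equal_entries_summing_to_one(self):
        pi = uniform_pi()
        np.testing.assert_allclose(pi, 0.2)
        assert pi.sum() == pytest.approx(1.0)


class TestEstimateTransitions:
    def test_hand_counted_pairs(self):
        A = estimate_transitions([0, 0, 1, 1, 1], alpha=0.0)
        np.testing.assert_allclose(A[0], [0.5, 0.5, 0, 0, 0])
        np.testing.assert_allclose(A[1], [0, 1, 0, 0, 0])

    def test_constant_sequence_gives_identity_row(self):
        A = estimate_transitions([3] * 10, alpha=0.0)
        np.testing.assert_allclose(A[3], [0, 0, 0, 1, 0])

    def test_smoothing_makes_all_entries_positive(self):
        A = estimate_transitions([0, 1, 2, 3, 4], alpha=0.5)
        assert np.all(A > 0)
        np.testing.assert_allclose(A.sum(1), 1.0)

    def test_too_short_sequences_rejected(self):
        for bad in ([], [2]):
            with pytest.raises(ValueError):
                estimate_transitions(bad)


class TestStateTemplates:
    def test_single_descriptor_class_returns_it(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 12))
        templates = compute_state_templates(LabeledDescriptors(X=X, y=np.arange(5)))
        np.testing.assert_allclose(templates.means, X)

    def test_two_descriptor_class_averages(self):
        X = np.vstack([np.arange(5, dtype=float)[:, None] @ np.ones((1, 4)),
                       np.full((1, 4), 10.0)])
        y = np.array([0, 1, 2, 3, 4, 0])
        templates = compute_state_templates(LabeledDescriptors(X=X, y=y))
        np.testing.assert_allclose(templates.means[0], (X[0] + X[5]) / 2)

    def test_mean_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(1)
        X = rng.random((90, 20))
        y = rng.integers(0, 5, 90)
        while len(np.unique(y)) < 5:
            y = rng.integers(0, 5, 90)
        templates = compute_state_templates(LabeledDescriptors(X=X, y=y))
        for j in range(5):
            acc = np.zeros(20)
            n = 0
            for row, lab in zip(X, y):
                if lab == j:
                    acc += row
                    n += 1
            np.testing.assert_allclose(templates.means[j], acc / n)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_state_templates(LabeledDescriptors(X=np.zeros((4, 3)), y=np.arange(4)))


class TestSymbolAssigners:
    def test_exact_template_match_wins(self):
        rng = np.random.default_rng(2)
        means = rng.random((5, 8))
        assert assign_symbol_mean(means[2], StateTemplates(means=means)) == 2

    def test_distance_tie_breaks_to_smaller_index(self):
        means = np.full((5, 4), 50.0)  # far-away decoys
        means[1] = [1, 0, 0, 0]
        means[3] = [0, 1, 0, 0]  # equidistant from the origin query
        assert assign_symbol_mean(np.zeros(4), StateTemplates(means=means)) == 1

    def test_assign_many_agrees_with_brute_force_distances(self):
        rng = np.random.default_rng(3)
        means = rng.random((5, 16))
        X = rng.random((40, 16))
        assigner = MeanTemplateAssigner(StateTemplates(means=means))
        got = assigner.assign_many(X)
        expected = [int(np.argmin([((x - m) ** 2).sum() for m in means])) for x in X]
        np.testing.assert_array_equal(got, expected)

    def test_knn_k1_returns_training_point_class(self):
        rng = np.random.default_rng(4)
        X = rng.random((25, 6))
        y = np.repeat(np.arange(5), 5)
        assigner = train_knn(LabeledDescriptors(X=X, y=y), k=1)
        np.testing.assert_array_equal(assigner.assign_many(X), y)
        assert assigner.assign(X[7]) == y[7]

    def test_missing_class_rejected(self):
        data = LabeledDescriptors(X=np.zeros((4, 3)), y=np.array([0, 1, 2, 3]))
        with pytest.raises(ValueError):
            train_knn(data)
        with pytest.raises(ValueError):
            train_svm(data)

    def test_svm_separates_well_separated_clusters(self):
        rng = np.random.default_rng(5)
        centers = np.eye(5) * 10.0
        X = np.vstack([c + rng.normal(0, 0.3, (20, 5)) for c in centers])
        y = np.repeat(np.arange(5), 20)
        assigner = train_svm(LabeledDescriptors(X=X, y=y), seed=0)
        held_out = np.vstack([c + rng.normal(0, 0.3, (5, 5)) for c in centers])
        np.testing.assert_array_equal(assigner.assign_many(held_out), np.repeat(np.arange(5), 5))


class TestEstimateEmissions:
    def _data(self, n_per_state=10, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((5 * n_per_state, dim))
        y = np.repeat(np.arange(5), n_per_state)
        return LabeledDescriptors(X=X, y=y)

    def test_single_label_row_is_deterministic(self):
        data = self._data()
        est = estimate_emissions(data, _FixedAssigner([0] * 10), alpha=0.0)
        np.testing.assert_allclose(est.B[0], [1, 0, 0, 0, 0])

    def test_half_split_gives_half_masses(self):
        data = self._data()
        est = estimate_emissions(data, _FixedAssigner([0] * 5 + [1] * 5), alpha=0.0)
        np.testing.assert_allclose(est.B[2], [0.5, 0.5, 0, 0, 0])

    def test_rows_normalize_and_frequencies_match_counts(self):
        data = self._data(seed=1)
        labels = np.random.default_rng(9).integers(0, 5, 10)
        est = estimate_emissions(data, _FixedAssigner(labels), alpha=0.0)
        np.testing.assert_allclose(est.B.sum(axis=1), 1.0)
        counts = np.bincount(labels, minlength=5)
        np.testing.assert_allclose(est.B[4], counts / counts.sum())

    def test_smoothing_positivity(self):
        data = self._data()
        est = estimate_emissions(data, _FixedAssigner([2] * 10), alpha=1e-3)
        assert np.all(est.B > 0)
        np.testing.assert_allclose(est.B.sum(axis=1), 1.0)

    def test_magnitude_evidence_is_retained(self):
        data = self._data()
        est = estimate_emissions(data, _FixedAssigner([0] * 10), alpha=0.0)
        np.testing.assert_allclose(est.magnitudes[1], np.linalg.norm(data.for_state(1), axis=1))
        assert est.bandwidths[1] >= 1e-6


class TestBaumWelch:
    def test_fixed_point_stays_put(self):
        model = _identity_emission_model(A=np.eye(5) * 0.9 + 0.02)
        states, symbols = sample(model, 400, np.random.default_rng(0))
        result = baum_welch(model, [symbols], max_iter=1)
        # one EM step from a well-matched model barely moves the parameters
        assert np.abs(result.model.A - model.A).max() < 0.12
        assert np.abs(result.model.B - model.B).max() < 0.12

    def test_log_likelihood_monotone_on_random_data(self):
        rng = np.random.default_rng(1)
        model = _random_model(rng)
        sequences = [rng.integers(0, 5, 60) for _ in range(4)]
        result = baum_welch(model, sequences, max_iter=30)
        lls = result.log_likelihoods
        assert len(lls) >= 2
        assert all(b >= a - 1e-7 for a, b in zip(lls, lls[1:]))

    def test_training_increases_likelihood_of_structured_data(self):
        rng = np.random.default_rng(2)
        truth = _identity_emission_model(A=np.eye(5) * 0.8 + 0.04)
        _, symbols = sample(truth, 800, rng)
        start = _random_model(rng)
        result = baum_welch(start, [symbols], max_iter=50)
        assert result.log_likelihoods[-1] > result.log_likelihoods[0]

    def test_invalid_symbols_rejected(self):
        model = _random_model(np.random.default_rng(3))
        with pytest.raises(ValueError):
            baum_welch(model, [[0, 1, 9]])
        with pytest.raises(ValueError):
            baum_welch(model, [])

    def test_zero_probability_sequence_names_the_sequence(self):
        B = np.zeros((5, 5))
        B[:, 0] = 1.0  # only symbol v1 can ever be emitted
        model = HmmModel(A=np.full((5, 5), 0.2), B=B, pi=uniform_pi())
        with pytest.raises(ValueError, match="sequence 1"):
            baum_welch(model, [[0, 0], [0, 3]])


class TestViterbi:
    def test_deterministic_emissions_echo_the_symbols(self):
        model = _identity_emission_model()
        obs = np.array([0, 3, 3, 1, 4, 2, 2])
        np.testing.assert_array_equal(viterbi(model, obs), obs)

    def test_length_one_reduces_to_argmax_base_case(self):
        rng = np.random.default_rng(4)
        model = _random_model(rng)
        for o in range(5):
            expected = int(np.argmax(model.pi * model.B[:, o]))
            assert viterbi(model, [o])[0] == expected

    def test_beats_random_paths(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng)
        obs = rng.integers(0, 5, 12)
        best = path_log_probability(model, obs, viterbi(model, obs))
        for _ in range(1000):
            random_path = rng.integers(0, 5, 12)
            assert best >= path_log_probability(model, obs, random_path) - 1e-12

    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(6)
        model = _random_model(rng)
        obs = rng.integers(0, 5, 6)
        paths = np.array(list(itertools.product(range(5), repeat=6)))
        lp = (np.log(model.pi[paths[:, 0]]) + np.log(model.B[paths[:, 0], obs[0]]))
        for t in range(1, 6):
            lp += np.log(model.A[paths[:, t - 1], paths[:, t]])
            lp += np.log(model.B[paths[:, t], obs[t]])
        best = path_log_probability(model, obs, viterbi(model, obs))
        assert best == pytest.approx(lp.max())

    def test_empty_observation_rejected(self):
        with pytest.raises(ValueError):
            viterbi(_random_model(np.random.default_rng(7)), [])


class TestAgainstHmmlearn:
    """The independent reference implementation must agree with ours."""

    def _to_hmmlearn(self, model):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ref = hmmlearn.CategoricalHMM(n_components=5, init_params="")
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.emissionprob_ = model.B
        return ref

    def test_viterbi_path_and_score_agree(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng, diag=1.0)
        obs = rng.integers(0, 5, 40)
        ref = self._to_hmmlearn(model)
        ref_lp, ref_path = ref.decode(obs[:, None], algorithm="viterbi")
        ours = viterbi(model, obs)
        np.testing.assert_array_equal(ours, ref_path)
        assert path_log_probability(model, obs, ours) == pytest.approx(ref_lp)

    def test_forward_log_likelihood_agrees(self):
        from depthact.hmm import _forward_backward

        rng = np.random.default_rng(9)
        model = _random_model(rng)
        obs = rng.integers(0, 5, 50)
        *_, ll = _forward_backward(model.A, model.B, model.pi, obs, "seq")
        assert ll == pytest.approx(self._to_hmmlearn(model).score(obs[:, None]))


class TestModelContainer:
    def test_row_sum_violations_rejected(self):
        A = np.full((5, 5), 0.2)
        B = np.full((5, 5), 0.25)
        with pytest.raises(ValueError):
            HmmModel(A=A, B=B, pi=uniform_pi())

    def test_json_round_trip(self):
        model = _random_model(np.random.default_rng(10))
        again = HmmModel.from_dict(model.to_dict())
        np.testing.assert_allclose(again.A, model.A)
        np.testing.assert_allclose(again.B, model.B)
        np.testing.assert_allclose(again.pi, model.pi)
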