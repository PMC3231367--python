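import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enosecnn import (
    NEW_CLASS,
    AdaptiveCompetitiveNet,
    FeatureMatrix,
    HyperParams,
    comparability,
    db_index,
    fit,
    predict,
)
from enosecnn.adaptive import (
    DegenerateVectorError,
    UndefinedDBError,
    add_neuron,
    check_novel,
    cluster_summaries,
    delete_empty,
    learning_rate,
    merge_neurons,
    split_neuron,
    superball_volume,
)
from enosecnn.network import NetworkState, find_winner


def brute_force_db(X, assignments, centers):
    """Independent textbook evaluation of the Davies-Bouldin index.

    Written directly from the definition: per-cluster mean member distance
    to the center, worst-case pairwise (d_i + d_j) / ||c_i - c_j||, averaged.
    """
    labels = [k for k in range(len(centers)) if (assignments == k).sum() > 0]
    d = {}
    for k in labels:
        members = X[assignments == k]
        d[k] = sum(math.dist(m, centers[k]) for m in members) / len(members)
    total = 0.0
    for i in labels:
        worst = -math.inf
        for j in labels:
            if i == j:
                continue
            sep = math.dist(centers[i], centers[j])
            worst = max(worst, (d[i] + d[j]) / sep if sep > 0 else math.inf)
        total += worst
    return total / len(labels)


class TestLearningRate:
    def test_clipped_up_at_start_and_end(self):
        hp = HyperParams(T=1000, eta_min=0.01, eta_max=0.9)
        assert learning_rate(0, hp) == hp.eta_min
        assert learning_rate(hp.T, hp) == hp.eta_min

    def test_clipped_down_at_midpoint(self):
        hp = HyperParams(T=1000, eta_min=0.01, eta_max=0.9)
        assert learning_rate(hp.T // 2, hp) == 0.9

    def test_rise_then_fall_shape(self):
        hp = HyperParams(T=1000, eta_min=0.001, eta_max=1.0)
        quarter = learning_rate(250, hp)
        mid = learning_rate(500, hp)
        late = learning_rate(900, hp)
        assert learning_rate(10, hp) < quarter < mid
        assert late < mid

    def test_out_of_range_iteration(self):
        hp = HyperParams(T=100)
        with pytest.raises(ValueError):
            learning_rate(101, hp)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 3000), st.integers(1, 8))
    def test_always_within_bounds_both_schedules(self, t, n):
        for schedule in ("half_sine", "cyclic"):
            hp = HyperParams(T=3000, schedule=schedule, c=3)
            eta = learning_rate(t, hp, n_current=n)
            assert hp.eta_min <= eta <= hp.eta_max


class TestDBIndex:
    def test_two_symmetric_clusters(self):
        X = np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]])
        state = NetworkState(np.array([[0.0, 1.0], [4.0, 1.0]]), np.array([2, 2]))
        a = np.array([0, 0, 1, 1])
        assert db_index(X, a, state) == pytest.approx(0.5, abs=1e-12)

    def test_halves_when_centers_move_apart_twofold(self):
        X1 = np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]])
        X2 = np.array([[0.0, 0.0], [0.0, 2.0], [8.0, 0.0], [8.0, 2.0]])
        a = np.array([0, 0, 1, 1])
        s1 = NetworkState(np.array([[0.0, 1.0], [4.0, 1.0]]), np.array([2, 2]))
        s2 = NetworkState(np.array([[0.0, 1.0], [8.0, 1.0]]), np.array([2, 2]))
        assert db_index(X2, a, s2) == pytest.approx(db_index(X1, a, s1) / 2)

    def test_zero_for_point_clusters(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        state = NetworkState(X.copy(), np.array([1, 1]))
        assert db_index(X, np.array([0, 1]), state) == 0.0

    def test_undefined_below_two_clusters(self):
        X = np.array([[0.0], [1.0]])
        state = NetworkState(np.array([[0.5], [9.0]]), np.array([2, 0]))
        with pytest.raises(UndefinedDBError):
            db_index(X, np.array([0, 0]), state)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 7)
        n = rng.integers(k, 51)
        d = rng.integers(1, 5)
        X = rng.random((n, d))
        a = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
        centers = rng.random((k, d))
        state = NetworkState(centers, np.bincount(a, minlength=k))
        assert db_index(X, a, state) == pytest.approx(
            brute_force_db(X, a, centers), abs=1e-9
        )

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_matches_sklearn_when_centers_are_centroids(self, seed):
        """With centroid centers, the index equals the standard library score."""
        from sklearn.metrics import davies_bouldin_score

        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        n = rng.integers(k * 2, 40)
        X = rng.random((n, 3))
        a = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
        centroids = np.stack([X[a == j].mean(axis=0) for j in range(k)])
        state = NetworkState(centroids, np.bincount(a, minlength=k))
        assert db_index(X, a, state) == pytest.approx(
            davies_bouldin_score(X, a), abs=1e-9
        )


class TestComparability:
    def test_parallel_is_one(self):
        v = np.array([0.3, 0.4, 0.5])
        assert comparability(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert comparability(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_forty_five_degrees(self):
        got = comparability(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        assert got == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_zero_norm_raises(self):
        with pytest.raises(DegenerateVectorError):
            comparability(np.zeros(3), np.ones(3))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6))
    def test_matches_direct_cosine_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, size=5)
        b = rng.uniform(-1, 1, size=5)
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            return
        direct = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert comparability(a, b) == pytest.approx(direct, abs=1e-12)
        assert -1.0 - 1e-12 <= comparability(a, b) <= 1.0 + 1e-12


class TestMergeNeurons:
    def test_equal_counts_give_midpoint(self):
        w = merge_neurons(np.array([0.0, 1.0]), np.array([1.0, 0.0]), 5, 5)
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_weighted_mean(self):
        w = merge_neurons(np.zeros(2), np.full(2, 4.0), 3, 1)
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_empty_merge_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            merge_neurons(np.zeros(2), np.ones(2), 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6), st.integers(0, 40), st.integers(0, 40))
    def test_weighted_centroid_identity_exact(self, seed, ni, nj):
        """Merge conserves n_i*w_i + n_j*w_j = (n_i + n_j)*w_new."""
        if ni + nj == 0:
            return
        rng = np.random.default_rng(seed)
        wi, wj = rng.random(4), rng.random(4)
        w = merge_neurons(wi, wj, ni, nj)
        np.testing.assert_allclose((ni + nj) * w, ni * wi + nj * wj, atol=1e-12)


class TestSuperballVolume:
    def test_zero_for_member_at_center(self):
        assert superball_volume(np.array([[1.0, 2.0]]), np.array([1.0, 2.0])) == 0.0

    def test_mean_squared_distance(self):
        members = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert superball_volume(members, np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            superball_volume(np.empty((0, 2)), np.zeros(2))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10**6), st.floats(0.1, 10.0))
    def test_quadratic_scaling(self, seed, s):
        rng = np.random.default_rng(seed)
        center = rng.random(3)
        members = center + rng.normal(size=(8, 3))
        v1 = superball_volume(members, center)
        v2 = superball_volume(center + s * (members - center), center)
        assert v2 == pytest.approx(s * s * v1, rel=1e-9)


class TestSplitNeuron:
    def test_offsets_along_spread(self):
        w1, w2 = split_neuron(np.array([0.5, 0.5]), np.array([0.1, 0.3]), 0.1)
        np.testing.assert_allclose(w1, [0.51, 0.53])
        np.testing.assert_allclose(w2, [0.49, 0.47])

    def test_point_mass_split_refused(self):
        with pytest.raises(ValueError, match="point-mass"):
            split_neuron(np.zeros(2), np.zeros(2), 0.1)

    def test_theta_bounds(self):
        with pytest.raises(ValueError, match="theta"):
            split_neuron(np.zeros(2), np.ones(2), 1.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6), st.floats(0.01, 0.99))
    def test_midpoint_symmetry_and_separation(self, seed, theta):
        """Children straddle the parent: midpoint exact, gap 2*theta*|sigma|."""
        rng = np.random.default_rng(seed)
        w = rng.random(5)
        sigma = rng.random(5) + 1e-6
        w1, w2 = split_neuron(w, sigma, theta)
        np.testing.assert_allclose((w1 + w2) / 2, w, atol=1e-12)
        assert np.linalg.norm(w1 - w2) == pytest.approx(
            2 * theta * np.linalg.norm(sigma), rel=1e-12
        )


class TestDeleteEmpty:
    def test_removes_only_empty_rows_in_order(self):
        state = NetworkState(np.arange(6.0).reshape(3, 2), np.array([5, 0, 3]))
        a = np.array([0] * 5 + [2] * 3)
        out = delete_empty(state, a)
        assert out.n_clusters == 2
        np.testing.assert_array_equal(out.counts, [5, 3])
        np.testing.assert_array_equal(out.weights, [[0.0, 1.0], [4.0, 5.0]])

    def test_identity_when_all_occupied(self):
        state = NetworkState(np.eye(2), np.array([1, 1]))
        out = delete_empty(state, np.array([0, 1]))
        np.testing.assert_array_equal(out.weights, state.weights)

    def test_single_survivor(self):
        state = NetworkState(np.eye(3), np.array([0, 0, 2]))
        out = delete_empty(state, np.array([2, 2]))
        assert out.n_clusters == 1


class TestNoveltyAndGrowth:
    def test_sample_at_weight_row_not_novel(self):
        state = NetworkState(np.array([[0.6, 0.8]]), np.array([4]))
        novel, sim, idx = check_novel(np.array([0.6, 0.8]), state, 0.65)
        assert not novel and sim == pytest.approx(1.0) and idx == 0

    def test_orthogonal_sample_is_novel(self):
        state = NetworkState(np.array([[1.0, 0.0]]), np.array([4]))
        novel, sim, _ = check_novel(np.array([0.0, 1.0]), state, 0.65)
        assert novel and sim == 0.0

    def test_threshold_boundary(self):
        state = NetworkState(np.array([[1.0, 0.0]]), np.array([4]))
        novel, sim, _ = check_novel(np.array([1.0, 1.0]), state, 0.65)
        assert not novel and sim == pytest.approx(1 / math.sqrt(2))

    def test_zero_norm_sample_rejected(self):
        state = NetworkState(np.ones((1, 2)), np.array([1]))
        with pytest.raises(DegenerateVectorError):
            check_novel(np.zeros(2), state, 0.65)

    def test_add_neuron_copies_sample_exactly(self):
        state = NetworkState(np.full((2, 3), 0.5), np.array([3, 3]))
        x = np.array([0.9, 0.1, 0.4])
        out = add_neuron(state, x)
        assert out.n_clusters == 3
        np.testing.assert_array_equal(out.weights[-1], x)
        assert out.counts[-1] == 1
        assert find_winner(out, x) == 2  # zero distance beats all

    def test_add_neuron_shape_check(self):
        state = NetworkState(np.ones((1, 2)), np.array([1]))
        with pytest.raises(ValueError, match="does not match"):
            add_neuron(state, np.ones(3))


class TestFit:
    def test_recovers_four_classes(self, four_class_norm, default_hp):
        Xn, labels, _ = four_class_norm
        state, trace, assignments = fit(Xn, default_hp, seed=0)
        assert state.n_clusters == 4
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, assignments) == 1.0

    def test_single_tight_class_collapses_to_one(self):
        rng = np.random.default_rng(0)
        X = FeatureMatrix(np.clip(rng.normal(0.5, 0.02, size=(30, 4)), 0, 1))
        hp = HyperParams(T=600)
        state, _, _ = fit(X, hp, seed=0)
        assert state.n_clusters == 1

    def test_empty_matrix_rejected(self, default_hp):
        with pytest.raises(ValueError):
            fit(FeatureMatrix(np.empty((0, 4))), default_hp, seed=0)

    def test_eta_stays_within_bounds_in_trace(self, four_class_norm, default_hp):
        Xn, _, _ = four_class_norm
        _, trace, _ = fit(Xn, default_hp, seed=5)
        assert all(default_hp.eta_min <= e <= default_hp.eta_max for e in trace.eta)

    def test_structural_events_move_cluster_count_consistently(
        self, four_class_norm, default_hp
    ):
        Xn, _, _ = four_class_norm
        _, trace, _ = fit(Xn, default_hp, seed=2)
        # cluster count only changes in epochs that report a structural event
        for i in range(1, len(trace)):
            if trace.n_clusters[i] != trace.n_clusters[i - 1]:
                assert trace.events[i] != "none"

    def test_trace_budget_respected(self, four_class_norm, default_hp):
        Xn, _, _ = four_class_norm
        _, trace, _ = fit(Xn, default_hp, seed=0)
        n = Xn.n_samples
        assert len(trace) <= default_hp.T // n + 1


class TestPredict:
    @pytest.fixture
    def trained(self, five_class_holdout, default_hp):
        from enosecnn import apply_normalization, normalize_minmax

        X, labels, holdout = five_class_holdout
        Xn, params = normalize_minmax(X)
        model = AdaptiveCompetitiveNet(Xn, default_hp)
        res = model.fit(seed=1)
        Hn = apply_normalization(holdout, params)
        return res, Xn, Hn

    def test_trained_center_maps_to_itself(self, trained, default_hp):
        res, Xn, _ = trained
        w = res.state.weights[0]
        r = predict(res.state, default_hp, w)
        assert r.label == 0 and r.similarity == pytest.approx(1.0)
        assert r.distance == pytest.approx(0.0)

    def test_holdout_class_flagged_new(self, trained, default_hp):
        res, _, Hn = trained
        results = [predict(res.state, default_hp, x) for x in Hn.values]
        assert all(r.is_new for r in results)

    def test_without_allow_new_absorbed_into_nearest(self, trained, default_hp):
        """Closed-world prediction assigns unknown odors to an existing class."""
        res, _, Hn = trained
        results = [predict(res.state, default_hp, x, allow_new=False) for x in Hn.values]
        assert all(not r.is_new for r in results)
        assert all(0 <= r.label < res.n_clusters for r in results)

    def test_online_growth_adds_exactly_one_neuron(self, trained):
        res, _, Hn = trained
        before = res.state.weights.copy()
        k0 = res.n_clusters
        out = res.predict(Hn.values, allow_new=True, update=True)
        assert out[0].is_new
        # first novel sample spawned a neuron; the rest match it
        assert res.n_clusters == k0 + 1
        np.testing.assert_array_equal(res.state.weights[:k0], before)
        assert sum(r.is_new for r in out) == 1

    def test_summary_mentions_structure(self, trained):
        res, _, _ = trained
        text = res.summary()
        assert "final neurons" in text and "DB" in text


class TestHyperParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(theta=0.0),
            dict(theta=1.0),
            dict(lambda_sim=0.0),
            dict(alpha=0.0),
            dict(epsilon=-1.0),
            dict(T=0),
            dict(n_init=0),
            dict(eta_min=0.5, eta_max=0.4),
            dict(schedule="linear"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HyperParams(**kwargs)

    def test_reference_defaults(self, default_hp):
        assert (default_hp.theta, default_hp.lambda_sim, default_hp.alpha,
                default_hp.epsilon, default_hp.n_init, default_hp.T) == (
            0.1, 0.65, 0.028, 0.001, 2, 3000)

    def test_dict_roundtrip(self, default_hp):
        assert HyperParams.from_dict(default_hp.to_dict()) == default_hp
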