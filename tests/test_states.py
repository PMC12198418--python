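import numpy as np
import pytest

from oscroute.states import (
    StateSequence,
    cluster_states,
    count_state_switches,
    distractor_contrast,
    load_regression,
    pc1_performance,
    state_occupancy,
    switch_performance_regression,
    time_in_state,
)


def _seq(labels, rate=1.0):
    return StateSequence(labels=np.asarray(labels), sampling_rate=rate)


class TestClustering:
    def test_well_separated_blobs_recovered(self, rng):
        K, per = 4, 500
        centers = 6 * np.eye(K)
        X = np.vstack([centers[k] + rng.standard_normal((per, K))
                       for k in range(K)])
        true = np.repeat(np.arange(1, K + 1), per)
        order = rng.permutation(X.shape[0])
        model, seq = cluster_states(X[order], K=4, seed=0)
        # dominance relabelling makes cluster j the one peaking at component j
        assert np.mean(seq.labels[0] == true[order]) > 0.99

    def test_duplicate_rows_get_identical_labels(self, rng):
        X = rng.standard_normal((50, 3))
        X = np.vstack([X, X])
        _, seq = cluster_states(X, K=3, seed=0)
        lab = seq.labels[0]
        assert np.array_equal(lab[:50], lab[50:])

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            cluster_states(X, K=2)

    def test_centroid_dominance_ordering(self, rng):
        centers = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5.0]])
        X = np.vstack([c + 0.1 * rng.standard_normal((100, 3)) for c in centers])
        model, _ = cluster_states(X, K=3, seed=0)
        assert np.array_equal(np.argmax(model.centroids, axis=1), [0, 1, 2])


class TestOccupancyAndSwitches:
    def test_occupancy_sums_to_one(self, rng):
        seq = _seq(rng.integers(1, 5, size=(10, 40)))
        occ = state_occupancy(seq)
        assert np.allclose(occ.sum(axis=0), 1.0)

    def test_uniform_random_occupancy_near_quarter(self, rng):
        seq = _seq(rng.integers(1, 5, size=(4000, 10)))
        assert np.allclose(state_occupancy(seq), 0.25, atol=0.02)

    def test_identical_subjects_dominant_everywhere(self):
        seq = _seq(np.tile([1, 2, 1, 3], (5, 1)))
        assert state_occupancy(seq).max(axis=0).min() == 1.0

    @pytest.mark.parametrize("labels, expected", [
        ([1, 1, 2, 2, 1], 2),
        ([1, 1, 1], 0),
        ([1, 2, 3, 4], 3),
    ])
    def test_switch_counting(self, labels, expected):
        assert count_state_switches(_seq([labels]))[0] == expected

    def test_switches_add_over_partition(self, rng):
        lab = rng.integers(1, 5, size=(1, 100))
        seq = _seq(lab, rate=1.0)
        total_inside = sum(
            count_state_switches(seq, window=(a, b))[0]
            for a, b in [(0, 25), (25, 50), (50, 100)])
        boundary = int(lab[0, 25] != lab[0, 24]) + int(lab[0, 50] != lab[0, 49])
        assert count_state_switches(seq)[0] == total_inside + boundary


class TestTimeInState:
    def test_full_window_single_state(self):
        seq = _seq(np.full((2, 10), 3), rate=10.0)
        assert np.allclose(time_in_state(seq, 3, fraction=True), 1.0)
        assert np.allclose(time_in_state(seq, 3), 1.0)  # 10 samples at 10 Hz

    def test_alternating_half_time(self):
        seq = _seq([np.tile([1, 3], 20)])
        assert time_in_state(seq, 1, fraction=True)[0] == pytest.approx(0.5)

    def test_partition_over_states(self, rng):
        seq = _seq(rng.integers(1, 5, size=(3, 60)), rate=5.0)
        total = sum(time_in_state(seq, k) for k in range(1, 5))
        assert np.allclose(total, 60 / 5.0)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            time_in_state(_seq([[1, 2]]), 7)


class TestRegressions:
    def test_linear_load_slope_recovered(self, rng):
        # noise sd 0.6 gives sd(y) = 1, so the standardized slope is -0.8
        load = np.tile(np.arange(6), 12)
        zload = (load - load.mean()) / load.std()
        y = -0.8 * zload + 0.6 * rng.standard_normal(load.size)
        rep = load_regression(y, load, form="linear")["report"]
        row = rep.table.loc["load"]
        se = (row["ci_high"] - row["ci_low"]) / (2 * 1.96)
        assert abs(row["beta_sd"] - (-0.8)) < 2 * se
        assert row["beta_sd"] == pytest.approx(-0.8, abs=0.15)

    def test_quadratic_vertex_recovered(self, rng):
        load = np.tile(np.arange(6), 10).astype(float)
        y = -(load - 3.0) ** 2 + 0.05 * rng.standard_normal(load.size)
        out = load_regression(y, load, form="quadratic")
        assert out["vertex"] == pytest.approx(3.0, abs=0.1)
        assert out["report"].beta("load_sq") < 0

    def test_quadratic_needs_three_levels(self):
        with pytest.raises(ValueError):
            load_regression(np.arange(4.0), np.array([0, 0, 1, 1]), "quadratic")

    def test_switch_optimum_noise_free_parabola(self):
        x = np.arange(1, 15, dtype=float)
        out = switch_performance_regression(x, -(x - 5.0) ** 2)
        assert out["optimal_switches"] == pytest.approx(5.0)

    def test_switch_optimum_at_nine_with_noise(self, rng):
        x = rng.integers(2, 17, size=120).astype(float)
        y = (x - 9.0) ** 2 + rng.standard_normal(x.size)
        out = switch_performance_regression(x, y)
        assert out["optimal_switches"] == pytest.approx(9.0, abs=0.3)

    def test_linear_outcome_has_no_curvature(self, rng):
        x = np.arange(30.0)
        out = switch_performance_regression(x, 2 * x + rng.normal(0, 1e-9, 30))
        assert abs(out["report"].beta("switches_sq")) < 1e-3


class TestPC1:
    def test_perfectly_correlated_tests(self, rng):
        base = rng.standard_normal(40)
        scores = np.column_stack([base, 2 * base + 1, -0.5 * base])
        out = pc1_performance(scores)
        assert out["explained_variance_ratio"] == pytest.approx(1.0)

    def test_anticorrelated_pair_splits_variance(self, rng):
        a = rng.standard_normal(2000)
        out = pc1_performance(np.column_stack([a, -a + 1e-9 * rng.standard_normal(2000)]))
        assert out["explained_variance_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_sign_fixed_to_mean_performance(self, rng):
        base = rng.standard_normal(60)
        scores = np.column_stack([base + 0.2 * rng.standard_normal(60)
                                  for _ in range(3)])
        out = pc1_performance(scores)
        assert np.corrcoef(out["pc1"], scores.mean(axis=1))[0, 1] > 0.9

    def test_loading_recovery(self, rng):
        # one common factor with per-test noise levels; since PC1 acts on
        # z-scored tests, the expected loadings are the top eigenvector of
        # the analytic correlation matrix (independent closed-form oracle)
        sigma = np.array([0.3, 0.6, 1.0])
        f = rng.standard_normal(20000)
        scores = f[:, None] + sigma * rng.standard_normal((20000, 3))
        col_sd = np.sqrt(1 + sigma ** 2)
        R = np.outer(1 / col_sd, 1 / col_sd)
        np.fill_diagonal(R, 1.0)
        evals, evecs = np.linalg.eigh(R)
        expected = np.abs(evecs[:, -1])
        out = pc1_performance(scores)
        got = np.abs(out["loadings"] / np.linalg.norm(out["loadings"]))
        assert np.allclose(got, expected, atol=0.05)

    def test_constant_column_rejected(self, rng):
        with pytest.raises(ValueError):
            pc1_performance(np.column_stack([np.ones(10), rng.random(10)]))


class TestDistractorContrast:
    windows = [(1.5, 2.0), (2.5, 3.0), (3.5, 4.0)]
    directions = [-1, -1, +1]

    def _pair_from_effect(self, rng, n_subj=13, effect_ms=100.0, sd_ms=50.0,
                          rate=100.0, T=450):
        """Two label sequences whose state-1 dwell differs by a planted effect."""
        dist = np.full((n_subj, T), 2)
        ctrl = np.full((n_subj, T), 2)
        for s in range(n_subj):
            for (a, b), sign in zip(self.windows, self.directions):
                i0 = int(a * rate)
                base = 0.25  # control dwell fraction of the 0.5 s window
                delta = sign * (effect_ms + sd_ms * rng.standard_normal()) / 1000.0
                n_ctrl = int(round(base * rate))
                n_dist = int(round((base * 0.5 + delta) * rate + n_ctrl * 0.5))
                ctrl[s, i0:i0 + n_ctrl] = 1
                dist[s, i0:i0 + max(n_dist, 0)] = 1
        return (StateSequence(labels=dist, sampling_rate=rate),
                StateSequence(labels=ctrl, sampling_rate=rate))

    def test_identical_conditions_zero_effect(self):
        seq = StateSequence(labels=np.tile([1, 2, 3, 1], (5, 120)),
                            sampling_rate=100.0)
        with pytest.raises(ValueError):  # zero-variance differences guarded
            distractor_contrast(seq, seq, self.windows, self.directions)

    def test_planted_effect_detected_with_expected_d(self, rng):
        ds = []
        for _ in range(6):
            dist, ctrl = self._pair_from_effect(rng)
            rep, per = distractor_contrast(dist, ctrl, self.windows,
                                           self.directions)
            ds.append(rep.d)
        # planted 100 ms effect with 50 ms sd, averaged over 3 windows
        assert np.mean(ds) > 1.0
        assert rep.sidedness == "one"

    def test_direction_validation(self):
        seq = StateSequence(labels=np.ones((3, 500), dtype=int),
                            sampling_rate=100.0)
        with pytest.raises(ValueError, match="expected_direction"):
            distractor_contrast(seq, seq, self.windows, [0, 1, -1])
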