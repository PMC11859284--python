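"""K-Means distance thresholding, penalized loss, contamination experiment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ntxent_bruteforce

from clumm.contrastive import PretrainConfig, nt_xent_loss
from clumm.encoder import EncoderConfig
from clumm.landmarks import FEATURE_DIM
from clumm.outliers import (
    analyze,
    cluster_spread_stats,
    flag_outliers,
    kmeans,
    landmark_outlier_analysis,
    nearest_centroid_distances,
    outlier_experiment,
    outlier_threshold,
    penalized_nt_xent,
)
from clumm.probe import ProbeConfig
from clumm.synth import (
    MotionClassSpec,
    SyntheticDatasetConfig,
    generate_dataset,
    inject_outliers,
)


class TestKMeans:
    def test_one_point_per_cluster_gives_zero_wcss(self, rng):
        X = rng.normal(size=(4, FEATURE_DIM)) * 10
        model = kmeans(X, c=4, seed=0)
        assert model.wcss == pytest.approx(0.0, abs=1e-18)
        assert sorted(model.assignments) == [0, 1, 2, 3]

    @pytest.mark.filterwarnings("ignore:Number of distinct clusters")
    def test_identical_rows_give_zero_wcss(self):
        X = np.tile(np.linspace(0, 1, FEATURE_DIM), (20, 1))
        model = kmeans(X, c=3, seed=0)
        assert model.wcss == pytest.approx(0.0, abs=1e-18)

    def test_two_blobs_recover_blob_means(self, rng):
        a = rng.normal(size=(50, FEATURE_DIM)) * 0.01
        b = 5.0 + rng.normal(size=(50, FEATURE_DIM)) * 0.01
        model = kmeans(np.vstack([a, b]), c=2, seed=0)
        means = sorted(model.centroids.mean(axis=1))
        assert means[0] == pytest.approx(a.mean(), abs=0.01)
        assert means[1] == pytest.approx(b.mean(), abs=0.01)

    def test_stored_wcss_matches_recomputation(self, small_dataset):
        model = kmeans(small_dataset, c=3, seed=0)
        recomputed = sum(
            ((small_dataset.values[model.assignments == i] - model.centroids[i]) ** 2).sum()
            for i in range(3)
        )
        assert model.wcss == pytest.approx(recomputed, abs=1e-9)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.normal(size=(2, FEATURE_DIM)), c=3)


class TestDistances:
    def test_point_at_centroid_has_zero_distance(self, small_dataset):
        model = kmeans(small_dataset, c=3, seed=0)
        d = nearest_centroid_distances(model.centroids, model)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_pythagorean_distance(self):
        from clumm.outliers import ClusterModel

        model = ClusterModel(
            n_clusters=1,
            centroids=np.zeros((1, FEATURE_DIM)),
            assignments=np.zeros(1, dtype=int),
            wcss=0.0,
        )
        point = np.zeros((1, FEATURE_DIM))
        point[0, 0], point[0, 1] = 3.0, 4.0
        assert nearest_centroid_distances(point, model)[0] == pytest.approx(5.0)

    def test_matches_exhaustive_minimization(self, rng, small_dataset):
        model = kmeans(small_dataset, c=3, seed=0)
        X = rng.normal(size=(40, FEATURE_DIM))
        d = nearest_centroid_distances(X, model)
        brute = np.array(
            [min(np.linalg.norm(x - mu) for mu in model.centroids) for x in X]
        )
        np.testing.assert_allclose(d, brute, atol=1e-12)


class TestThreshold:
    def test_constant_distances(self):
        t, mu, sigma = outlier_threshold(np.full(10, 2.5))
        assert (t, mu, sigma) == (2.5, 2.5, 0.0)
        mask, frac = flag_outliers(np.full(10, 2.5), t)
        assert frac == 0.0  # strict inequality: boundary points are inliers

    def test_hand_computed_example_with_population_sd(self):
        """(1,1,1,1,5): mean 1.8, population sd 1.6, threshold exactly 5.0."""
        d = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
        t, mu, sigma = outlier_threshold(d)
        assert mu == pytest.approx(1.8)
        assert sigma == pytest.approx(1.6)
        assert t == pytest.approx(5.0)
        mask, _ = flag_outliers(d, t)
        assert mask.sum() == 0  # 5.0 is on the boundary, not beyond it

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance(self, shift):
        d = np.array([0.2, 0.5, 1.0, 3.0, 0.7])
        t0, _, _ = outlier_threshold(d)
        t1, _, _ = outlier_threshold(d + shift)
        assert t1 == pytest.approx(t0 + shift, abs=1e-9)

    def test_empty_distances_rejected(self):
        with pytest.raises(ValueError):
            outlier_threshold(np.array([]))


class TestClusterSpread:
    def test_singleton_cluster_has_zero_spread(self, rng):
        X = rng.normal(size=(3, FEATURE_DIM)) * 10
        model = kmeans(X, c=3, seed=0)
        means, maxes = cluster_spread_stats(X, model)
        np.testing.assert_allclose(means, 0.0, atol=1e-12)
        np.testing.assert_allclose(maxes, 0.0, atol=1e-12)

    def test_symmetric_pair(self):
        X = np.zeros((2, FEATURE_DIM))
        X[1, 0] = 2.0
        model = kmeans(X, c=1, seed=0)
        means, maxes = cluster_spread_stats(X, model)
        assert means[0] == pytest.approx(1.0)
        assert maxes[0] == pytest.approx(1.0)

    def test_matches_per_member_loop(self, small_dataset):
        model = kmeans(small_dataset, c=3, seed=0)
        means, maxes = cluster_spread_stats(small_dataset, model)
        for i in range(3):
            member_d = [
                np.linalg.norm(row - model.centroids[i])
                for row, a in zip(small_dataset.values, model.assignments)
                if a == i
            ]
            assert means[i] == pytest.approx(np.mean(member_d))
            assert maxes[i] == pytest.approx(np.max(member_d))


class TestFlagging:
    def test_injected_far_outliers_are_flagged(self, small_dataset, rng):
        report_clean = analyze(small_dataset, c=3, seed=0)
        offset = 10 * report_clean.mean_distance
        far = MotionClassSpec(
            name="far",
            prototype=lambda p: np.full((10, 3), 0.5) + offset,
            noise_sd=0.02,
            dropout_rate=0.0,
        )
        contaminated, truth = inject_outliers(small_dataset, far, 20, rng)
        reference_model = kmeans(small_dataset, c=3, seed=0)
        report = analyze(contaminated, model=reference_model)
        recall = report.outlier_mask[truth].mean()
        assert recall >= 0.95
        # false-positive rate on the genuine frames stays small
        assert report.outlier_mask[~truth].mean() < 0.05

    def test_mask_consistency_invariant(self, small_dataset):
        report = analyze(small_dataset, c=3, seed=0)
        np.testing.assert_array_equal(
            report.outlier_mask, report.distances > report.threshold
        )
        assert report.outlier_fraction == pytest.approx(report.outlier_mask.mean())

    def test_threshold_covers_bulk_of_unimodal_data(self, small_dataset):
        report = analyze(small_dataset, c=3, seed=0)
        assert report.outlier_fraction <= 0.1

    def test_per_landmark_report_structure(self, small_dataset):
        audit = landmark_outlier_analysis(small_dataset, c=3, seed=0)
        assert audit["per_landmark_fraction"].shape == (10,)
        assert 0.0 <= audit["pct_outlier_landmarks"] <= 1.0
        assert audit["max_outlier_distance"] >= audit["mean_outlier_distance"] >= 0.0


class TestPenalizedLoss:
    def test_reduces_exactly_to_unpenalized_when_no_outliers(self, rng):
        z1, z2 = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        plain = nt_xent_loss(z1, z2, 0.5)
        penalized = penalized_nt_xent(z1, z2, 0.5, omega=np.zeros(4), lam=3.0, delta=1.0)
        assert penalized == plain

    def test_flagged_anchor_strictly_increases_loss(self, rng):
        z1, z2 = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        omega = np.array([1.0, 0.0, 0.0, 0.0])
        plain = nt_xent_loss(z1, z2, 0.5)
        penalized = penalized_nt_xent(z1, z2, 0.5, omega=omega, lam=2.0, delta=1.5)
        assert penalized > plain

    def test_matches_direct_formula(self, rng):
        """Independent evaluation: explicit per-anchor denominator + lam*delta*omega."""
        import math

        b = 5
        z1, z2 = rng.normal(size=(b, 8)), rng.normal(size=(b, 8))
        omega = rng.integers(0, 2, size=b).astype(float)
        lam, delta, tau = 1.7, 0.8, 0.4
        views = [v for v in np.vstack([z1, z2])]
        omega2 = np.tile(omega, 2)

        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        total = 0.0
        for i in range(2 * b):
            pos = (i + b) % (2 * b)
            num = math.exp(cos(views[i], views[pos]) / tau)
            den = sum(
                math.exp(cos(views[i], views[k]) / tau) for k in range(2 * b) if k != i
            ) + lam * delta * omega2[i]
            total += -math.log(num / den)
        expected = total / (2 * b)
        got = penalized_nt_xent(z1, z2, tau, omega=omega, lam=lam, delta=delta)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_oracle_agreement_with_unpenalized_bruteforce(self, rng):
        z1, z2 = rng.normal(size=(3, 8)), rng.normal(size=(3, 8))
        assert penalized_nt_xent(z1, z2, 0.5, np.zeros(3), lam=0.0) == pytest.approx(
            ntxent_bruteforce(z1, z2, 0.5), abs=1e-9
        )


class TestOutlierExperiment:
    def test_smoke_report_and_count_zero_identity(self):
        matrix = generate_dataset(SyntheticDatasetConfig(frames_per_class=40, seed=2))
        rows = outlier_experiment(
            matrix,
            [0, 10],
            encoder_config=EncoderConfig(kind="mlp", repr_dim=32, mlp_hidden=32),
            pretrain_config=PretrainConfig(epochs=2, batch_size=32, seed=2),
            probe_config=ProbeConfig(epochs=20, seed=2),
            seed=2,
        )
        assert [r.n_outliers for r in rows] == [0, 10]
        for r in rows:
            assert 0.0 <= r.accuracy <= 1.0
            assert r.max_outlier_distance >= r.mean_outlier_distance

        # the count-0 row equals the uncontaminated pipeline run
        from clumm.contrastive import pretrain
        from clumm.probe import cross_validate

        result = pretrain(
            matrix,
            EncoderConfig(kind="mlp", repr_dim=32, mlp_hidden=32),
            config=PretrainConfig(epochs=2, batch_size=32, seed=2),
        )
        _, mean = cross_validate(result.encoder, matrix, ProbeConfig(epochs=20, seed=2))
        assert rows[0].accuracy == pytest.approx(mean.accuracy)
        assert rows[0].f1 == pytest.approx(mean.f1)
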