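"""Classifier stages: sphering, ICA, seed patches, slice SVM, (iterative) FLDA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trioseg import BrainMask
from trioseg.classifier import (
    LabeledSampleSet, SegmentConfig, extract_seed_samples, fit_flda, fit_sphering,
    flda_classify, ica_unmix, iterate_flda, scatter_matrices, segment,
    svm_classify_slice,
)
from trioseg.phantom import default_seeds
from trioseg.types import TrainingSeeds


# ---------------------------------------------------------------------- sphering

class TestSphering:
    def test_removes_first_two_moments(self):
        rng = np.random.default_rng(0)
        X = rng.normal([10.0, 20.0], [2.0, 3.0], size=(500, 2))
        model = fit_sphering(X)
        Z = model.transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-8
        cov = np.cov(Z, rowvar=False, ddof=1)
        assert np.abs(cov - np.eye(2)).max() < 1e-6

    def test_invertible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3)) @ rng.normal(size=(3, 3)) + 5.0
        model = fit_sphering(X)
        np.testing.assert_allclose(model.inverse_transform(model.transform(X)), X,
                                   atol=1e-8)

    def test_constant_channel_without_ridge_rejected(self):
        X = np.column_stack([np.arange(50.0), np.full(50, 3.0)])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_sphering(X)
        fit_sphering(X, ridge=1e-3)  # regularized fit succeeds

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="C\\+1"):
            fit_sphering(np.zeros((3, 3)))


# ---------------------------------------------------------------------- ICA

class TestIca:
    @staticmethod
    def _mixed_uniforms(seed=0, n=20000):
        rng = np.random.default_rng(seed)
        sources = rng.uniform(-1, 1, (n, 2))
        mixed = sources @ np.array([[1.0, 0.6], [0.4, 1.0]]).T
        return sources, mixed

    def test_recovers_independent_uniform_sources(self):
        sources, mixed = self._mixed_uniforms()
        sph = fit_sphering(mixed)
        _, scores = ica_unmix(sph.transform(mixed), seed=0)
        corr = np.corrcoef(np.hstack([scores, sources]).T)[:2, 2:]
        # each recovered component matches one true source almost perfectly
        assert sorted(np.abs(corr).max(axis=1) > 0.95) == [True, True]

    def test_unmixing_mixing_are_inverse_pair(self):
        _, mixed = self._mixed_uniforms(seed=1)
        model, _ = ica_unmix(fit_sphering(mixed).transform(mixed), seed=0)
        np.testing.assert_allclose(model.unmixing @ model.mixing, np.eye(2), atol=1e-6)

    def test_deterministic_given_seed(self):
        _, mixed = self._mixed_uniforms(seed=2)
        Z = fit_sphering(mixed).transform(mixed)
        m1, s1 = ica_unmix(Z, seed=7)
        m2, s2 = ica_unmix(Z, seed=7)
        assert np.array_equal(m1.unmixing, m2.unmixing)
        assert np.array_equal(s1, s2)

    def test_unsphered_input_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="not sphered"):
            ica_unmix(rng.normal(0, 5.0, (500, 2)))


# ---------------------------------------------------------------------- seed patches

class TestSeedExtraction:
    @staticmethod
    def _fvol(shape=(20, 20, 5, 2)):
        return np.arange(np.prod(shape), dtype=float).reshape(shape)

    def test_default_patches_give_36_samples(self):
        seeds = TrainingSeeds(2, {0: (2, 2), 1: (8, 8), 2: (14, 14), 3: (2, 14)})
        out = extract_seed_samples(self._fvol(), seeds)
        assert out.features.shape == (36, 2)
        assert np.bincount(out.labels).tolist() == [9, 9, 9, 9]
        assert out.provenance == "seed"

    def test_patch_size_one_gives_four_samples(self):
        seeds = TrainingSeeds(0, {0: (1, 1), 1: (5, 5), 2: (9, 9), 3: (13, 13)},
                              patch_size=1)
        assert extract_seed_samples(self._fvol(), seeds).features.shape == (4, 2)

    def test_edge_patch_rejected_naming_class(self):
        seeds = TrainingSeeds(0, {0: (0, 5), 1: (8, 8), 2: (14, 14), 3: (2, 14)})
        with pytest.raises(ValueError, match="class 0"):
            extract_seed_samples(self._fvol(), seeds)

    def test_overlapping_patches_rejected(self):
        seeds = TrainingSeeds(0, {1: (8, 8), 2: (8, 9)})
        with pytest.raises(ValueError, match="overlaps"):
            extract_seed_samples(self._fvol(), seeds)

    def test_out_of_mask_patch_rejected(self):
        seeds = TrainingSeeds(1, {1: (8, 8)})
        mask = BrainMask(np.zeros((20, 20, 5), bool))
        with pytest.raises(ValueError, match="outside the mask"):
            extract_seed_samples(self._fvol(), seeds, mask=mask)


# ---------------------------------------------------------------------- slice SVM

def _blobs(seed=1, n=500, spread=0.5):
    rng = np.random.default_rng(seed)
    means = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [0, 0, 6]], float)
    X = np.vstack([rng.normal(m, spread, (n, 3)) for m in means])
    y = np.repeat(np.arange(4), n)
    return X, y


class TestSvmSlice:
    def test_separable_blobs_recovered(self):
        X, y = _blobs()
        seed_idx = np.concatenate([np.flatnonzero(y == c)[:9] for c in range(4)])
        seeds = LabeledSampleSet(X[seed_idx], y[seed_idx], "seed")
        out = svm_classify_slice(seeds, X)
        assert (out.labels == y).mean() >= 0.99
        assert out.provenance == "svm_slice"
        assert out.features.shape[0] == X.shape[0]

    def test_seed_self_consistency(self):
        X, y = _blobs(seed=2)
        seed_idx = np.concatenate([np.flatnonzero(y == c)[:9] for c in range(4)])
        seeds = LabeledSampleSet(X[seed_idx], y[seed_idx], "seed")
        out = svm_classify_slice(seeds, seeds.features)
        assert (out.labels == seeds.labels).mean() >= 0.95

    def test_missing_class_rejected(self):
        X, y = _blobs()
        keep = y < 3
        seeds = LabeledSampleSet(X[keep][:27], y[keep][:27], "seed")
        with pytest.raises(ValueError, match="lack required classes"):
            svm_classify_slice(seeds, X)

    def test_empty_slice_rejected(self):
        X, y = _blobs()
        seed_idx = np.concatenate([np.flatnonzero(y == c)[:9] for c in range(4)])
        seeds = LabeledSampleSet(X[seed_idx], y[seed_idx], "seed")
        with pytest.raises(ValueError, match="no in-mask voxels"):
            svm_classify_slice(seeds, np.empty((0, 3)))


# ---------------------------------------------------------------------- FLDA

TOY = LabeledSampleSet(np.array([[0.0], [1.0], [4.0], [5.0]]),
                       np.array([1, 1, 2, 2]), "seed")


class TestFlda:
    def test_toy_scatter_values(self):
        # class means 0.5 and 4.5, global mean 2.5
        model = fit_flda(TOY)
        assert model.S_W[0, 0] == pytest.approx(1.0)
        assert model.S_B[0, 0] == pytest.approx(16.0)
        assert model.S_T[0, 0] == pytest.approx(17.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scatter_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3)) * rng.uniform(0.5, 3.0, 3) + rng.normal(size=3)
        y = rng.integers(0, 3, 40)
        if min(np.bincount(y, minlength=3)) < 2:
            y[:6] = [0, 0, 1, 1, 2, 2]
        S_W, S_B, S_T, _ = scatter_matrices(X, y)
        scale = max(np.abs(S_T).max(), 1.0)
        assert np.abs(S_T - (S_W + S_B)).max() / scale < 1e-8

    def test_four_classes_give_three_projection_vectors(self):
        X, y = _blobs(n=30)
        model = fit_flda(LabeledSampleSet(X, y, "seed"))
        assert model.projection.shape == (3, 3)
        assert model.centroids.shape == (4, 3)

    def test_projection_maximizes_fisher_ratio(self):
        # brute-force direction search over the unit circle as the oracle
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal([0, 0], [1, 2], (200, 2)),
                       rng.normal([3, 1], [1.5, 0.5], (200, 2))])
        y = np.repeat([1, 2], 200)
        model = fit_flda(LabeledSampleSet(X, y, "seed"), ridge=0.0)
        fitted = model.fisher_ratio(model.projection[:, 0])
        angles = np.linspace(0, np.pi, 20001)
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        brute = max(model.fisher_ratio(d) for d in dirs)
        assert fitted == pytest.approx(brute, rel=1e-3)

    def test_singular_within_scatter_without_ridge_rejected(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([1, 1, 2, 2])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_flda(LabeledSampleSet(X, y, "seed"), ridge=0.0)
        fit_flda(LabeledSampleSet(X, y, "seed"), ridge=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_flda(LabeledSampleSet(np.zeros((4, 2)), np.zeros(4, int), "seed"))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_flda(LabeledSampleSet(np.zeros((3, 2)), np.array([1, 1, 2]), "seed"))


class TestFldaClassify:
    def test_centroids_classify_to_own_class(self):
        X, y = _blobs(n=30)
        model = fit_flda(LabeledSampleSet(X, y, "seed"))
        means = np.stack([X[y == c].mean(axis=0) for c in range(4)])
        assert flda_classify(model, means).tolist() == [0, 1, 2, 3]

    def test_tie_goes_to_lowest_class_code(self):
        model = fit_flda(TOY)
        midpoint = np.array([[2.5]])  # equidistant from centroids 0.5 and 4.5
        assert flda_classify(model, midpoint)[0] == 1

    def test_toy_point_near_first_class(self):
        model = fit_flda(TOY)
        assert flda_classify(model, np.array([[0.4]]))[0] == 1

    def test_dimension_mismatch_rejected(self):
        model = fit_flda(TOY)
        with pytest.raises(ValueError, match="dimension"):
            flda_classify(model, np.zeros((2, 3)))


class TestIterateFlda:
    def test_degenerate_tolerance_stops_after_one_iteration(self):
        X, y = _blobs(n=30)
        initial = LabeledSampleSet(X, y, "svm_slice")
        _, trace, _ = iterate_flda(initial, X, tolerance=1.0)
        assert trace.n_iterations == 1 and trace.converged

    def test_max_iterations_caps_trace(self):
        X, y = _blobs(n=30, spread=3.0)  # overlapping: won't settle in one pass
        initial = LabeledSampleSet(X, y, "svm_slice")
        _, trace, _ = iterate_flda(initial, X, tolerance=0.0, max_iterations=1)
        assert trace.n_iterations == 1

    def test_separable_data_reaches_fixed_point_by_second_iteration(self):
        X, y = _blobs(n=50, spread=0.2)
        initial = LabeledSampleSet(X, y, "svm_slice")
        labels, trace, _ = iterate_flda(initial, X, tolerance=0.0)
        assert trace.converged
        assert trace.n_iterations == 2
        assert trace.changed_fractions[-1] == 0.0
        assert (labels == y).all()


# ---------------------------------------------------------------------- pipeline

class TestSegment:
    def test_zero_noise_phantom_recovered_exactly(self, full_mask):
        from trioseg.phantom import PhantomSpec, render_phantom
        ph = render_phantom(PhantomSpec(grid_shape=(32, 32, 32)))
        seeds = default_seeds(ph.spec)
        labels, trace, _ = segment(ph.image, full_mask, seeds)
        assert np.array_equal(labels.labels, ph.truth.labels)
        assert trace.converged and trace.changed_fractions[-1] == 0.0

    def test_pipeline_deterministic(self, small_phantom, small_seeds, full_mask):
        cfg = SegmentConfig()
        a, trace_a, _ = segment(small_phantom.image, full_mask, small_seeds, cfg)
        b, trace_b, _ = segment(small_phantom.image, full_mask, small_seeds, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert trace_a.changed_fractions == trace_b.changed_fractions

    def test_ica_disabled_still_segments(self, small_phantom, small_seeds, full_mask):
        cfg = SegmentConfig(use_ica=False)
        labels, trace, models = segment(small_phantom.image, full_mask, small_seeds, cfg)
        assert "ica" not in models
        assert (labels.labels == small_phantom.truth.labels).mean() > 0.99

    def test_config_roundtrip(self, tmp_path):
        cfg = SegmentConfig(use_ica=False, svm_cost=2.0, max_iterations=7)
        path = tmp_path / "config.yaml"
        cfg.save(path)
        assert SegmentConfig.load(path) == cfg
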