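"""Montage mirroring, windowed features, PCA/LDA, and the three decoding
configurations."""

import numpy as np
import pytest

from reachdecode.decoding import (
    DecodeResult,
    MIRRORED_MONTAGE,
    STANDARD_MONTAGE,
    WINDOW_SAMPLE_OFFSETS,
    cross_hand_eval,
    extract_features,
    fit_pca,
    lda_predict,
    lda_train,
    mirror_channels,
    mirror_permutation,
    run_classifier,
    window_starts,
    within_hand_cv,
)
from reachdecode.task_model import classifier_groups

GROUPS = classifier_groups()


class TestMontage:
    def test_standard_and_mirrored_printed_orders(self):
        assert STANDARD_MONTAGE == (
            "F1", "F3", "F5", "FC5", "FC3", "FC1", "C1", "C3", "C5", "CP5", "CP3",
            "CP1", "P1", "P3", "P5", "F2", "F4", "F6", "FC6", "FC4", "FC2", "C2",
            "C4", "C6", "CP6", "CP4", "CP2", "P2", "P4", "P6",
        )
        assert MIRRORED_MONTAGE == (
            "F2", "F4", "F6", "FC6", "FC4", "FC2", "C2", "C4", "C6", "CP6", "CP4",
            "CP2", "P2", "P4", "P6", "F1", "F3", "F5", "FC5", "FC3", "FC1", "C1",
            "C3", "C5", "CP5", "CP3", "CP1", "P1", "P3", "P5",
        )

    def test_permutation_is_involution(self):
        perm = mirror_permutation()
        assert np.array_equal(perm[perm], np.arange(30))

    def test_mirror_moves_partner_signal_into_position(self):
        # epoch whose channel c carries the constant value c
        epochs = np.tile(np.arange(30.0)[None, :, None], (2, 1, 150))
        mirrored = mirror_channels(epochs)
        # position 0 (F1) must now hold F2's signal (channel index 15)
        assert np.all(mirrored[:, 0] == 15)
        assert np.array_equal(mirror_channels(mirrored), epochs)

    def test_midline_symmetric_pattern_unchanged(self):
        from reachdecode.synthetic_session import SpatialPatternSet

        pat = SpatialPatternSet.default().s_act
        epochs = np.tile(pat[None, :, None], (3, 1, 150))
        assert np.array_equal(mirror_channels(epochs), epochs)


class TestWindows:
    def test_fifteen_starts_inside_epoch(self):
        for phase in ("planning", "execution"):
            starts = window_starts(phase)
            assert len(starts) == 15
            assert starts[0] == 0.0 and starts[-1] == pytest.approx(1.4)
            assert np.all(starts + 0.4 <= 1.8)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            window_starts("resting")

    def test_feature_vector_dimension_and_layout(self):
        n_tr = 4
        data = np.zeros((n_tr, 30, 150))
        for c in range(30):
            data[:, c, :] = 1000.0 * c + np.arange(150)
        feats = extract_features(data, 0.2)
        assert feats.shape == (n_tr, 270)
        i0 = int(round((0.2 + 1.0) * 50))
        for c in (0, 7, 29):
            for s in range(9):
                assert feats[0, c * 9 + s] == 1000.0 * c + i0 + WINDOW_SAMPLE_OFFSETS[s]

    def test_constant_epoch_gives_all_ones(self):
        feats = extract_features(np.ones((2, 30, 150)), 1.4)
        assert np.array_equal(feats, np.ones((2, 270)))

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_features(np.ones((2, 30, 150)), 1.7)


class TestPca:
    def test_exact_low_rank_pool(self):
        rng = np.random.default_rng(3)
        u, v = rng.normal(size=270), rng.normal(size=270)
        coeff = rng.normal(size=(20, 2))
        x = coeff @ np.stack([u, v])
        proj = fit_pca(x, var_frac=0.85)
        assert proj.k == 2
        assert proj.explained_variance_ratio.sum() >= 0.85

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 40))
        proj = fit_pca(x, var_frac=0.85)
        cov = np.cov(x.T, bias=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        ratios = evals / evals.sum()
        k_oracle = int(np.argmax(np.cumsum(ratios) >= 0.85)) + 1
        assert proj.k == k_oracle
        assert np.allclose(proj.explained_variance_ratio, ratios[: proj.k])
        for i in range(proj.k):
            assert abs(proj.components[i] @ evecs[:, i]) == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_components(self):
        rng = np.random.default_rng(5)
        proj = fit_pca(rng.normal(size=(30, 50)))
        g = proj.components @ proj.components.T
        assert np.allclose(g, np.eye(proj.k), atol=1e-10)

    def test_degenerate_pools_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca(np.ones((5, 10)))
        with pytest.raises(ValueError, match="2 trials"):
            fit_pca(np.ones((1, 10)))


class TestLda:
    def _clouds(self, sep=6.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        x0 = rng.normal(size=(n, 2))
        x1 = rng.normal(size=(n, 2)) + [sep, 0.0]
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], n)
        return x, y

    def test_separable_clouds_perfect_training_accuracy(self):
        x, y = self._clouds()
        model = lda_train(x, y)
        assert np.mean(lda_predict(model, x) == y) == 1.0

    def test_weights_parallel_to_mean_difference_under_isotropy(self):
        x, y = self._clouds(sep=2.0, n=4000, seed=1)
        model = lda_train(x, y)
        d = x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0)
        cos = model.weights @ d / np.linalg.norm(model.weights) / np.linalg.norm(d)
        assert cos > 0.99

    def test_label_swap_negates_decision_exactly(self):
        x, y = self._clouds(sep=2.0, seed=2)
        m1 = lda_train(x, y)
        m2 = lda_train(x, 1 - y)
        assert np.array_equal(m1.decision(x), -m2.decision(x))
        assert np.mean(lda_predict(m1, x) == y) == np.mean(lda_predict(m2, x) == 1 - y)

    def test_matches_sklearn_discriminant(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x, y = self._clouds(sep=3.0, seed=3)
        ours = lda_predict(lda_train(x, y), x)
        ref = LinearDiscriminantAnalysis().fit(x, y).predict(x)
        assert np.array_equal(ours, ref)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            lda_train(np.ones((4, 2)), np.zeros(4))


class TestPeakSelection:
    def test_peak_is_brute_force_max_earliest_tie(self):
        starts = window_starts("planning")
        accs = np.full(15, 0.5)
        accs[[4, 9]] = 0.9
        res = DecodeResult(window_starts=starts, accuracies=accs, n_test=np.full(15, 80))
        assert res.peak == max(accs)
        assert res.peak_time == pytest.approx(starts[4])


class TestWithinHand:
    def test_deterministic_under_seed(self, small_pre):
        spec = GROUPS[("within", "action")][0]
        a = within_hand_cv(small_pre.planning, spec, seed=7)
        b = within_hand_cv(small_pre.planning, spec, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_noise_free_pool_perfect_at_source_window(self, clean_act_pre):
        spec = GROUPS[("within", "action")][0]
        res = within_hand_cv(clean_act_pre.planning, spec, windows=[0.3, 0.4])
        assert res.peak == 1.0

    def test_fold_reduction_warning_on_small_pool(self, clean_act_pre):
        spec = GROUPS[("within", "action")][0]
        sub = clean_act_pre.planning.subset(spec.train_pair)
        small = type(sub)(
            data=sub.data[:12],
            alignment=sub.alignment,
            conditions=sub.conditions[:12],
            trial_ids=sub.trial_ids[:12],
        )
        with pytest.warns(UserWarning, match="reducing"):
            within_hand_cv(small, spec, windows=[0.4])


class TestCrossHand:
    def test_extrinsic_intrinsic_accuracies_complement_exactly(self, small_pre):
        ext = GROUPS[("cross", "direction", "extrinsic", "standard")][0]
        intr = GROUPS[("cross", "direction", "intrinsic", "standard")][0]
        assert ext.train_pair == intr.train_pair and ext.test_pair == intr.test_pair
        a = cross_hand_eval(small_pre.execution, small_pre.execution, ext)
        b = cross_hand_eval(small_pre.execution, small_pre.execution, intr)
        assert np.array_equal(a.accuracies + b.accuracies, np.ones(15))

    def test_matched_encoding_noise_free_is_perfect(self, clean_ext_pre):
        spec = GROUPS[("cross", "direction", "extrinsic", "standard")][0]
        res = cross_hand_eval(clean_ext_pre.execution, clean_ext_pre.execution, spec,
                              windows=[0.3, 0.4, 0.5])
        assert res.peak == 1.0

    def test_mirror_intrinsic_matches_hand_mirrored_encoding(self, clean_int_pre):
        spec = GROUPS[("cross", "direction", "intrinsic", "mirror")][0]
        res = cross_hand_eval(clean_int_pre.execution, clean_int_pre.execution, spec,
                              windows=[0.3, 0.4, 0.5])
        assert res.peak == 1.0

    def test_symmetric_action_source_invariant_to_montage(self, clean_act_pre):
        """With a midline-symmetric source and no noise, mirroring the test
        montage changes nothing, bit for bit."""
        std = GROUPS[("cross", "action", "extrinsic", "standard")][0]
        mir = GROUPS[("cross", "action", "extrinsic", "mirror")][0]
        wins = [0.2, 0.3, 0.4]
        a = cross_hand_eval(clean_act_pre.execution, clean_act_pre.execution, std, windows=wins)
        b = cross_hand_eval(clean_act_pre.execution, clean_act_pre.execution, mir, windows=wins)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_run_classifier_dispatch(self, small_pre):
        within = GROUPS[("within", "direction")][0]
        cross = GROUPS[("cross", "direction", "extrinsic", "standard")][0]
        assert run_classifier(small_pre.planning, within, seed=1).spec is within
        assert run_classifier(small_pre.planning, cross).spec is cross

    def test_pca_scope_modes_differ_but_both_run(self, small_pre):
        spec = GROUPS[("cross", "direction", "extrinsic", "standard")][0]
        pool = cross_hand_eval(small_pre.execution, small_pre.execution, spec, windows=[0.4])
        train = cross_hand_eval(small_pre.execution, small_pre.execution, spec,
                                pca_scope="train_only", windows=[0.4])
        assert pool.pca_scope == "pool" and train.pca_scope == "train_only"


class TestNullCalibration:
    def test_shuffled_labels_near_chance(self, small_pre):
        """A label-shuffled pool cannot be decoded above chance."""
        rng = np.random.default_rng(0)
        spec = GROUPS[("within", "action")][0]
        pool = small_pre.planning.subset(spec.train_pair)
        shuffled = type(pool)(
            data=pool.data[rng.permutation(len(pool))],
            alignment=pool.alignment,
            conditions=pool.conditions,
            trial_ids=pool.trial_ids,
        )
        res = within_hand_cv(shuffled, spec, windows=[0.4], seed=3)
        n = len(pool)
        band = 1.96 * np.sqrt(0.25 / n)
        assert abs(res.accuracies[0] - 0.5) < band + 0.05
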