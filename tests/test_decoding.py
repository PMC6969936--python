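"""Shrinkage-LDA decoding: classifier correctness, fold hygiene, schemes."""

import numpy as np
import pandas as pd
import pytest

from eegdecode.decoding import (
    ClassifierSpec,
    SchemeSpec,
    cross_decode,
    cv_timecourse,
    make_folds,
    temporal_generalization,
    train_classifier,
    window_features,
    window_width_ms,
)
from eegdecode.preprocess import EpochSet

from conftest import constant_pattern_epochs, make_epochs


def mahalanobis_oracle(Xtr, ytr, Xte, lam):
    """Independent LDA oracle: classify to the nearer class mean under the
    shrunk pooled Mahalanobis metric (explicit inverse, scalar loops)."""
    Xtr, Xte = np.asarray(Xtr, float), np.asarray(Xte, float)
    mu = [Xtr[ytr == c].mean(axis=0) for c in (0, 1)]
    p = Xtr.shape[1]
    S = np.zeros((p, p))
    for c in (0, 1):
        for row in Xtr[ytr == c]:
            d = row - mu[c]
            S += np.outer(d, d)
    S /= max(len(Xtr) - 2, 1)
    S = (1 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    Sinv = np.linalg.inv(S)
    preds = []
    for x in Xte:
        d0 = (x - mu[0]) @ Sinv @ (x - mu[0])
        d1 = (x - mu[1]) @ Sinv @ (x - mu[1])
        preds.append(1 if d1 < d0 else 0)  # ties -> class 0
    return np.array(preds)


class TestShrinkageLDA:
    def test_separable_clouds_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        clf = train_classifier(X, y)
        assert (clf.predict(X) == y).all()

    def test_full_shrinkage_is_nearest_mean(self, rng):
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        clf = train_classifier(X, y, ClassifierSpec(shrinkage_lambda=1.0))
        d = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        cos = clf.w_ @ d / (np.linalg.norm(clf.w_) * np.linalg.norm(d))
        assert np.isclose(cos, 1.0, atol=1e-10)

    def test_toy_boundary_at_midpoint(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        clf = train_classifier(X, y)
        grid = np.array([[x, yy] for x in np.linspace(-1, 4, 51) for yy in (0.0, 1.0)])
        pred = clf.predict(grid)
        assert ((grid[:, 0] > 1.5) == pred.astype(bool)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mahalanobis_oracle_on_tiny_problems(self, seed):
        gen = np.random.default_rng(seed)
        n, p = gen.integers(4, 7), gen.integers(1, 4)
        X = gen.standard_normal((n, p))
        y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        Xte = gen.standard_normal((20, p))
        for lam in (0.01, 0.2, 0.9):
            clf = train_classifier(X, y, ClassifierSpec(shrinkage_lambda=lam))
            assert (clf.predict(Xte) == mahalanobis_oracle(X, y, Xte, lam)).all()

    def test_matches_sklearn_lsqr_shrinkage(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X = rng.standard_normal((40, 6))
        y = np.repeat([0, 1], 20)
        X[y == 1] += 0.8
        ours = train_classifier(X, y, ClassifierSpec(shrinkage_lambda=0.1))
        ref = sklearn.LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=0.1
        ).fit(X, y)
        assert (ours.predict(X) == ref.predict(X)).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((4, 2)), np.zeros(4))


class TestWindowFeatures:
    def test_feature_dimension(self, null_epochs):
        F = window_features(null_epochs, 5, 3)
        assert F.shape == (len(null_epochs), null_epochs.n_channels * 3)

    def test_width_one_is_raw_sample(self, null_epochs):
        F = window_features(null_epochs, 7, 1)
        assert np.array_equal(F, null_epochs.data[:, :, 7])

    def test_out_of_range_raises(self, null_epochs):
        with pytest.raises(ValueError):
            window_features(null_epochs, 0, 3)

    def test_window_label_convention(self):
        assert window_width_ms(3, 250.0) == 12.0


class TestFolds:
    def test_chunk_integrity_and_no_overlap(self, null_epochs):
        folds = make_folds(null_epochs.labels, SchemeSpec("leave_one_chunk_out"))
        chunks = null_epochs.labels["chunk"].to_numpy()
        assert len(folds) == null_epochs.labels["chunk"].nunique()
        for train, test in folds:
            assert set(train) & set(test) == set()
            assert set(chunks[train]) & set(chunks[test]) == set()
            assert len(train) + len(test) == len(null_epochs)

    def test_leave_two_exemplar_out_structure(self, null_epochs):
        folds = make_folds(
            null_epochs.labels, SchemeSpec("leave_two_exemplar_out", "category")
        )
        assert len(folds) == 4  # 2 exemplars x 2 exemplars
        lab = null_epochs.labels
        for train, test in folds:
            held = lab.iloc[test].groupby("category")["exemplar"].nunique()
            assert (held == 1).all()  # one exemplar per category held out
            # training uses only the complementary exemplars
            for cat in ("face", "place"):
                tr_ex = set(lab.iloc[train].query("category == @cat")["exemplar"])
                te_ex = set(lab.iloc[test].query("category == @cat")["exemplar"])
                assert tr_ex.isdisjoint(te_ex)

    def test_exemplar_contrast_with_leave_two_out_rejected(self, null_epochs):
        with pytest.raises(ValueError):
            make_folds(
                null_epochs.labels,
                SchemeSpec("leave_two_exemplar_out", "exemplar_within_category"),
            )


class TestCvTimecourse:
    def test_perfectly_separable_epochs_decode_fully(self):
        ep = constant_pattern_epochs(amp=5.0)
        tc = cv_timecourse(ep, SchemeSpec("leave_one_chunk_out", "category"))
        assert (tc.accuracy == 1.0).all()

    def test_channel_permutation_invariance(self):
        ep = make_epochs(n_chunks=4, snr=2.0, seed=5)
        perm = np.random.default_rng(0).permutation(ep.n_channels)
        ep_perm = EpochSet(
            data=ep.data[:, perm, :], times_ms=ep.times_ms, labels=ep.labels
        )
        sc = SchemeSpec("leave_one_chunk_out", "category")
        a = cv_timecourse(ep, sc).accuracy
        b = cv_timecourse(ep_perm, sc).accuracy
        assert np.allclose(a, b)

    def test_edge_time_points_omitted(self, null_epochs):
        tc = cv_timecourse(null_epochs, SchemeSpec("leave_one_chunk_out"))
        assert len(tc.times_ms) == len(null_epochs.times_ms) - 2

    def test_exemplar_contrast_needs_single_category(self, null_epochs):
        with pytest.raises(ValueError):
            cv_timecourse(
                null_epochs,
                SchemeSpec("leave_one_chunk_out", "exemplar_within_category"),
            )

    def test_exemplar_decoding_within_category(self):
        ep = make_epochs(n_chunks=6, snr=4.0, seed=6)
        face = ep.select((ep.labels["category"] == "face").to_numpy())
        tc = cv_timecourse(
            face, SchemeSpec("leave_one_chunk_out", "exemplar_within_category")
        )
        inside = (tc.times_ms > 150) & (tc.times_ms < 350)
        assert tc.accuracy[inside].mean() > 0.7


class TestCrossDecode:
    def test_shared_pattern_generalizes(self):
        # same spatial structure in both "conditions": cross decoding works
        tr = constant_pattern_epochs(seed=1)
        te = constant_pattern_epochs(seed=2)
        tc = cross_decode(tr, te, "split_half")
        assert tc.accuracy.mean() > 0.95

    def test_orthogonal_patterns_do_not_generalize(self):
        tr = constant_pattern_epochs(seed=3)
        te = constant_pattern_epochs(seed=4)
        te = EpochSet(  # move the class difference to an orthogonal channel
            data=te.data[:, [1, 0, 2, 3], :], times_ms=te.times_ms, labels=te.labels
        )
        tc = cross_decode(tr, te, "split_half")
        assert abs(tc.accuracy.mean() - 0.5) < 0.2

    def test_split_half_on_identical_sets_is_training_accuracy(self):
        ep = constant_pattern_epochs(seed=5)
        tc = cross_decode(ep, ep, "split_half")
        assert (tc.accuracy == 1.0).all()

    def test_leave_one_out_excludes_same_trial_epochs(self):
        # test epochs are exact copies of train epochs with matching chunk
        # ids: split-half memorizes them, leave-one-out cannot
        ep = make_epochs(n_chunks=6, snr=0.0, seed=7)
        sh = cross_decode(ep, ep, "split_half")
        loo = cross_decode(ep, ep, "leave_one_out")
        assert sh.accuracy.mean() > 0.9  # memorization of noise
        assert abs(loo.accuracy.mean() - 0.5) < 0.1

    def test_mismatched_grids_raise(self):
        a = make_epochs(n_chunks=2, seed=8, window_ms=(-100, 300))
        b = make_epochs(n_chunks=2, seed=8, window_ms=(-100, 400))
        with pytest.raises(ValueError):
            cross_decode(a, b)


class TestTemporalGeneralization:
    def test_diagonal_matches_cross_decode(self):
        tr = make_epochs(n_chunks=4, snr=2.0, seed=9)
        te = make_epochs(n_chunks=4, snr=2.0, seed=10)
        gm = temporal_generalization(tr, te)
        tc = cross_decode(tr, te, "split_half")
        assert np.allclose(np.diag(gm.accuracy), tc.accuracy, atol=1e-12)

    def test_transient_pattern_stays_near_diagonal(self):
        from eegdecode.synthetic import make_class_patterns

        shared = make_class_patterns(8, np.random.default_rng(99))
        cfg_kwargs = dict(
            n_chunks=8, snr=6.0, seed=11, onset_ms=100.0, duration_ms=100.0,
            window_ms=(-100.0, 500.0), patterns=shared,
        )
        tr = make_epochs(**cfg_kwargs)
        te = make_epochs(**{**cfg_kwargs, "seed": 12})
        gm = temporal_generalization(tr, te)
        t = gm.train_times_ms
        inside = (t >= 120) & (t <= 180)
        far = (t >= 350) & (t <= 450)
        on_diag = gm.accuracy[np.ix_(inside, inside)].mean()
        off_diag = gm.accuracy[np.ix_(inside, far)].mean()
        assert on_diag > 0.8
        assert off_diag < on_diag - 0.2

    def test_null_data_stays_at_chance(self):
        tr = make_epochs(n_chunks=8, snr=0.0, seed=13)
        te = make_epochs(n_chunks=8, snr=0.0, seed=14)
        gm = temporal_generalization(tr, te)
        # 32 test epochs: binomial SE ~ 0.088; allow 4 SE for the max cell
        assert np.all(np.abs(gm.accuracy - 0.5) < 4 * np.sqrt(0.25 / 32))
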