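"""CSP eigenstructure, feature map, LDA and cross-validation protocol."""
import numpy as np
import pytest

from miconn.cspclf import (
    CSPModel,
    CVResult,
    cross_validate,
    csp_features,
    fit_csp,
    fit_lda,
    predict,
    select_m,
    _class_covariance,
)
from miconn.preprocess import ALPHA, TrialSet


def _ts(epochs, condition="a", fs=250.0):
    n = epochs.shape[-1]
    return TrialSet(
        epochs=epochs,
        time_axis=np.arange(n) / fs,
        condition=condition,
        hand="right",
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(epochs.shape[1])],
    )


def _scaled_noise(rng, n_trials, scales, n=500):
    return rng.standard_normal((n_trials, len(scales), n)) * np.asarray(scales)[None, :, None]


@pytest.fixture()
def toy_classes(rng):
    """Two channels; class 1 varies along channel 0, class 2 along channel 1."""
    c1 = _ts(_scaled_noise(rng, 20, [3.0, 0.3]), "c1")
    c2 = _ts(_scaled_noise(rng, 20, [0.3, 3.0]), "c2")
    return c1, c2


class TestFitCSP:
    def test_toy_recovers_discriminative_axis(self, toy_classes):
        model = fit_csp(*toy_classes)
        w = model.filters[:, 0]  # largest eigenvalue: maximal class-1 variance
        cosine = abs(w[0]) / np.linalg.norm(w)
        assert cosine > 0.99

    def test_identical_classes_give_equal_eigenvalues(self, rng):
        a = _ts(_scaled_noise(rng, 10, [1.0, 1.0, 1.0]))
        model = fit_csp(a, a)
        np.testing.assert_allclose(model.eigenvalues, model.eigenvalues[0], rtol=1e-9)

    def test_whitening_invariant(self, rng):
        a = _ts(_scaled_noise(rng, 15, [2.0, 1.0, 0.5, 1.5]), "a")
        b = _ts(_scaled_noise(rng, 15, [0.7, 1.2, 2.2, 0.9]), "b")
        model = fit_csp(a, b)
        r2 = _class_covariance(b.epochs)
        np.testing.assert_allclose(
            model.filters.T @ r2 @ model.filters, np.eye(4), atol=1e-6
        )
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)  # sorted descending

    def test_eigenvalue_duality_under_class_swap(self, toy_classes):
        m_ab = fit_csp(*toy_classes)
        m_ba = fit_csp(toy_classes[1], toy_classes[0])
        np.testing.assert_allclose(
            m_ba.eigenvalues, (1.0 / m_ab.eigenvalues)[::-1], rtol=1e-8
        )

    def test_zero_variance_channel_rejected(self, rng):
        bad = _scaled_noise(rng, 10, [1.0, 0.0])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_csp(_ts(bad), _ts(bad.copy()))


class TestFeatures:
    def test_equal_variance_components_give_uniform_features(self):
        """Components with identical variance -> every feature log(1/(2m))."""
        t = np.arange(500) / 250.0
        epochs = np.stack(
            [np.vstack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])] * 3
        )
        model = CSPModel(
            filters=np.eye(2), eigenvalues=np.ones(2), band=None,
            class_labels=("a", "b"), channel_labels=["ch0", "ch1"],
        )
        feats = csp_features(model, _ts(epochs), m=1)
        np.testing.assert_allclose(feats, np.log(0.5), atol=1e-9)

    def test_duplicate_trial_gives_identical_features(self, toy_classes):
        c1, c2 = toy_classes
        model = fit_csp(c1, c2)
        feats = csp_features(model, c1, m=1)
        doubled = _ts(np.concatenate([c1.epochs[:1], c1.epochs[:1]]), "c1")
        f2 = csp_features(model, doubled, m=1)
        np.testing.assert_array_equal(f2[0], f2[1])
        np.testing.assert_allclose(f2[0], feats[0])

    def test_toy_feature_separation(self, toy_classes):
        c1, c2 = toy_classes
        model = fit_csp(c1, c2)
        f1 = csp_features(model, c1, m=1)[:, 0]
        f2 = csp_features(model, c2, m=1)[:, 0]
        gap = abs(f1.mean() - f2.mean())
        spread = max(f1.std(), f2.std())
        assert gap > 10 * spread

    def test_m_out_of_range_rejected(self, toy_classes):
        model = fit_csp(*toy_classes)
        with pytest.raises(ValueError):
            csp_features(model, toy_classes[0], m=2)


class TestLDA:
    def test_separated_clouds_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(-5, 1, (30, 2)), rng.normal(5, 1, (30, 2))])
        y = np.repeat([0, 1], 30)
        clf = fit_lda(x, y)
        assert (predict(clf, x) == y).all()

    def test_1d_equal_variance_boundary_at_midpoint(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])[:, None]
        y = np.repeat([0, 1], 200)
        clf = fit_lda(x, y)
        mid = (x[y == 0].mean() + x[y == 1].mean()) / 2
        assert predict(clf, [[mid - 0.5]])[0] == 0
        assert predict(clf, [[mid + 0.5]])[0] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((5, 2)), np.zeros(5))


class TestCrossValidate:
    def test_same_seed_reproduces_per_repeat_accuracies(self, toy_classes):
        c1, c2 = toy_classes
        r1 = cross_validate(c1, c2, [], m=1, k=5, repeats=4, seed=9)
        r2 = cross_validate(c1, c2, [], m=1, k=5, repeats=4, seed=9)
        np.testing.assert_array_equal(r1.per_repeat, r2.per_repeat)

    def test_separable_classes_near_perfect(self, toy_classes):
        res = cross_validate(*toy_classes, bands=[], m=1, k=5, repeats=4, seed=1)
        assert res.mean > 0.95

    def test_channel_permutation_invariance(self, rng):
        """Permuting channels consistently leaves accuracies unchanged."""
        e1 = _scaled_noise(rng, 16, [3.0, 0.5, 1.0])
        e2 = _scaled_noise(rng, 16, [0.5, 3.0, 1.0])
        perm = [2, 0, 1]
        base = cross_validate(_ts(e1), _ts(e2), [], m=1, k=4, repeats=3, seed=5)
        permuted = cross_validate(
            _ts(e1[:, perm]), _ts(e2[:, perm]), [], m=1, k=4, repeats=3, seed=5
        )
        np.testing.assert_allclose(base.per_repeat, permuted.per_repeat)

    def test_k_larger_than_class_rejected(self, toy_classes):
        with pytest.raises(ValueError):
            cross_validate(*toy_classes, bands=[], m=1, k=30)

    def test_cross_validate_with_band_filtering(self, tiny_trials):
        from dataclasses import replace

        def stacked(hand):
            a = tiny_trials[("tMI", hand)].crop((0.0, 2.0))
            b = tiny_trials[("rmMI", hand)].crop((0.0, 2.0))
            return replace(a, epochs=np.concatenate([a.epochs, b.epochs]))

        res = cross_validate(stacked("left"), stacked("right"), [ALPHA],
                             m=1, k=2, repeats=2, seed=3)
        assert res.per_repeat.shape == (2,)
        assert 0.0 <= res.mean <= 1.0


class TestSelectM:
    def test_sweep_covers_default_range(self, rng):
        """The m sweep returns one accuracy per candidate in 1..8."""
        e1 = _scaled_noise(rng, 12, [2.0] + [1.0] * 15, n=120)
        e2 = _scaled_noise(rng, 12, [0.5] + [1.0] * 15, n=120)
        best, accs = select_m(_ts(e1), _ts(e2), bands=[], k=3, repeats=2, seed=7)
        assert sorted(accs) == list(range(1, 9))
        assert best in accs
        assert accs[best] == max(accs.values())

    def test_ties_break_toward_smaller_m(self, monkeypatch):
        import miconn.cspclf as mod

        vals = {1: 0.9, 2: 0.9, 3: 0.8}

        def fake_cv(*args, m=1, **kwargs):
            return CVResult(per_repeat=np.array([vals[m]]), m=m, k=2)

        monkeypatch.setattr(mod, "cross_validate", fake_cv)
        best, accs = mod.select_m(None, None, bands=[], m_range=[1, 2, 3])
        assert best == 1
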