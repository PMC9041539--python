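"""Transfer entropy: embedding selection, k-NN estimator, matrix assembly."""
import numpy as np
import pytest

from miconn.preprocess import BETA_TE
from miconn.synth import Coupling, SynthConfig, generate_coupled_ar, generate_session
from miconn.pipeline import preprocess_session
from miconn.te import (
    EmbeddingParams,
    relative_te,
    select_delay,
    select_dimension,
    te_knn,
    te_matrix,
)

P11 = EmbeddingParams(d=1, tau=1, u=1, K=4, theiler=1)


class TestSelectDelay:
    def test_white_noise_tau_1(self, rng):
        assert select_delay(rng.standard_normal(5000)) == 1

    def test_sinusoid_quarter_period(self):
        t = np.arange(5000) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        # autocorrelation cos(2*pi*10*tau/250) crosses 1/e near tau = 4.8
        assert select_delay(x) in (4, 5, 6)

    def test_ar1_exponential_decay(self, rng):
        x = np.empty(50_000)
        x[0] = 0.0
        eps = rng.standard_normal(50_000)
        for i in range(1, x.size):
            x[i] = 0.9 * x[i - 1] + eps[i]
        # rho^tau < 1/e  =>  tau > -1/ln(0.9) ~ 9.5
        assert select_delay(x) in (9, 10, 11)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            select_delay(np.ones(1000))


class TestSelectDimension:
    def test_white_noise_is_one_dimensional(self, rng):
        assert select_dimension(rng.standard_normal(4000), tau=1) == 1

    def test_noiseless_cycle_needs_two_dimensions(self):
        t = np.arange(4000) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        assert select_dimension(x, tau=6) == 2

    def test_ar1_low_order(self, rng):
        x = np.empty(5000)
        x[0] = 0.0
        eps = rng.standard_normal(5000)
        for i in range(1, x.size):
            x[i] = 0.9 * x[i - 1] + eps[i]
        assert select_dimension(x, tau=1) <= 2

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            select_dimension(rng.standard_normal(50), tau=5)


class TestTeKnn:
    def test_independent_pair_near_zero(self):
        vals = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals.append(te_knn(r.standard_normal(2000), r.standard_normal(2000), P11))
        assert abs(np.mean(vals)) < 0.02

    def test_linear_gaussian_closed_form(self):
        ests = [
            te_knn(p.y, p.x, P11)
            for p in (generate_coupled_ar(5000, 1.0, seed=s) for s in range(5))
        ]
        assert np.mean(ests) == pytest.approx(0.5 * np.log(2), rel=0.2)

    def test_directionality(self):
        hits = 0
        for seed in range(10):
            p = generate_coupled_ar(2000, 1.0, seed=seed)
            hits += te_knn(p.y, p.x, P11) > te_knn(p.x, p.y, P11)
        assert hits == 10

    def test_estimator_consistency(self):
        """Median absolute error against the closed form shrinks with n."""
        errors = []
        for n in (500, 2000, 8000):
            errs = [
                abs(te_knn(p.y, p.x, P11) - p.population_te)
                for p in (generate_coupled_ar(n, 1.0, seed=s) for s in range(9))
            ]
            errors.append(np.median(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_affine_invariance(self):
        p = generate_coupled_ar(2000, 1.0, seed=3)
        base = te_knn(p.y, p.x, P11)
        scaled = te_knn(5.0 * p.y - 2.0, 0.1 * p.x + 7.0, P11)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_theiler_window_negligible_on_independent_noise(self):
        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x, y = r.standard_normal(2000), r.standard_normal(2000)
            t0 = te_knn(x, y, EmbeddingParams(d=1, tau=1, theiler=0))
            t1 = te_knn(x, y, EmbeddingParams(d=1, tau=1, theiler=1))
            diffs.append(abs(t1 - t0))
        assert np.mean(diffs) < 0.02

    def test_trial_ensemble_pools_points(self):
        p = generate_coupled_ar(4000, 1.0, seed=8)
        stacked = te_knn(p.y.reshape(8, 500), p.x.reshape(8, 500), P11)
        assert stacked == pytest.approx(0.5 * np.log(2), rel=0.3)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            te_knn(np.zeros(20), np.zeros(20), P11)


@pytest.fixture(scope="module")
def coupled_trials():
    """One down-scaled subject with a beta-band Pz->Cz coupling in bcMI."""
    cfg = SynthConfig(
        conditions=("tMI", "bcMI"),
        hands=("right",),
        n_trials_per_hand=4,
        stage_durations=(2.0, 2.0, 1.0),
        couplings=(Coupling("Pz", "Cz", ("bcMI",), lag=4, strength=1.0, band=BETA_TE),),
        seed=77,
    )
    rec, _, _ = generate_session(cfg)
    return preprocess_session(rec, epoch_window=(-2.0, 3.0))


class TestTeMatrix:
    def test_montage_has_72_directed_pairs(self, coupled_trials):
        mat = te_matrix(coupled_trials[("tMI", "right")], BETA_TE, (0.0, 2.0),
                        params=P11, max_points=300)
        assert np.isnan(mat.values).sum() == 9
        assert np.isfinite(mat.values).sum() == 72
        assert len(mat.edge_list()) == 72

    def test_planted_coupling_dominates_reverse(self, coupled_trials):
        mat = te_matrix(coupled_trials[("bcMI", "right")], BETA_TE, (0.0, 2.0),
                        params=P11, max_points=800)
        assert mat.pair("Pz", "Cz") > mat.pair("Cz", "Pz")

    def test_channel_permutation_equivariance(self, coupled_trials):
        ts = coupled_trials[("bcMI", "right")]
        chans = ["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4"]
        perm = chans[::-1]
        a = te_matrix(ts, BETA_TE, (0.0, 2.0), channels=chans, params=P11, max_points=300)
        b = te_matrix(ts, BETA_TE, (0.0, 2.0), channels=perm, params=P11, max_points=300)
        np.testing.assert_allclose(a.values, b.values[::-1, ::-1], rtol=1e-9, atol=1e-12)

    def test_embedding_selection_recorded(self, coupled_trials):
        mat = te_matrix(coupled_trials[("tMI", "right")], BETA_TE, (-2.0, 0.0),
                        channels=["Pz", "Cz", "F3"], max_points=300)
        assert set(mat.params) == {"Pz", "Cz", "F3"}
        for p in mat.params.values():
            assert p["d"] >= 1 and p["tau"] >= 1

    def test_missing_channel_named(self, coupled_trials):
        with pytest.raises(ValueError, match="Oz"):
            te_matrix(coupled_trials[("tMI", "right")], BETA_TE, (0.0, 2.0),
                      channels=["Oz", "Cz"], params=P11)


class TestRelativeTe:
    def test_task_equals_baseline_gives_zero(self, coupled_trials):
        mat = te_matrix(coupled_trials[("tMI", "right")], BETA_TE, (0.0, 2.0),
                        params=P11, max_points=300)
        rel = relative_te(mat, mat)
        assert np.nanmax(np.abs(rel.values)) == 0.0
        assert rel.window == "relative"

    def test_constant_shift_linearity(self, coupled_trials):
        from dataclasses import replace

        mat = te_matrix(coupled_trials[("tMI", "right")], BETA_TE, (0.0, 2.0),
                        params=P11, max_points=300)
        shifted = replace(mat, values=mat.values + 0.3)
        rel = relative_te(shifted, mat)
        np.testing.assert_allclose(rel.values[np.isfinite(rel.values)], 0.3, atol=1e-12)

    def test_montage_mismatch_rejected(self, coupled_trials):
        ts = coupled_trials[("tMI", "right")]
        a = te_matrix(ts, BETA_TE, (0.0, 2.0), channels=["Pz", "Cz", "F3"],
                      params=P11, max_points=300)
        b = te_matrix(ts, BETA_TE, (-2.0, 0.0), channels=["Pz", "Cz", "F4"],
                      params=P11, max_points=300)
        with pytest.raises(ValueError, match="montage"):
            relative_te(a, b)

    def test_mi_only_coupling_yields_positive_relative_te(self):
        """Coupling active during MI but not fixation -> positive relative TE
        at the planted pair (median over 20 seeds)."""
        from miconn.preprocess import filter_band, TrialSet

        vals = []
        for seed in range(20):
            cfg = SynthConfig(
                channels=["Pz", "Cz"],
                erd_channels={},
                conditions=("bcMI",),
                hands=("right",),
                n_trials_per_hand=4,
                stage_durations=(2.0, 2.0, 1.0),
                couplings=(Coupling("Pz", "Cz", ("bcMI",), 4, 1.0, BETA_TE),),
                seed=500 + seed,
            )
            rec, _, _ = generate_session(cfg)
            ts = preprocess_session(rec, epoch_window=(-2.0, 3.0))[("bcMI", "right")]
            filt = filter_band(ts.epochs, ts.fs, BETA_TE)
            t = ts.time_axis
            mi = (t >= 0) & (t < 2)
            base = (t >= -2) & (t < 0)
            te_mi = te_knn(filt[:, 1, mi], filt[:, 0, mi], P11, max_points=400)
            te_base = te_knn(filt[:, 1, base], filt[:, 0, base], P11, max_points=400)
            vals.append(te_mi - te_base)
        assert np.median(vals) > 0.05
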