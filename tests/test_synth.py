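"""Generator contracts: paradigm structure, determinism, planted truths."""
import numpy as np
import pytest

from miconn.preprocess import ALPHA, BETA_TE, ConfigError, filter_band
from miconn.synth import (
    Coupling,
    SynthConfig,
    generate_coupled_ar,
    generate_session,
)


def test_default_session_has_120_trials():
    """Three conditions x two hands x twenty trials per hand."""
    cfg = SynthConfig()
    rec, events, gt = generate_session(cfg)
    assert len(events) == 120
    assert len(gt.trials) == 120
    per_cell = {}
    for ev in events:
        per_cell[(ev.condition, ev.hand)] = per_cell.get((ev.condition, ev.hand), 0) + 1
    assert set(per_cell.values()) == {20}
    assert rec.n_samples == 120 * int(15.0 * cfg.fs_native)


def test_same_seed_reproduces_samples(tiny_session):
    cfg, rec, events, _ = tiny_session
    rec2, events2, _ = generate_session(cfg)
    np.testing.assert_array_equal(rec.data, rec2.data)
    assert events == events2


def test_different_seed_changes_samples(tiny_session):
    cfg, rec, _, _ = tiny_session
    from dataclasses import replace

    rec2, _, _ = generate_session(replace(cfg, seed=cfg.seed + 1))
    assert not np.array_equal(rec.data, rec2.data)


@pytest.mark.parametrize(
    "bad",
    [
        dict(erd_depth=0.0),
        dict(erd_depth=1.5),
        dict(noise_sd=-1.0),
        dict(couplings=(Coupling("Pz", "XX", ("tMI",), 4, 1.0, BETA_TE),)),
        dict(couplings=(Coupling("Pz", "Cz", ("tMI",), 0, 1.0, BETA_TE),)),
        dict(couplings=(Coupling("Pz", "Cz", ("nope",), 4, 1.0, BETA_TE),)),
        dict(channels=["C3", "C3", "C4"]),
    ],
)
def test_invalid_config_raises_naming_field(bad):
    with pytest.raises(ConfigError):
        generate_session(SynthConfig(**bad))


def test_no_erd_leaves_mi_alpha_power_at_baseline_level():
    """With erd_depth = 1 and no couplings, MI-stage alpha power matches the
    fixation stage in expectation (within 5% over 100 trials)."""
    cfg = SynthConfig(
        channels=["C3", "C4"],
        conditions=("tMI",),
        hands=("right",),
        n_trials_per_hand=100,
        erd_depth=1.0,
        seed=11,
    )
    rec, events, _ = generate_session(cfg)
    n_trial = int(15.0 * cfg.fs_native)
    alpha = filter_band(rec.data[0], cfg.fs_native, ALPHA)  # C3, contralateral
    fix_pow, mi_pow = [], []
    for ev in events:
        t0 = ev.sample - n_trial // 15 * 2  # trial start (2 s fixation)
        fix = alpha[ev.sample - 1500 : ev.sample - 500]  # interior of fixation
        mi = alpha[ev.sample + 500 : ev.sample + 9500]  # interior of MI stage
        fix_pow.append(np.mean(fix**2))
        mi_pow.append(np.mean(mi**2))
    ratio = np.mean(mi_pow) / np.mean(fix_pow)
    assert abs(ratio - 1.0) < 0.05


def test_planted_erd_suppresses_contralateral_alpha():
    cfg = SynthConfig(
        channels=["C3", "C4"],
        conditions=("tMI",),
        hands=("right",),
        n_trials_per_hand=30,
        erd_depth=0.5,
        seed=12,
    )
    rec, events, gt = generate_session(cfg)
    assert gt.erd_factors["right"]["C3"] == 0.5
    assert gt.erd_factors["right"]["C4"] == 1.0
    alpha_c3 = filter_band(rec.data[0], cfg.fs_native, ALPHA)
    mi_pow, fix_pow = [], []
    for ev in events:
        fix_pow.append(np.mean(alpha_c3[ev.sample - 1500 : ev.sample - 500] ** 2))
        mi_pow.append(np.mean(alpha_c3[ev.sample + 500 : ev.sample + 9500] ** 2))
    assert np.mean(mi_pow) < 0.6 * np.mean(fix_pow)


def test_coupling_restricted_to_condition_and_mi_stage():
    coup = Coupling("Pz", "Cz", ("bcMI",), lag=4, strength=2.0, band=BETA_TE)
    cfg = SynthConfig(
        conditions=("tMI", "bcMI"),
        hands=("right",),
        n_trials_per_hand=6,
        stage_durations=(2.0, 2.0, 1.0),
        couplings=(coup,),
        seed=13,
    )
    rec, events, gt = generate_session(cfg)
    assert gt.planted_pairs("bcMI") == {("Pz", "Cz")}
    assert gt.planted_pairs("tMI") == set()
    cz = rec.channel_index("Cz")
    # coupled condition raises MI-stage variance on the sink channel only
    var = {"tMI": [], "bcMI": []}
    for ev in events:
        seg = rec.data[cz, ev.sample : ev.sample + 2000]
        var[ev.condition].append(seg.var())
    assert np.mean(var["bcMI"]) > 1.1 * np.mean(var["tMI"])


class TestCoupledAR:
    def test_zero_coupling_gives_independent_series(self):
        pair = generate_coupled_ar(50_000, c=0.0, seed=3)
        r = np.corrcoef(pair.x[:-1], pair.y[1:])[0, 1]
        assert abs(r) < 0.02

    def test_population_te_matches_gaussian_information(self):
        """0.5*ln(1 + c^2/sigma^2) equals the Gaussian mutual information
        -0.5*ln(1 - rho^2) computed from the realized lagged correlation."""
        pair = generate_coupled_ar(200_000, c=1.0, lag=1, sd_noise=1.0, seed=4)
        rho = np.corrcoef(pair.x[:-1], pair.y[1:])[0, 1]
        mi_from_corr = -0.5 * np.log(1 - rho**2)
        assert pair.population_te == pytest.approx(0.5 * np.log(2))
        assert mi_from_corr == pytest.approx(pair.population_te, rel=0.02)

    def test_no_reverse_dependence(self):
        pair = generate_coupled_ar(50_000, c=1.0, lag=1, seed=5)
        fwd = np.corrcoef(pair.x[:-1], pair.y[1:])[0, 1]
        rev = np.corrcoef(pair.y[:-1], pair.x[1:])[0, 1]
        assert fwd > 0.5
        assert abs(rev) < 0.02

    @pytest.mark.parametrize("kwargs", [dict(n=50), dict(lag=0), dict(sd_noise=0.0)])
    def test_invalid_parameters_raise(self, kwargs):
        args = dict(n=1000, c=1.0, lag=1, sd_noise=1.0, seed=0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_coupled_ar(**args)
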