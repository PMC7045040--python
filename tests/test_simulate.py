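"""Synthetic panel generator: defaults, determinism, stationary structure."""

import numpy as np
import pytest
from scipy import stats

import memlag as ml
from memlag.panel import WEEKDAYS
from memlag.simulate import (
    auto_innovation_sd,
    default_config,
    expected_sample_variance,
    make_fixture_suite,
    simulate_panel,
    stationary_autocovariance,
    weekday_profile,
)


class TestDefaultConfig:
    def test_lag_coefficients(self):
        cfg = default_config()
        assert cfg.ar_coefficients[7] == pytest.approx(0.1934)
        assert cfg.ar_coefficients[1] == pytest.approx(0.2468)
        assert sum(cfg.ar_coefficients.values()) == pytest.approx(0.9839)

    def test_weekday_effects_sunday_reference(self):
        cfg = default_config()
        assert cfg.weekday_effects["Mon"] == pytest.approx(-0.3845)
        assert cfg.weekday_effects["Sun"] == 0.0

    def test_study_shape_defaults(self):
        cfg = default_config()
        assert cfg.n_subjects == 62
        assert cfg.length_mode == 84
        assert cfg.missing_rate == pytest.approx(0.0108)
        assert cfg.innovation_sd is None  # AUTO


class TestStationaryStructure:
    def test_yule_walker_against_long_simulation(self):
        """Analytic autocovariances match a brute-force long simulation."""
        ar = {1: 0.5, 3: 0.2}
        gam = stationary_autocovariance(ar, 1.0, max_lag=5)
        rng = np.random.default_rng(0)
        n = 400_000
        y = np.zeros(n)
        eps = rng.normal(size=n)
        for t in range(3, n):
            y[t] = 0.5 * y[t - 1] + 0.2 * y[t - 3] + eps[t]
        y = y[1000:]
        emp = [np.mean((y[k:] - y.mean()) * (y[: len(y) - k] - y.mean())) for k in range(6)]
        assert np.allclose(gam, emp, rtol=0.02, atol=0.02)

    def test_auto_innovation_pins_stationary_variance(self):
        cfg = default_config()
        sig = auto_innovation_sd(cfg)
        g0 = stationary_autocovariance(cfg.ar_coefficients, sig**2)[0]
        mu = weekday_profile(cfg.ar_coefficients, cfg.weekday_effects, cfg.intercept)
        assert g0 + mu.var() == pytest.approx(1.0, abs=1e-10)

    def test_expected_sample_variance_below_stationary_for_persistent_ar(self):
        cfg = default_config()
        sig2 = auto_innovation_sd(cfg) ** 2
        ev = expected_sample_variance(cfg.ar_coefficients, sig2, 84)
        g0 = stationary_autocovariance(cfg.ar_coefficients, sig2)[0]
        assert ev < 0.6 * g0  # an 84-day window expresses far less than gamma_0

    def test_nonstationary_config_rejected(self):
        cfg = default_config(ar_coefficients={1: 0.7, 2: 0.4})
        with pytest.raises(ValueError, match="non-stationary"):
            simulate_panel(cfg)


class TestSimulatePanel:
    def test_determinism(self):
        a, ta = simulate_panel(default_config(seed=9))
        b, tb = simulate_panel(default_config(seed=9))
        assert a.data.equals(b.data)
        assert ta == tb
        c, _ = simulate_panel(default_config(seed=10))
        assert not a.data.equals(c.data)

    def test_degenerate_ar_is_iid_gaussian(self):
        """With all AR and weekday effects zero the raw series is iid
        Normal(m_j s_j, s_j) — checked by KS against the closed form."""
        cfg = default_config(
            seed=2,
            n_subjects=3,
            length_min=500,
            length_max=500,
            length_mode=500,
            mode_mass=1.0,
            ar_coefficients={},
            weekday_effects={w: 0.0 for w in WEEKDAYS},
            missing_rate=0.0,
            burn_in=0,
        )
        ds, truth = simulate_panel(cfg)
        for sid, info in truth["subjects"].items():
            x = ds.series(sid)["count"].to_numpy()
            m, s = info["mean"] * info["scale"], info["scale"] * truth["innovation_sd"]
            _, p = stats.kstest(x, "norm", args=(m, s))
            assert p > 0.01

    def test_sample_variance_matches_window_oracle(self):
        """Per-subject sample variance of the latent homoscedastic series
        concentrates on the Yule–Walker finite-window prediction, not on
        the (much larger) stationary variance."""
        cfg = default_config(seed=4, missing_rate=0.0, length_min=84, length_max=84,
                             length_mode=84, mode_mass=1.0)
        ds, truth = simulate_panel(cfg)
        scales = {k: v["scale"] for k, v in truth["subjects"].items()}
        lat = ds.data["count"] / ds.data["subject_id"].map(scales)
        v = lat.groupby(ds.data["subject_id"]).var()
        sig2 = truth["innovation_sd"] ** 2
        mu = weekday_profile(cfg.ar_coefficients, cfg.weekday_effects, cfg.intercept)
        pred = expected_sample_variance(cfg.ar_coefficients, sig2, 84) + mu.var()
        assert v.mean() == pytest.approx(pred, rel=0.15)

    def test_missingness_rate(self):
        cfg = default_config(seed=3, n_subjects=200)
        ds, _ = simulate_panel(cfg)
        assert ds.missing_fraction() == pytest.approx(0.0108, abs=0.004)

    def test_weekday_ordering_saturday_above_monday(self):
        """Pooled weekday means: Saturday above Monday, as in the
        observed weekly consumption pattern."""
        cfg = default_config(seed=6, n_subjects=150, missing_rate=0.0)
        ds, _ = simulate_panel(cfg)
        hp = ml.homoscedastic_transform(ds)
        w = ml.weekday_stats(hp.panel)
        assert w.loc["Sat", "mean"] > w.loc["Mon", "mean"]

    def test_pooled_acf_seasonal_decay(self):
        """Seasonal autocorrelations are positive and decay with lag."""
        cfg = default_config(seed=8, n_subjects=150, length_min=150, length_max=150,
                             length_mode=150, mode_mass=1.0, missing_rate=0.0)
        ds, _ = simulate_panel(cfg)
        cg = ml.pooled_acf(ml.homoscedastic_transform(ds), 56)
        seasonal = cg.acf[[7, 14, 21, 28, 35, 42, 49, 56]]
        assert np.all(seasonal > 0)
        assert seasonal[0] > seasonal[-1]
        # overall downward trend across the eight seasonal lags
        assert np.polyfit(np.arange(8), seasonal, 1)[0] < 0


class TestFixtureSuite:
    def test_deterministic_and_shaped(self, tmp_path):
        suite = make_fixture_suite(seed=1)
        tiny, _ = suite["tiny"]
        assert len(tiny.data) == 20  # 2 subjects x 10 days
        study, _ = suite["study_scale"]
        assert study.n_subjects == 62
        assert suite["no_missing"][0].missing_fraction() == 0.0
        from memlag.simulate import write_fixture_suite

        p1 = write_fixture_suite(1, tmp_path / "a")
        p2 = write_fixture_suite(1, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()
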