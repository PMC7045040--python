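"""Synthetic heteroscedastic seasonal-AR panel generator.

Emulates a daily smoking-diary study: ~62 subjects, record lengths
69–91 days (mode 84), subject-specific means and scales, a shared
within-subject seasonal autoregression at lags {1, 2, 7, 14, ..., 56}
with a weekday mean profile (Sunday reference), and a small completely-
at-random missingness rate.

The latent process runs on the homoscedastic scale (within-subject
variance 1); raw counts are obtained by multiplying by each subject's
scale s_j.  Per subject j with weekday w(t):

    y_t = c_j + sum_k b_k y_{t-k} + d_{w(t)} + sigma_eps * eps_t

where c_j is solved so the subject's stationary mean equals its drawn
mean, and sigma_eps in AUTO mode is solved so the stationary
within-subject variance (autoregressive part plus the deterministic
weekday profile) equals 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import WEEKDAYS, PanelDataset, write_panel_csv

__all__ = [
    "SimulationConfig",
    "default_config",
    "stationary_autocovariance",
    "weekday_profile",
    "auto_innovation_sd",
    "simulate_panel",
    "make_fixture_suite",
]

#: Default AR coefficients of the fitted habit-memory model (homoscedastic scale).
DEFAULT_AR: dict[int, float] = {
    1: 0.2468,
    2: 0.0983,
    7: 0.1934,
    14: 0.0867,
    21: 0.0716,
    28: 0.0653,
    35: 0.0652,
    42: 0.0523,
    49: 0.0522,
    56: 0.0521,
}

#: Default weekday effects, Sunday = 0 reference (homoscedastic scale).
DEFAULT_WEEKDAY_EFFECTS: dict[str, float] = {
    "Mon": -0.3845,
    "Tue": -0.2052,
    "Wed": -0.1910,
    "Thu": -0.1479,
    "Fri": -0.0449,
    "Sat": -0.0732,
    "Sun": 0.0,
}


@dataclass
class SimulationConfig:
    """Full generative parameterisation of a synthetic diary panel.

    Record lengths are drawn from {length_min..length_max} with
    probability ``mode_mass`` on ``length_mode`` and the remaining mass
    uniform elsewhere.  Subject homoscedastic means are Normal(mean_loc,
    mean_scale); the default spread makes the pooled (total) variance on
    the homoscedastic scale ≈ mean_scale² + 1 ≈ 2.253.  Raw scales s_j
    are log-normal.  ``innovation_sd=None`` means AUTO (see
    :func:`auto_innovation_sd`).
    """

    n_subjects: int = 62
    length_min: int = 69
    length_max: int = 91
    length_mode: int = 84
    mode_mass: float = 46.0 / 62.0
    mean_loc: float = 4.546
    mean_scale: float = float(np.sqrt(2.253 - 1.0))
    scale_logmean: float = float(np.log(3.45) - 0.5 * 0.35**2)
    scale_logsd: float = 0.35
    ar_coefficients: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_AR))
    weekday_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKDAY_EFFECTS)
    )
    intercept: float = 0.2618
    innovation_sd: float | None = None  # None = AUTO
    missing_rate: float = 0.0108
    integerize: bool = False
    burn_in: int = 200
    seed: int = 0

    def lags(self) -> list[int]:
        return sorted(self.ar_coefficients)

    def max_lag(self) -> int:
        return max(self.lags(), default=0)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ar_coefficients and not is_stationary(self.ar_coefficients):
            raise ValueError("AR coefficients define a non-stationary process")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ar_coefficients"] = {int(k): v for k, v in d["ar_coefficients"].items()}
        return d


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-emulation defaults: 62 subjects, mode-84 lengths, the
    fitted seasonal-AR coefficients and weekday effects, 1.08% missingness,
    AUTO innovation variance."""
    cfg = SimulationConfig(seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Stationary structure
# ---------------------------------------------------------------------------


def is_stationary(ar: dict[int, float]) -> bool:
    """Check all roots of 1 - sum b_k z^k lie outside the unit circle."""
    if not ar:
        return True
    p = max(ar)
    # polynomial in z: coefficients of z^0..z^p for 1 - sum b_k z^k
    coefs = np.zeros(p + 1)
    coefs[0] = 1.0
    for k, b in ar.items():
        coefs[k] -= b
    roots = np.roots(coefs[::-1])
    return bool(np.all(np.abs(roots) > 1.0 + 1e-10))


def stationary_autocovariance(
    ar: dict[int, float], sigma2: float = 1.0, max_lag: int | None = None
) -> np.ndarray:
    """Autocovariances gamma_0..gamma_m of the stationary AR process by
    solving the Yule–Walker linear system.

    gamma_h = sum_k b_k gamma_{|h-k|} + sigma2 * 1[h = 0].
    """
    p = max(ar, default=0)
    m = p if max_lag is None else max(max_lag, p)
    A = np.eye(m + 1)
    for h in range(m + 1):
        for k, b in ar.items():
            A[h, abs(h - k)] -= b
    rhs = np.zeros(m + 1)
    rhs[0] = sigma2
    return np.linalg.solve(A, rhs)


def weekday_profile(
    ar: dict[int, float], weekday_effects: dict[str, float], intercept: float
) -> np.ndarray:
    """Stationary periodic mean mu_w (indexed Mon..Sun as in WEEKDAYS)
    of the recursion with a constant intercept.

    Solves the 7x7 linear system mu_w = intercept + sum_k b_k mu_{w-k} + d_w.
    """
    M = np.eye(7)
    for k, b in ar.items():
        for w in range(7):
            M[w, (w - k) % 7] -= b
    d = np.array([weekday_effects.get(w, 0.0) for w in WEEKDAYS])
    return np.linalg.solve(M, intercept + d)


def _profile_basis(ar, weekday_effects):
    """mu = c * a + m0 for intercept c; returns (a, m0)."""
    a = weekday_profile(ar, weekday_effects, 1.0) - weekday_profile(ar, weekday_effects, 0.0)
    m0 = weekday_profile(ar, weekday_effects, 0.0)
    return a, m0


def intercept_for_mean(
    ar: dict[int, float], weekday_effects: dict[str, float], target_mean: float
) -> float:
    """Intercept c such that the stationary mean (averaged over the week)
    equals ``target_mean``."""
    a, m0 = _profile_basis(ar, weekday_effects)
    return (target_mean - m0.mean()) / a.mean()


def expected_sample_variance(
    ar: dict[int, float], sigma2: float, n: int, ddof: int = 1
) -> float:
    """Expected sample variance of an n-day window of the stationary AR
    process (around the window's own mean).

    For a persistent process this is well below the stationary
    variance: E[s^2] = n (gamma_0 - Var(ybar_n)) / (n - ddof), with
    Var(ybar_n) = (1/n) sum_{|h|<n} (1 - |h|/n) gamma_h from the
    Yule–Walker autocovariances.
    """
    if not ar:
        return sigma2 * n / (n - ddof) * (1 - 1.0 / n)
    gam = stationary_autocovariance(ar, sigma2, max_lag=n - 1)
    h = np.arange(1, n)
    var_mean = (gam[0] + 2.0 * np.sum((1.0 - h / n) * gam[1:n])) / n
    return float(n * (gam[0] - var_mean) / (n - ddof))


def auto_innovation_sd(cfg: SimulationConfig) -> float:
    """Innovation SD pinning the within-subject *stationary* variance
    to 1 on the homoscedastic scale.

    The unit variance splits into the autoregressive part (gamma_0) and
    the variance of the deterministic weekday profile; AUTO solves
    gamma_0(sigma^2) = 1 - Var_w(mu_w) through the Yule–Walker system.

    Note that for the persistent default coefficients (lag weights
    summing to .984) an 84-day record expresses much less than the
    stationary variance — :func:`expected_sample_variance` predicts the
    sample variance a finite window will actually show (~0.44 here).
    The per-subject rescaling of the analysis pipeline absorbs exactly
    this gap, which is why fitted coefficients are unaffected by it.
    """
    if cfg.innovation_sd is not None:
        return float(cfg.innovation_sd)
    if not cfg.ar_coefficients:
        mu = np.array([cfg.weekday_effects.get(w, 0.0) for w in WEEKDAYS])
        var_w = float(mu.var())
        return float(np.sqrt(max(1.0 - var_w, 1e-12)))
    mu = weekday_profile(cfg.ar_coefficients, cfg.weekday_effects, cfg.intercept)
    var_w = float(mu.var())
    if var_w >= 1.0:
        raise ValueError("weekday profile variance exceeds the unit variance target")
    g0_unit = stationary_autocovariance(cfg.ar_coefficients, 1.0)[0]
    return float(np.sqrt((1.0 - var_w) / g0_unit))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    others = [n for n in range(cfg.length_min, cfg.length_max + 1) if n != cfg.length_mode]
    if not others or rng.random() < cfg.mode_mass:
        return cfg.length_mode
    return int(rng.choice(others))


def simulate_panel(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PanelDataset, dict]:
    """Simulate a panel from ``cfg``; returns (dataset, ground_truth).

    Ground truth records the resolved innovation SD and every per-subject
    latent (homoscedastic mean, raw scale, intercept, length, start
    weekday).  The same config and seed always yield the same dataset.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma_eps = auto_innovation_sd(cfg)
    ar = cfg.ar_coefficients
    lags = sorted(ar)
    p = max(lags, default=0)
    d = np.array([cfg.weekday_effects.get(w, 0.0) for w in WEEKDAYS])

    rows = []
    truth_subjects = {}
    subj_meta = []
    for j in range(cfg.n_subjects):
        sid = f"S{j + 1:02d}"
        n_days = _draw_length(rng, cfg)
        start_wd = int(rng.integers(0, 7))
        m_j = float(rng.normal(cfg.mean_loc, cfg.mean_scale))
        s_j = float(rng.lognormal(cfg.scale_logmean, cfg.scale_logsd))
        if ar:
            c_j = intercept_for_mean(ar, cfg.weekday_effects, m_j)
            mu = weekday_profile(ar, cfg.weekday_effects, c_j)
        else:
            c_j = m_j - d.mean()
            mu = c_j + d
        total = cfg.burn_in + n_days
        # history initialised at the stationary weekday profile; burn-in
        # (>= 3x the 56-day memory) removes the remaining transient
        hist_wd = [(start_wd - cfg.burn_in - h) % 7 for h in range(1, p + 1)]
        y = np.empty(p + total)
        for h, w in enumerate(hist_wd):
            y[p - 1 - h] = mu[w]
        eps = rng.normal(0.0, sigma_eps, size=total)
        for i in range(total):
            w = (start_wd + i - cfg.burn_in) % 7  # weekday of this simulated day
            val = c_j + d[w] + eps[i]
            for k in lags:
                val += ar[k] * y[p + i - k]
            y[p + i] = val
        series = y[p + cfg.burn_in :]
        start_weekday_label = WEEKDAYS[start_wd]
        raw = series * s_j
        if cfg.integerize:
            raw = np.maximum(np.round(raw), 0.0)
        miss = rng.random(n_days) < cfg.missing_rate
        raw = raw.astype(float)
        raw[miss] = np.nan
        for t in range(n_days):
            rows.append((sid, t + 1, WEEKDAYS[(start_wd + t) % 7], raw[t]))
        truth_subjects[sid] = {
            "mean": m_j,
            "scale": s_j,
            "intercept": c_j,
            "n_days": n_days,
            "start_weekday": start_weekday_label,
        }
        subj_meta.append(sid)

    # level-2 labels (no effect on counts, mirroring the study population)
    n_m = int(round(cfg.n_subjects * 36 / 62))
    genders = np.array(["M"] * n_m + ["F"] * (cfg.n_subjects - n_m))
    rng.shuffle(genders)
    ages = rng.integers(18, 27, size=cfg.n_subjects)
    subjects = pd.DataFrame(
        {"gender": genders, "age": ages}, index=pd.Index(subj_meta, name="subject_id")
    )
    data = pd.DataFrame(rows, columns=["subject_id", "t", "weekday", "count"])
    truth = {
        "config": cfg.as_dict(),
        "innovation_sd": sigma_eps,
        "subjects": truth_subjects,
    }
    return PanelDataset(data=data, subjects=subjects), truth


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------


def make_fixture_suite(seed: int = 1) -> dict[str, tuple[PanelDataset, dict]]:
    """Small named datasets for tests and examples, deterministic per seed.

    - ``tiny``: 2 subjects x 10 days, white noise, no missing.
    - ``no_missing``: 8 subjects, default AR structure, missing_rate 0.
    - ``white_noise``: 20 subjects x 84 days, all AR and weekday effects 0.
    - ``study_scale``: the full default configuration (62 subjects).
    """
    out = {}
    tiny_cfg = default_config(
        seed=seed,
        n_subjects=2,
        length_min=10,
        length_max=10,
        length_mode=10,
        mode_mass=1.0,
        ar_coefficients={},
        weekday_effects={w: 0.0 for w in WEEKDAYS},
        missing_rate=0.0,
        burn_in=0,
    )
    out["tiny"] = simulate_panel(tiny_cfg)
    out["no_missing"] = simulate_panel(
        default_config(seed=seed + 1, n_subjects=8, missing_rate=0.0)
    )
    out["white_noise"] = simulate_panel(
        default_config(
            seed=seed + 2,
            n_subjects=20,
            length_min=84,
            length_max=84,
            length_mode=84,
            mean_loc=0.0,
            mean_scale=0.0,  # zero-mean homogeneous noise: truly no lag signal
            ar_coefficients={},
            weekday_effects={w: 0.0 for w in WEEKDAYS},
            missing_rate=0.0,
            burn_in=0,
        )
    )
    out["study_scale"] = simulate_panel(default_config(seed=seed + 3))
    return out


def write_fixture_suite(seed: int, out_dir) -> dict[str, Path]:
    """Write each fixture as CSV plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, (ds, truth) in make_fixture_suite(seed).items():
        csv_path = write_panel_csv(ds, out_dir / f"{name}.csv")
        with open(out_dir / f"{name}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)
        paths[name] = csv_path
    return paths
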