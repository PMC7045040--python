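import numpy as np
import pandas as pd
import pytest

import memlag as ml
from memlag.panel import WEEKDAYS


def build_panel(series: dict, start_weekdays: dict | None = None) -> ml.PanelDataset:
    """Hand-build a panel from {subject_id: list of counts (np.nan = missing)}."""
    rows = []
    for sid, values in series.items():
        w0 = WEEKDAYS.index((start_weekdays or {}).get(sid, "Mon"))
        for i, v in enumerate(values):
            rows.append((sid, i + 1, WEEKDAYS[(w0 + i) % 7], float(v)))
    return ml.PanelDataset(
        data=pd.DataFrame(rows, columns=["subject_id", "t", "weekday", "count"])
    )


@pytest.fixture
def tiny_panel():
    """Two subjects x 14 days of small deterministic counts, no missing."""
    rng = np.random.default_rng(42)
    return build_panel(
        {
            "A": (5 + rng.integers(0, 6, size=14)).tolist(),
            "B": (10 + rng.integers(0, 8, size=14)).tolist(),
        },
        start_weekdays={"A": "Mon", "B": "Thu"},
    )


@pytest.fixture(scope="session")
def study_panel():
    """One study-scale simulation from the default configuration."""
    ds, truth = ml.simulate_panel(ml.default_config(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def study_design(study_panel):
    ds, _ = study_panel
    hp = ml.homoscedastic_transform(ds)
    return ml.build_lag_design(hp, ml.LagSpec())


@pytest.fixture(scope="session")
def white_noise_panel():
    cfg = ml.default_config(
        seed=5,
        n_subjects=20,
        length_min=84,
        length_max=84,
        length_mode=84,
        mode_mass=1.0,
        mean_loc=0.0,
        mean_scale=0.0,  # zero-mean homogeneous noise: truly no lag signal
        ar_coefficients={},
        weekday_effects={w: 0.0 for w in WEEKDAYS},
        missing_rate=0.0,
        burn_in=0,
    )
    return ml.simulate_panel(cfg)[0]
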