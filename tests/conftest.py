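import numpy as np
import pytest

from dins import ComparisonData, ScenarioConfig, simulate_comparison


def make_balanced(n, R, rng, cv=0.01, beta0=0.0, beta1=1.0):
    """Small random balanced comparison dataset for unit tests."""
    cfg = ScenarioConfig(
        scenario=1, n=n, R=R, cv_x=cv, cv_y=cv, beta0=beta0, beta1=beta1
    )
    return simulate_comparison(cfg, rng)


def data_from_arrays(x, y, **kw):
    """ComparisonData from (n, R) arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, R = x.shape
    return ComparisonData(
        sample_ids=np.repeat(np.arange(1, n + 1), R),
        replicate_ids=np.tile(np.arange(1, R + 1), n),
        x=x.reshape(-1),
        y=y.reshape(-1),
        require_positive=False,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def glucose_style_data():
    """A 25-sample x 3-replicate dataset shaped like a serum-glucose study."""
    cfg = ScenarioConfig(
        scenario=1, n=25, R=3, cv_x=0.006, cv_y=0.005,
        c_lower=4.2, c_upper=13.3, seed=7,
    )
    return simulate_comparison(cfg)


@pytest.fixture
def glucose_table(tmp_path, glucose_style_data):
    """The same dataset written as a CSV with three device columns."""
    df = glucose_style_data.to_frame().rename(
        columns={"X": "DeviceA", "Y": "DeviceB"}
    )
    rng = np.random.default_rng(11)
    df["DeviceC"] = df["DeviceA"] * 1.02 + rng.normal(0, 0.05, len(df))
    path = tmp_path / "glucose.csv"
    df.to_csv(path, index=False)
    return path
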