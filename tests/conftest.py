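import pandas as pd
import pytest

import vineclim as vc


@pytest.fixture(scope="session")
def small_scene() -> vc.Scene:
    """Desk-scale defective scene: 20x20 grid, 12 sensors, one year."""
    return vc.simulate_scene(seed=42, nx=20, ny=20, n_sensors=12, years=(2018,))


@pytest.fixture(scope="session")
def clean_small(small_scene):
    clean, report = vc.clean_daily(small_scene.obs)
    return clean, report


@pytest.fixture(scope="session")
def pristine_scene() -> vc.Scene:
    """Defect-free scene (no probe noise, no spikes, no gaps)."""
    return vc.simulate_scene(seed=43, nx=20, ny=20, n_sensors=12, years=(2018,),
                             probe_sd_C=0.0, outlier_rate=0.0, missing_rate=0.0)


@pytest.fixture(scope="session")
def sensor_covariates(small_scene):
    return vc.extract_at_points(small_scene.grid, small_scene.meta)


def two_regime_weather(regimes=("clear_calm", "cloudy"), scale=(1.0, 0.15),
                       tn=5.0, tx=15.0) -> pd.DataFrame:
    """Minimal weather frame with matched regional values across regimes."""
    dates = pd.date_range("2018-06-01", periods=len(regimes), freq="D")
    return pd.DataFrame({
        "date": dates, "doy": dates.dayofyear,
        "regime": list(regimes), "amplitude_scale": list(scale),
        "regional_tn": tn, "regional_tx": tx,
    })
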