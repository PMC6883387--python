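import numpy as np
import pandas as pd
import pytest

import swpmodel as sm


def generate_uniform_design(form_id: str, n: int, seed: int,
                            params: sm.ModelParams | None = None,
                            noise_sd: float | None = None) -> pd.DataFrame:
    """Draw observations from a published model over uniform predictor ranges:
    PLWP on [-0.9, 0] MPa, Tmax on [23.8, 38.9] °C, VPDmax on [1.2, 5.6] kPa,
    DOY on [159, 257], with Gaussian SWP noise (default: the form's published
    training RMSE)."""
    rng = np.random.default_rng(seed)
    params = params if params is not None else sm.published_params(form_id)
    form = sm.get_form(form_id)
    noise = params.rmse_train if noise_sd is None else noise_sd
    cols = {"plwp": rng.uniform(-0.9, 0.0, n)}
    clim = seas = None
    if form.climate == "tmax":
        clim = rng.uniform(23.8, 38.9, n)
    elif form.climate == "vpd_max":
        clim = rng.uniform(1.2, 5.6, n)
    if clim is not None:
        cols[form.climate] = clim
    if form.seasonal == "doy":
        seas = rng.uniform(159.0, 257.0, n)
        cols["doy"] = seas
    mu = sm.predict_swp(form, params, cols["plwp"], clim, seas)
    cols["swp"] = mu + (rng.normal(0.0, noise, n) if noise > 0 else 0.0)
    return pd.DataFrame(cols)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (18 plots, 6 two-day campaigns, M5 truth)."""
    return sm.generate_study(sm.SyntheticStudyConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_study():
    """Same design with measurement noise switched off."""
    return sm.generate_study(
        sm.SyntheticStudyConfig(seed=1, noise_sd_swp=0.0, noise_sd_plwp=0.0)
    )


@pytest.fixture
def toy_observations():
    """Hand-written six-row observation table across two plots, with the
    climate covariates attached, for exhaustive pairing oracles."""
    return pd.DataFrame({
        "plot": ["A", "A", "A", "B", "B", "B"],
        "vine": ["v1", "v1", "v2", "v1", "v1", "v1"],
        "cultivar": ["Merlot"] * 3 + ["Cabernet-Sauvignon"] * 3,
        "date": pd.to_datetime([
            "2018-06-10", "2018-06-18", "2018-06-10",
            "2018-06-10", "2018-06-17", "2018-07-20",
        ]),
        "doy": [161, 169, 161, 161, 168, 201],
        "plwp": [-0.20, -0.204, -0.208, -0.40, -0.403, -0.55],
        "swp": [-0.80, -0.90, -0.85, -1.10, -1.05, -1.30],
        "tmax": [28.0, 33.0, 28.0, 28.0, 31.0, 36.0],
        "vpd_max": [2.1, 3.4, 2.1, 2.1, 2.8, 4.4],
    })
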