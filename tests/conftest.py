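import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lipidmed import pipeline, simulate

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def small_params() -> simulate.GenerativeParams:
    """A reduced-size study configuration used across the suite."""
    return simulate.default_params(
        n_source=25_000,
        seed=7,
        n_cases_chd=350,
        n_cases_is=150,
        n_cases_ich=150,
        n_controls=600,
        n_selection=3_000,
    )


@pytest.fixture(scope="session")
def small_study(small_params) -> simulate.StudyData:
    return simulate.simulate_study(small_params, keep_source=True)


@pytest.fixture(scope="session")
def small_bundle(small_params, small_study) -> dict:
    cfg = pipeline.RunConfig(seed=small_params.seed, n_source=small_params.n_source)
    return pipeline.run_full_analysis(cfg, study=small_study)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_raw_lifestyle() -> pd.DataFrame:
    """Hand-built raw lifestyle rows covering the definitional boundaries."""
    rows = [
        # the all-five-flags participant: never smoker, daily 20 g, diet 5/6,
        # active, BMI 24 / WC 80 female
        dict(sex="female", smoking_status="never", alcohol_freq="daily", alcohol_g_per_day=20.0,
             diet_veg_daily=1, diet_fruit_daily=1, diet_red_meat_lt7=1, diet_soybean_ge4=1,
             diet_fish_ge1=1, diet_grains_ge4=0, activity_met_h=30.0, bmi=24.0, wc=80.0),
        # male at the BMI boundary 28.0 (exclusive above 27.9)
        dict(sex="male", smoking_status="current", alcohol_freq="never", alcohol_g_per_day=0.0,
             diet_veg_daily=1, diet_fruit_daily=0, diet_red_meat_lt7=1, diet_soybean_ge4=0,
             diet_fish_ge1=0, diet_grains_ge4=0, activity_met_h=10.0, bmi=28.0, wc=85.0),
        # female exactly at WC 85.0 (strict <85)
        dict(sex="female", smoking_status="former", alcohol_freq="weekly", alcohol_g_per_day=50.0,
             diet_veg_daily=1, diet_fruit_daily=1, diet_red_meat_lt7=1, diet_soybean_ge4=1,
             diet_fish_ge1=0, diet_grains_ge4=0, activity_met_h=20.0, bmi=22.0, wc=85.0),
        # daily exactly 30 g (heavy, inclusive)
        dict(sex="male", smoking_status="never", alcohol_freq="daily", alcohol_g_per_day=30.0,
             diet_veg_daily=0, diet_fruit_daily=0, diet_red_meat_lt7=1, diet_soybean_ge4=0,
             diet_fish_ge1=1, diet_grains_ge4=1, activity_met_h=25.0, bmi=23.0, wc=85.0),
        # low-activity male inside both adiposity rules
        dict(sex="male", smoking_status="never", alcohol_freq="monthly", alcohol_g_per_day=5.0,
             diet_veg_daily=1, diet_fruit_daily=1, diet_red_meat_lt7=1, diet_soybean_ge4=1,
             diet_fish_ge1=1, diet_grains_ge4=1, activity_met_h=5.0, bmi=23.0, wc=85.0),
        # female BMI 26: healthy under the standard rule, not under strict
        dict(sex="female", smoking_status="never", alcohol_freq="never", alcohol_g_per_day=0.0,
             diet_veg_daily=0, diet_fruit_daily=0, diet_red_meat_lt7=0, diet_soybean_ge4=0,
             diet_fish_ge1=0, diet_grains_ge4=0, activity_met_h=15.0, bmi=26.0, wc=75.0),
    ]
    return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])
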