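import numpy as np
import pytest

from portmort.config import (
    AGE_CLASSES,
    SES_CATEGORIES,
    ScenarioConfig,
    SurfaceParams,
    ancona_preset,
)
from portmort.stratify import classify_harbour
from portmort.synth import generate_city


def small_config(n_tracts: int = 4, total_population: int = 2000,
                 mode: str = "grid_tracts", seed: int = 11,
                 flat_rate: float = 5e-3, beta: float = 0.0,
                 noise_sd: float = 0.0, amplitude: float = 4.0,
                 **overrides) -> ScenarioConfig:
    """A tiny 2 x 2 km city for fast exact-answer tests."""
    base = dict(
        n_tracts=n_tracts,
        # off-centre source so tract exposures (and the harbour
        # indicator) vary across tracts
        city_extent=(0.0, 0.0, 2000.0, 2000.0),
        harbour_centroid=(600.0, 700.0),
        harbour_radius_m=800.0,
        tract_mode=mode,
        grid_origin=(0.0, 0.0),
        grid_shape=(4, 4),
        grid_cell_size=500.0,
        pollutants={
            "pm25": SurfaceParams(background=18.1, amplitude=amplitude,
                                  decay_length=800.0, noise_sd=noise_sd),
        },
        total_population=total_population,
        harbour_pop_share=None,
        age_margins={a: p for a, p in zip(AGE_CLASSES,
                                          [0.05, 0.28, 0.42, 0.12, 0.13])},
        sex_margins={"f": 0.52, "m": 0.48},
        ses_distribution={c: p for c, p in zip(
            SES_CATEGORIES, [0.11, 0.12, 0.15, 0.21, 0.35, 0.06])},
        baseline_rates={
            "natural": dict.fromkeys(AGE_CLASSES, flat_rate),
            "cardiovascular": dict.fromkeys(AGE_CLASSES, flat_rate * 0.35),
            "respiratory": dict.fromkeys(AGE_CLASSES, flat_rate * 0.07),
            "cancer": dict.fromkeys(AGE_CLASSES, flat_rate * 0.28),
            "lung_cancer": dict.fromkeys(AGE_CLASSES, flat_rate * 0.05),
        },
        cause_totals=None,
        true_beta={"cardiovascular": {"pm25": beta}} if beta else {},
        study_years=5,
        seed=seed,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def preset_city():
    """The full 722-tract calibrated scenario, built once per session."""
    return generate_city(ancona_preset())


@pytest.fixture(scope="session")
def preset_stratum(preset_city):
    cfg = preset_city.config
    return classify_harbour(preset_city.tracts, cfg.harbour_centroid,
                            cfg.harbour_radius_m)


@pytest.fixture()
def toy_city():
    return generate_city(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20230920)
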