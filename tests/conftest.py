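import numpy as np
import pandas as pd
import pytest

from mossmap import (StudyConfig, ZoneSpec, CovariateSpec, SiteTable,
                     StudyGenerator)


@pytest.fixture
def small_config():
    """Compact two-zone study used by fast tests: 120 sites, one buffer
    family, one zero-inflated family and three single covariates."""
    return StudyConfig(
        n_sites=120,
        zones=[
            ZoneSpec("North", 0.0, 100e3, 50e3, 150e3, weight=80),
            ZoneSpec("South", 0.0, 100e3, 0.0, 50e3, weight=40),
        ],
        species_probs={"Hc": 0.5, "Pp": 0.4, "Tt": 0.1},
        tree_probs={"deciduous": 0.6, "coniferous": 0.4},
        covariates=[
            CovariateSpec("Forest", "percent", (1, 5, 10, 15),
                          corr_length_m=3e4),
            CovariateSpec("Sea", "percent", (5, 10), corr_length_m=4e4,
                          zero_inflation=0.6),
            CovariateSpec("EMEP_air", "positive", (), corr_length_m=5e4,
                          scale=0.5, log_sd=0.4),
            CovariateSpec("RMQS_tot", "positive", (), corr_length_m=3e4,
                          scale=0.3, log_sd=0.5),
            CovariateSpec("Altitude", "positive", (), corr_length_m=4e4,
                          scale=400.0, log_sd=0.7),
        ],
        true_alpha=0.3,
        true_betas={"EMEP_air": -0.6, "RMQS_tot": -0.5,
                    "moss_species:Pp": 0.2, "tree_cover:coniferous": -0.15},
        sigma=0.25,
        cd_max=1.5,
        seed=11,
    )


@pytest.fixture
def small_sites(small_config):
    gen = StudyGenerator(small_config)
    return gen.simulate_response(gen.generate_sites())


def make_table(df: pd.DataFrame, covariates=None, cd_max=1.5) -> SiteTable:
    return SiteTable.from_frame(df, covariates=covariates, cd_max=cd_max)


@pytest.fixture
def toy_regression_table():
    """Deterministic 30-row table with two covariates and a response built
    from known coefficients plus fixed noise."""
    rng = np.random.default_rng(5)
    n = 30
    df = pd.DataFrame({
        "site_id": [f"t{i}" for i in range(n)],
        "x": rng.uniform(0, 1e5, n),
        "y": rng.uniform(0, 1e5, n),
        "zone": "North",
        "moss_species": rng.choice(["Hc", "Pp"], n),
        "tree_cover": "deciduous",
        "a": rng.normal(0, 1, n),
        "b": rng.normal(0, 1, n),
    })
    eta = 0.2 - 0.5 * df["a"] + 0.3 * df["b"] + rng.normal(0, 0.2, n)
    df["cd"] = 1.5 * np.exp(-np.exp(eta))
    return make_table(df, covariates=["a", "b"])
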