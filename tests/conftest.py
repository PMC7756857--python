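import numpy as np
import pandas as pd
import pytest

from vinescape import pipeline, synthdata


@pytest.fixture(scope="session")
def small_config():
    """A reduced-scale study: quick enough for unit tests, large enough
    that every downstream stage has realistic structure."""
    return synthdata.SimulationConfig(
        n_farms=60,
        n_years=4,
        n_regions=6,
        n_observers=12,
        n_cultivars=5,
        n_stations=15,
        raster_extent_m=20000.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthdata.generate_study(small_config)


@pytest.fixture(scope="session")
def small_tables(small_study):
    """Model-ready per-generation and per-season tables at delta=1250."""
    cfg = pipeline.PipelineConfig(
        seed=42, deltas=(1250.0,), run_powersim=False
    )
    gen_tables, season_tables, report = pipeline.build_model_tables(
        small_study, cfg
    )
    return gen_tables[1250.0], season_tables[1250.0], report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_visits():
    """A handful of hand-written visits for exact aggregation checks."""
    rows = []
    for d, pct in [
        ("2010-04-01", 0.0),
        ("2010-04-08", 5.0),
        ("2010-06-15", 8.0),
        ("2010-06-22", 9.0),
        ("2010-08-01", 12.0),
    ]:
        rows.append(
            {
                "farm_id": 1,
                "date": pd.Timestamp(d),
                "year": 2010,
                "observer": 7,
                "infested_pct": pct,
            }
        )
    return pd.DataFrame(rows)
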