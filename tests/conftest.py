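import numpy as np
import pandas as pd
import pytest

from nirleaf import SimulationConfig, load_fixture_tables, simulate_dataset
from nirleaf.data_model import UNITS, ReferenceTable


@pytest.fixture(scope="session")
def fixtures():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset: 8 cultivars, one region, three seasons."""
    cfg = SimulationConfig(seed=42, n_cultivars=8, regions=("RA",))
    spectra, ref = simulate_dataset(cfg)
    return cfg, spectra, ref


def make_reference(values: dict, parameter: str = "TPC") -> ReferenceTable:
    """Hand-built reference table: {sample_id: mean}, one region/season."""
    rows = [
        {
            "sample_id": sid,
            "cultivar": sid,
            "species": "V. corymbosum",
            "region": "RA",
            "season": "spring",
            "plant_id": sid,
            "parameter": parameter,
            "mean": float(v),
            "sd": 0.0,
            "units": UNITS.get(parameter, "a.u."),
        }
        for sid, v in values.items()
    ]
    return ReferenceTable(pd.DataFrame(rows))
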