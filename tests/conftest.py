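import numpy as np
import pandas as pd
import pytest

from esgeo import (
    RegionSpec,
    SamplingDesign,
    SyntheticFieldSpec,
    VariogramModel,
    grid_random_sample,
    simulate_es_field,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_survey():
    """A 60-plot synthetic survey with one lognormal service column."""
    region = RegionSpec(width_m=20_000.0, height_m=15_000.0)
    design = SamplingDesign(cell_size_m=1500.0, n_target=60, exclusion_fraction=0.1, seed=7)
    loc = grid_random_sample(region, design)
    model = VariogramModel(nugget=0.1, sill=0.8, range_=6000.0)
    vals = simulate_es_field(loc, SyntheticFieldSpec(model=model, mean_log=2.0, seed=11))
    table = pd.DataFrame(
        {
            "plot_id": [f"P{i:03d}" for i in range(len(loc))],
            "x": loc[:, 0],
            "y": loc[:, 1],
            "es": vals,
        }
    )
    return region, table, model
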