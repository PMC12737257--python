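import numpy as np
import pandas as pd
import pytest

from sorisk import (ConcentrationTable, ElementReference, default_study_spec,
                    generate_mixture)
from sorisk.health import Distribution, ExposureScenario


@pytest.fixture(scope="session")
def reference():
    return ElementReference.default()


@pytest.fixture(scope="session")
def study_dataset():
    """Default synthetic survey (24 samples, 10 elements, 4 sources)."""
    return generate_mixture(default_study_spec(1))


@pytest.fixture(scope="session")
def study_table(study_dataset):
    return study_dataset.table


@pytest.fixture
def small_table():
    """Tiny handmade table (4 samples x 3 elements)."""
    data = pd.DataFrame(
        {"Pb": [20.0, 30.0, 25.0, 40.0],
         "Cd": [0.05, 0.10, 0.08, 0.20],
         "Hg": [0.02, 0.06, 0.03, 0.10]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    land_use = pd.Series(["farmland", "forest", "grassland", "flooded"],
                         index=data.index)
    return ConcentrationTable(data, land_use)


def point_scenario(receptor="child", **overrides):
    """All-point scenario built from the default catalogue means, with
    selected parameters overridden (floats stay points; Distribution
    objects are used as given)."""
    base = ExposureScenario.default(receptor)
    params = {}
    for name, dist in base.parameters.items():
        if name in overrides:
            ov = overrides[name]
            params[name] = (ov if isinstance(ov, Distribution)
                            else Distribution("point", {"value": float(ov)}))
        else:
            params[name] = Distribution("point", {"value": dist.mean()})
    return ExposureScenario(receptor, params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
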