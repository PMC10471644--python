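import numpy as np
import pytest
from hypothesis import settings

from pufalakes.data_model import SurveySample, load_reference_profiles

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_profiles():
    return load_reference_profiles()


@pytest.fixture(scope="session")
def profile_table(reference_profiles):
    return {p.taxon: p for p in reference_profiles}


def make_sample(abundances, lake_id="L001", site_id="S1", **overrides):
    """A valid survey sample with neutral covariates."""
    kwargs = dict(
        lake_id=lake_id,
        site_id=site_id,
        lake_type="T01",
        vegetation="V1",
        substrate="S1",
        latitude=62.0,
        color=50.0,
        ph=6.8,
        tp=15.0,
        tn=500.0,
        abundances=abundances,
    )
    kwargs.update(overrides)
    return SurveySample(**kwargs)


@pytest.fixture
def simple_sample():
    return make_sample({"A": 3, "B": 0, "C": 1})
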