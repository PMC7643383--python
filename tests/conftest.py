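import numpy as np
import pytest

from ecgcn.signals import RoiTimeSeries
from ecgcn.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (R=12, short series) for fast unit tests."""
    return simulate_cohort(
        n_mdd=8, n_hc=10, R=12, T=80, density=0.12, effect_size=1.5, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_series(data, subject_id="s001", tr=2.0):
    return RoiTimeSeries(subject_id=subject_id, data=np.asarray(data, float), tr_seconds=tr)
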