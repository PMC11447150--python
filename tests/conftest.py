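import numpy as np
import pandas as pd
import pytest

from hypodiary.cgm import RegularTrace
from hypodiary.simulate import SimulationConfig, generate_study

T0 = pd.Timestamp("2023-03-06 00:00:00")
STEP = pd.Timedelta(minutes=5)


def make_regular(values, start=T0, participant="P1", step=STEP):
    return RegularTrace(
        participant_id=participant,
        start=start,
        glucose=np.asarray(values, dtype=float),
        step=step,
    )


@pytest.fixture
def regular_trace_factory():
    return make_regular


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across test modules."""
    cfg = SimulationConfig(n_type1=8, n_type2=8, n_days=12, seed=7)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    paths = small_study.write(outdir)
    return paths
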