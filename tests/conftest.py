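import numpy as np
import pytest
from hypothesis import settings

from stemrx.pipeline import RunConfig, run_pipeline
from stemrx.synthetic_data import SimulationConfig, make_fixture_bundle

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20230126)


@pytest.fixture(scope="session")
def engineered_bundle(tmp_path_factory):
    """Deterministic 21-target fixture bundle (13 targets drug-covered)."""
    path = tmp_path_factory.mktemp("bundle") / "engineered"
    make_fixture_bundle(SimulationConfig(seed=7), path, engineered=True)
    return path


@pytest.fixture(scope="session")
def engineered_report(engineered_bundle, tmp_path_factory):
    """Summary dict and output dir of a full run on the engineered bundle."""
    out = tmp_path_factory.mktemp("report") / "run"
    summary = run_pipeline(RunConfig(bundle_dir=engineered_bundle, out_dir=out, seed=7))
    return summary, out
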