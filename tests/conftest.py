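import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exofrag as xf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_curve_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no secreted transcripts at cutoff")
        warnings.filterwarnings("ignore", message="no transcript qualifies")
        yield


@pytest.fixture
def toy_transcripts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": ["T1", "T2", "T3"],
            "length": [2100, 2000, 600],
            "cds_start": [200, 200, 100],
            "cds_end": [1600, 1400, 500],
        }
    )


@pytest.fixture
def toy_probes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": ["P1", "P2", "P3", "P4", "P5"],
            "transcript_id": ["T1", "T1", "T2", "T2", "T3"],
            "start": [990, 0, 1440, 1840, 100],
            "end": [1050, 60, 1500, 1900, 160],
        }
    )


@pytest.fixture
def toy_mappings(toy_probes, toy_transcripts) -> pd.DataFrame:
    return xf.annotate_probes(toy_probes, toy_transcripts)


@pytest.fixture
def toy_matrix(toy_probes) -> xf.ExpressionMatrix:
    values = pd.DataFrame(
        {
            "E1": [4.0, 1.0, 30.0, 8.0, 2.0],
            "E2": [6.0, 1.0, 30.0, 12.0, 2.0],
            "C1": [2.0, 2.0, 10.0, 2.0, 2.0],
            "C2": [3.0, 2.0, 10.0, 2.0, 2.0],
        },
        index=pd.Index(toy_probes["probe_id"], name="probe_id"),
    )
    groups = pd.Series(
        ["exosome", "exosome", "cell", "cell"], index=["E1", "E2", "C1", "C2"]
    )
    return xf.ExpressionMatrix(values=values, groups=groups)


@pytest.fixture(scope="session")
def sim_bundle() -> xf.SimBundle:
    """One mid-sized planted-fragmentation cohort shared across tests."""
    return xf.simulate_bundle(xf.SimConfig(seed=11, n_transcripts=800))


@pytest.fixture(scope="session")
def sim_secretion(sim_bundle) -> pd.DataFrame:
    return xf.probe_secretion(sim_bundle.matrix, sim_bundle.mappings, cutoff=3.0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_bundle):
    d = tmp_path_factory.mktemp("fixtures")
    xf.write_fixture_bundle(sim_bundle, d)
    return d
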