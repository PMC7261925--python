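import warnings

import pytest
from hypothesis import HealthCheck, settings

from fnirskit.config import RunConfig, run_single
from fnirskit.synthetic import SimulationConfig, simulate_recording, simulate_streams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SESSION_SEED = 11


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, sim_config):
    """One synthetic HDR+XDF recording on disk, shared across the session."""
    out = tmp_path_factory.mktemp("sim")
    paths, truth = simulate_recording(sim_config, out)
    return {"paths": paths, "truth": truth, "config": sim_config}


@pytest.fixture(scope="session")
def sim_memory(sim_config):
    """The same recording in memory (metadata, streams, ground truth)."""
    return simulate_streams(sim_config)


@pytest.fixture(scope="session")
def run_config_factory(sim_dir, tmp_path_factory):
    def make(method: str = "uncorrected", **overrides) -> RunConfig:
        out = tmp_path_factory.mktemp(f"out_{method}")
        doc = {
            "input": {
                "hdr": str(sim_dir["paths"]["hdr"]),
                "xdf": [str(sim_dir["paths"]["xdf"])],
            },
            "output_dir": str(out),
            "subject": "S01",
            "task": "ME",
            "conditions": [{"name": "task", "marker": 1, "n_trials": 10}],
            "method": method,
            "probe_set": sim_dir["config"].n_channels,
        }
        doc.update(overrides)
        return RunConfig.from_dict(doc)

    return make


@pytest.fixture(scope="session")
def tf_bundle(run_config_factory):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_single(run_config_factory("tf"))


@pytest.fixture(scope="session")
def uncorrected_bundle(run_config_factory):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_single(run_config_factory("uncorrected"))


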