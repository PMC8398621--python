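import numpy as np
import pytest

from gaitknee.cli_io import ExperimentConfig, read_cycles_csv, run_experiment
from gaitknee.synthetic_data import DEFAULT_SHOES, SubjectProfile


@pytest.fixture(scope="session")
def metronome_profile() -> SubjectProfile:
    """A noise-free subject walking at exactly 60 strides/min.

    The 1.00 s cycle aligns heel strikes with the 100 Hz grid, so the
    noiseless preprocessing round trip can be checked against the generator
    templates without interpolation slack on the pressure side.
    """
    return SubjectProfile(subject_id="METRO", body_weight=50.4 * 9.81,
                          comfortable_speed=2.4, fast_speed=5.1,
                          cadence_comfortable=60.0, cadence_fast=66.0,
                          rom_scale=1.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def experiment(tmp_path_factory):
    """One full default experiment (7 subjects, 6 models), shared by the
    acceptance tests.  Seeded with the package's default demo seed."""
    out = tmp_path_factory.mktemp("experiment")
    config = ExperimentConfig(seed=1)
    report = run_experiment(config, out)
    pairs = read_cycles_csv(out / "cycles.csv")
    train_ids = [f"SUBJ{i:02d}" for i in range(1, 6)]
    return {"config": config, "report": report, "pairs": pairs,
            "train_ids": train_ids, "out": out}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def shoes():
    return DEFAULT_SHOES
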