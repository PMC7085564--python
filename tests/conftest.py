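import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stdd.pipeline import PipelineConfig, run_pipeline
from stdd.synthetic_data import GROUPS, StudyConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

FULL_COMPLIANCE = {7: 1.0, 10: 1.0, 13: 1.0, 16: 1.0, 19: 1.0, 22: 1.0}


def tiny_config(n_per_group=1, n_days=3, burst_s=10.0,
                compliance=None) -> StudyConfig:
    """A fast, fully compliant study configuration for unit tests."""
    return StudyConfig(
        n_per_group={g: n_per_group for g in GROUPS}, n_days=n_days,
        burst_s=burst_s, compliance=compliance or dict(FULL_COMPLIANCE))


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """One participant per group, 3 days, full compliance."""
    from stdd.synthetic_data import simulate_study
    out = tmp_path_factory.mktemp("tiny_study") / "data"
    simulate_study(seed=11, out_dir=out, config=tiny_config())
    return out


@pytest.fixture(scope="session")
def tiny_participant(tiny_dataset_dir):
    from stdd.sensing_io import list_participants, load_participant
    pid = list_participants(tiny_dataset_dir)[0]
    return load_participant(tiny_dataset_dir, pid)


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The full default synthetic study (5/group, 28 days) run end to end.

    Shared across the acceptance tests; this is the expensive fixture.
    """
    out = tmp_path_factory.mktemp("default_study")
    cfg = PipelineConfig(seed=42)
    artifacts = run_pipeline(cfg, out)
    return {"config": cfg, "out": out, "artifacts": artifacts}


def rng_windows(n: int, length: int = 50, seed: int = 123) -> np.ndarray:
    """Random heterogeneous test windows (varied scales and offsets)."""
    rng = np.random.default_rng(seed)
    scales = rng.uniform(0.01, 50.0, size=n)[:, None]
    offsets = rng.uniform(-20.0, 20.0, size=n)[:, None]
    return rng.standard_normal((n, length)) * scales + offsets
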