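import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_study(tmp_path_factory):
    """Full default study with noise switched off, run once per session."""
    from prmsurv.pipeline import default_config, run_study

    config = default_config(seed=1)
    config.simulation.noise_rel = 0.0
    config.simulation.noise_floor = 0.0
    workdir = tmp_path_factory.mktemp("noise_free_study")
    report, summaries, tests = run_study(config, workdir)
    return config, workdir, report, summaries, tests


@pytest.fixture(scope="session")
def noisy_study(tmp_path_factory):
    """Full default study at the default 1% proportional noise, fixed seed."""
    from prmsurv.pipeline import default_config, run_study

    config = default_config(seed=1)
    workdir = tmp_path_factory.mktemp("noisy_study")
    report, summaries, tests = run_study(config, workdir)
    return config, workdir, report, summaries, tests


@pytest.fixture(scope="session")
def reference_db():
    from prmsurv.datasets import load_reference_proteins

    return load_reference_proteins()
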