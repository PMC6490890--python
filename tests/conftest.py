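import numpy as np
import pytest

from esnp.pipeline import RunConfig, run_pipeline
from esnp.simulate import demo_config, demo_pwms, simulate_study

DEMO_SEED = 11


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """The shipped synthetic study, generated once per session."""
    outdir = tmp_path_factory.mktemp("study")
    manifest = simulate_study(demo_config(DEMO_SEED), outdir)
    return manifest, outdir


@pytest.fixture(scope="session")
def demo_run(demo_study, tmp_path_factory):
    """One full pipeline run over the demo study."""
    manifest, study_dir = demo_study
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig.from_manifest(study_dir / "manifest.json", outdir, seed=DEMO_SEED)
    report = run_pipeline(config)
    return manifest, outdir, report


@pytest.fixture(scope="session")
def stat_pwm():
    return demo_pwms()[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
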