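import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vertchem as vc
from vertchem.synthetic import NoiseParams

settings.register_profile(
    "ci", deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], derandomize=True,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mass_config():
    return vc.default_mass_config()


@pytest.fixture(scope="session")
def noiseless_study(mass_config):
    """Default study design rendered through the deterministic forward model."""
    design = vc.StudyDesign(seed=11)
    run, specimens, truth = vc.make_study(design, mass_config,
                                          noise=NoiseParams.noiseless())
    return run, specimens, truth


@pytest.fixture(scope="session")
def noiseless_reduction(noiseless_study, mass_config):
    # replicate screening is switched off: with zero within-litter spread the
    # pooled replicate set is degenerate clusters, where outlyingness is
    # meaningless; the fixture isolates the calibration chain itself
    run, _, _ = noiseless_study
    thr = vc.Thresholds(outlyingness_cutoff=np.inf)
    return vc.reduce_run(run, mass_config, thr)


@pytest.fixture(scope="session")
def noisy_study(mass_config):
    design = vc.StudyDesign(seed=11)
    return vc.make_study(design, mass_config)


@pytest.fixture(scope="session")
def noisy_reduction(noisy_study, mass_config):
    run, _, _ = noisy_study
    return vc.reduce_run(run, mass_config)


@pytest.fixture(scope="session")
def specimen_info(noisy_study):
    _, specimens, _ = noisy_study
    return specimens.set_index("specimen_id")
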