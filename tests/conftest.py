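import numpy as np
import pytest

from mmae_pbpk.pbpk_model import default_drug_params, default_tumor_params
from mmae_pbpk.physiology import load_physiology
from mmae_pbpk.simulator import DoseEvent, simulate
from mmae_pbpk.synthetic_data import StudyDesign, generate_study

STUDY_TIMES = (5.0 / 60.0, 1.0, 6.0, 12.0, 24.0, 168.0)


@pytest.fixture(scope="session")
def phys():
    return load_physiology("mouse_28g")


@pytest.fixture(scope="session")
def drug(phys):
    return default_drug_params(phys)


@pytest.fixture(scope="session")
def tum():
    return default_tumor_params()


@pytest.fixture(scope="session")
def study_sim(phys, drug, tum):
    """Reference simulation of the biodistribution study design."""
    return simulate(DoseEvent(0.1, 28.0), phys, drug, tum, np.array(STUDY_TIMES))


@pytest.fixture(scope="session")
def noise_free_dataset(phys, drug, tum):
    design = StudyDesign(sigma1=0.0, sigma2=0.0, seed=7)
    return generate_study(design, phys, drug, tum)
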