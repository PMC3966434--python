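import numpy as np
import pytest
from hypothesis import settings

from symseg.config import PipelineConfig
from symseg.phantom import make_phantom, standard_suite
from symseg.pipelines import run_chanvese_baseline, run_ehasa, run_hasa

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def suite():
    return dict(standard_suite())


@pytest.fixture(scope="session")
def phantoms(suite):
    """name -> (image, truth) for every standard fixture."""
    return {name: make_phantom(spec) for name, spec in suite.items()}


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def runs(phantoms, default_config):
    """(pipeline, fixture-name) -> SegmentationResult, shared across tests.

    The level-set evolution dominates test runtime, so every test that needs
    a default-config pipeline result reads it from here.
    """
    out = {}
    for name, (img, _truth) in phantoms.items():
        out[("hasa", name)] = run_hasa(img, default_config)
        out[("ehasa", name)] = run_ehasa(img, default_config)
    out[("baseline", "left-lesion")] = run_chanvese_baseline(
        phantoms["left-lesion"][0], default_config
    )
    return out


@pytest.fixture()
def disk_image():
    """64x64 two-phase fixture: bright disk of radius 12 on dark ground."""
    rr, cc = np.ogrid[:64, :64]
    truth = np.sqrt((rr - 32.0) ** 2 + (cc - 32.0) ** 2) <= 12.0
    image = np.where(truth, 0.9, 0.1).astype(float)
    return image, truth
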