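import numpy as np
import pytest

import fretbench as fb


@pytest.fixture(scope="session")
def gastrula():
    """Noise-free gastrula phantom with a hot margin (activity 0.6) over a
    cool bulk (0.2)."""
    return fb.make_embryo_phantom(
        "gastrula_5hpf", (64, 64), {"margin": 0.6, "bulk": 0.2}, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_stack(gastrula):
    return fb.render_lambda_stack(gastrula, noise=fb.NOISE_OFF, seed=11)


@pytest.fixture(scope="session")
def margin_roi(gastrula):
    return fb.ROI("margin", gastrula.domain_mask("margin")[0])


@pytest.fixture(scope="session")
def bulk_roi(gastrula):
    return fb.ROI("bulk", gastrula.domain_mask("bulk")[0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
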