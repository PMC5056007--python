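import numpy as np
import pytest

from srcstroke import (
    Blob,
    PhantomSpec,
    compute_brain_mask,
    generate_phantom,
    generate_suite,
    prepare_study,
)


def rescale_with_mask(study):
    """Rescaled study with a derived brain mask (no MSP/ASYM)."""
    from dataclasses import replace

    rs = study.rescaled()
    return replace(rs, brain_mask=compute_brain_mask(rs.b0))


@pytest.fixture(scope="session")
def lesion_phantom():
    """One easy phantom with a single off-midline lesion."""
    spec = PhantomSpec(
        lesions=(Blob(center=(45.0, 32.0, 8.0), radii=(5.0, 5.0, 2.0)),),
        seed=123,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def easy20():
    """The standard 20-phantom easy suite."""
    return generate_suite("easy", 20, 7)


@pytest.fixture(scope="session")
def easy20_prepared(easy20):
    """The easy suite after full preprocessing (rescale, mask, MSP, ASYM)."""
    return [prepare_study(ph.study) for ph in easy20]


@pytest.fixture(scope="session")
def mimic20():
    """Suite with shine-through mimic blobs that the ROI must exclude."""
    return generate_suite("mimic", 20, 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
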