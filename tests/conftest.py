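import logging

import numpy as np
import pytest

from mmseg.core import BinaryMask, VolumetricImage
from mmseg.phantom import PhantomSpec, generate_phantom_pair
from mmseg.registration import RegistrationConfig

logging.getLogger("mmseg").setLevel(logging.ERROR)


def make_mask(data, spacing=(1.0, 1.0, 1.0), role=None):
    return BinaryMask(np.asarray(data, dtype=bool), spacing=spacing, role=role)


def make_image(data, spacing=(1.0, 1.0, 1.0)):
    return VolumetricImage(np.asarray(data, dtype=float), spacing=spacing)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition subject (5 lesions, Rician noise)."""
    return generate_phantom_pair(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def coarse_spec():
    """Low-resolution spec for registration-heavy unit tests."""
    return PhantomSpec(shape=(32, 24, 56), spacing=(5.0, 5.0, 5.0), seed=2)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    return generate_phantom_pair(coarse_spec)


@pytest.fixture(scope="session")
def desk_cfg():
    return RegistrationConfig.desk_scale(seed=11)
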