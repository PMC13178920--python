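import numpy as np
import pytest

from smvk.config import rng_stream
from smvk.synthetic import (CohortParams, MifImageParams, generate_cohort,
                            generate_disk_raster, generate_mif_image)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort at seed 1: two MVI+ and two MVI- sections."""
    return generate_cohort(1, groups=("MVI_POS", "MVI_POS", "MVI_NEG", "MVI_NEG"))


@pytest.fixture(scope="session")
def mvi_pos(cohort):
    return cohort.samples[0]


@pytest.fixture(scope="session")
def disk_raster():
    """Two-region (disk vs background) raster fixture at seed 5."""
    return generate_disk_raster(rng=rng_stream(5, "disk"))


@pytest.fixture(scope="session")
def mif_default():
    """Default MIF field at seed 7 with its ground-truth cell table."""
    return generate_mif_image(MifImageParams(), rng_stream(7, "mif"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
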