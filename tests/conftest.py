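import numpy as np
import pytest

from iqspect.core import AcquisitionSchedule, Geometry, ImageVolume
from iqspect.phantoms import make_brain_phantom, make_cylinder_phantom
from iqspect.profiles import INSTITUTION_A, INSTITUTION_B, INSTITUTION_C


@pytest.fixture(scope="session")
def brain_phantom():
    return make_brain_phantom()


@pytest.fixture(scope="session")
def schedule_c():
    return AcquisitionSchedule(dose1_mbq=INSTITUTION_C.imp_dose_mbq,
                               dose2_mbq=INSTITUTION_C.imp_dose_mbq)


@pytest.fixture(scope="session")
def calib_c_noise_free():
    from iqspect.pipeline import calibrate_institution
    return calibrate_institution(INSTITUTION_C, noise=False)


@pytest.fixture
def disc_64():
    """64x64 uniform disc (radius 30 mm, 2 mm pixels) with its geometry."""
    n, sp = 64, 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    r = np.hypot((xx - c) * sp, (yy - c) * sp)
    img = ImageVolume((r < 30).astype(float), (1.0, sp, sp))
    return img, Geometry(60, n, sp), r
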