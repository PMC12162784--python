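import numpy as np
import pytest

from hyperfiber.models import FiberParams, YeohParams
from hyperfiber.synthetic import SyntheticSpec, calibrate_emulation, generate_curves

#: Representative soft-tissue Yeoh set (kPa) with the characteristic
#: negative third constant; used throughout as a ground truth.
TISSUE_YEOH = YeohParams(C1=3.54, C2=38.21, C3=-14.6)


@pytest.fixture(scope="session")
def tissue_yeoh() -> YeohParams:
    return TISSUE_YEOH


@pytest.fixture(scope="session")
def emulation_params() -> FiberParams:
    """Fiber-model constants calibrated to the urethral anchor stresses."""
    return calibrate_emulation()


@pytest.fixture(scope="session")
def anisotropic_curves(emulation_params):
    """Noise-free circumferential + longitudinal curves from the fiber model."""
    spec = SyntheticSpec(ground_truth=emulation_params,
                         strain_grid=np.linspace(0.0, 0.5, 51))
    return generate_curves(spec)


@pytest.fixture(scope="session")
def yeoh_curves(tissue_yeoh):
    """Noise-free curves generated from the isotropic Yeoh ground truth."""
    spec = SyntheticSpec(ground_truth=tissue_yeoh,
                         strain_grid=np.arange(0.0, 0.5001, 0.01))
    return generate_curves(spec)
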