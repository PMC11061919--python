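import numpy as np
import pytest

from trabkit import MaskVolume, PhantomSpec, Segmentation, make_phantom


@pytest.fixture(scope="session")
def plate_phantom():
    """Plate stack, width 0.2 mm / pitch 1.0 mm at 0.05 mm voxels (2 mm cube)."""
    spec = PhantomSpec(kind="plate_stack", pitch_mm=1.0, element_width_mm=0.2,
                       extent_mm=(2.0, 2.0, 2.0), base_spacing_mm=0.05)
    volume, truth = make_phantom(spec)
    voi = MaskVolume(np.ones(volume.shape, bool), volume.spacing_mm)
    return volume, voi, truth


@pytest.fixture(scope="session")
def plate_segmentation(plate_phantom):
    volume, voi, truth = plate_phantom
    return Segmentation(bone=truth.bone, voi=voi)
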