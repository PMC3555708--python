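import numpy as np
import pytest

from cilia3d.imagestack import VoxelGrid

WF_SPACING = (500.0, 108.0, 108.0)


@pytest.fixture(scope="session")
def wf_spacing():
    """Wide-field water-immersion voxel spacing (dz, dy, dx) in nm."""
    return WF_SPACING


def gaussian_blob(shape, spacing, fwhm, center=None, amplitude=1.0, baseline=0.0):
    """Analytic anisotropic Gaussian blob sampled on a voxel grid.

    ``fwhm`` is (axial, lateral) in nm; used as a noise-free stand-in for
    a bead image whose generating widths are known exactly.
    """
    k = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sz, sl = fwhm[0] / k, fwhm[1] / k
    if center is None:
        center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    z = np.arange(shape[0]) * spacing[0] - center[0]
    y = np.arange(shape[1]) * spacing[1] - center[1]
    x = np.arange(shape[2]) * spacing[2] - center[2]
    data = baseline + amplitude * (
        np.exp(-0.5 * (z / sz) ** 2)[:, None, None]
        * np.exp(-0.5 * (y / sl) ** 2)[None, :, None]
        * np.exp(-0.5 * (x / sl) ** 2)[None, None, :]
    )
    return VoxelGrid(data, spacing, name="blob")


@pytest.fixture(scope="session")
def blob_factory():
    return gaussian_blob
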