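import numpy as np
import pytest

from bonemorph.core import Volume
from bonemorph.phantoms import (
    ImagingSpec,
    PhantomSpec,
    add_cortex_and_grayscale,
    make_gaussian_phantom,
    make_lattice_phantom,
)


@pytest.fixture(scope="session")
def plate_spec():
    return PhantomSpec(
        lattice_kind="plate", voxel_size=0.05, dims=(64, 64, 64),
        thickness=0.2, spacing=0.6,
    )


@pytest.fixture(scope="session")
def plate_phantom(plate_spec):
    vol, truth = make_lattice_phantom(plate_spec)
    return vol, truth


@pytest.fixture(scope="session")
def iso_gaussian_phantom():
    spec = PhantomSpec(
        lattice_kind="gaussian_field", voxel_size=0.05, dims=(64, 64, 64), rng_seed=3
    )
    return make_gaussian_phantom(0.3, (1.0, 1.0, 1.0), spec)


@pytest.fixture(scope="session")
def shelled_phantom():
    """Noiseless grayscale phantom: plate interior + 0.5 mm cortical shell."""
    spec = PhantomSpec(
        lattice_kind="plate", voxel_size=0.05, dims=(96, 96, 96),
        thickness=0.2, spacing=0.6, shell_thickness=0.5,
    )
    trab, _ = make_lattice_phantom(spec)
    gray, truth = add_cortex_and_grayscale(trab, spec, ImagingSpec())
    return gray, truth, spec


@pytest.fixture(scope="session")
def template():
    from bonemorph.gmm import make_synthetic_template

    return make_synthetic_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def face_count_mil(mask: np.ndarray, directions: np.ndarray, voxel: float = 1.0):
    """Independent MIL oracle: closed form from axis-aligned interface-face
    counts.  Lines of direction u cross an axis-a face with probability
    proportional to |u_a|, so the crossing count per unit test-line length
    is (Nx|ux| + Ny|uy| + Nz|uz|) / V for the voxelized geometry."""
    nx = (mask[1:, :, :] != mask[:-1, :, :]).sum()
    ny = (mask[:, 1:, :] != mask[:, :-1, :]).sum()
    nz = (mask[:, :, 1:] != mask[:, :, :-1]).sum()
    d = np.abs(directions)
    return voxel * mask.size / (nx * d[:, 0] + ny * d[:, 1] + nz * d[:, 2])
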