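import numpy as np
import pytest

from synaptomo.synth import SynthParams, generate_synapse
from synaptomo.volume import VoxelVolume


@pytest.fixture(scope="session")
def small_synapse():
    """A scaled-down voxelized synapse used across ultrastructure tests."""
    params = SynthParams(contact_radius=100.0, vesicle_count=12, n_proximal=3,
                         n_az_clusters=2, n_psd_clusters=2, rng_seed=1)
    return params, generate_synapse(params)


@pytest.fixture(scope="session")
def flat_synapse_nogeom():
    """Analytic-only synapse (no voxel masks) for alignment tests."""
    params = SynthParams(vesicle_count=10, n_proximal=5, n_az_clusters=4,
                         n_psd_clusters=4, alignment_offset_sd=0.0,
                         rng_seed=3, voxelize=False)
    return params, generate_synapse(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def disk_domain():
    """Flat circular point domain (voxel centres) for CSR/alignment tests."""
    vx, R = 2.0, 150.0
    g = np.arange(-R, R + vx, vx)
    yy, xx = np.meshgrid(g, g, indexing="ij")
    keep = yy ** 2 + xx ** 2 <= R * R
    return np.column_stack([np.zeros(keep.sum()), yy[keep], xx[keep]])


def make_mask(shape, voxel_size=1.0, fill=True):
    return VoxelVolume(np.full(shape, fill, dtype=bool), voxel_size)
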