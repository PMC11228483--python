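"""Voxel volumes with physical scale, and MRC map I/O.

Arrays are ordered ``(z, y, x)`` with 0-based half-open voxel indexing.
Physical coordinates are nanometres, origin at the volume corner, so the
centre of voxel ``(k, j, i)`` sits at ``origin + (k + 0.5, j + 0.5, i + 0.5)
* voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "read_mrc", "write_mrc", "voxel_centers"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with a physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar values; bool for masks, float for density/distance fields.
    voxel_size : float
        Edge length of one (isotropic) voxel in nm.
    origin : ndarray, shape (3,)
        Physical (z, y, x) offset of the volume corner in nm.
    """

    data: np.ndarray
    voxel_size: float = 1.36
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        # NaN is tolerated as an "undefined here" marker (e.g. unsupported
        # autocorrelation lags); infinities are not.
        if self.data.dtype != bool and np.any(np.isinf(self.data)):
            raise ValueError("volume contains infinite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "VoxelVolume":
        """New volume sharing this volume's grid but holding ``data``."""
        return VoxelVolume(data, self.voxel_size, self.origin.copy())

    def physical_extent(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size

    def index_to_nm(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (z,y,x) -> physical voxel-centre coordinates in nm."""
        return (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size + self.origin

    def nm_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Physical coordinates (nm) -> containing voxel indices (z,y,x)."""
        return np.floor((np.asarray(pos, dtype=float) - self.origin)
                        / self.voxel_size).astype(int)


def voxel_centers(mask: VoxelVolume) -> np.ndarray:
    """Physical (z,y,x) centres (nm) of the True voxels of a boolean mask."""
    idx = np.argwhere(mask.data)
    return mask.index_to_nm(idx)


def read_mrc(path) -> VoxelVolume:
    """Read an MRC/CCP4 map into a :class:`VoxelVolume` (voxel size in nm).

    MRC headers store spacing in angstroms; values are converted to nm.
    """
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    arr = np.array(m.grid, copy=True)
    # gemmi grids are (x, y, z) fastest-last; reorder to (z, y, x)
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing_ang = m.grid.unit_cell.a / m.grid.nu
    return VoxelVolume(arr, voxel_size=spacing_ang / 10.0)


def write_mrc(path, volume: VoxelVolume) -> None:
    """Write a :class:`VoxelVolume` as an MRC/CCP4 map (mode 2 float)."""
    import gemmi

    data = volume.data.astype(np.float32)
    nz, ny, nx = data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(nx * volume.voxel_size * 10.0,
                                      ny * volume.voxel_size * 10.0,
                                      nz * volume.voxel_size * 10.0,
                                      90, 90, 90))
    arr = np.array(grid, copy=False)
    arr[...] = data.transpose(2, 1, 0)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
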