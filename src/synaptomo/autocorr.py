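"""Masked, normalised spatial autocorrelation with radial shell averaging.

For a density volume restricted to an irregular region mask, the
autocorrelation of the masked image is normalised by the autocorrelation
of the mask itself times the squared in-mask mean. With that calibration
a spatially uncorrelated (i.i.d.) field inside the mask gives G(r) = 1 at
all nonzero lags, so values above one measure genuine spatial structure,
and the characteristic decay length reports the size of repeating
features (e.g. scaffold nanoclusters, vesicle shells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .volume import VoxelVolume

__all__ = ["RadialAutocorr", "masked_autocorrelation", "radial_average"]

#: minimum voxel-pair overlap for a lag to be considered supported
_MIN_OVERLAP = 0.5


@dataclass
class RadialAutocorr:
    """Radially averaged autocorrelation G(r).

    ``g`` is NaN for shells with no supported lags (flagged absent rather
    than zero); ``n_voxels`` counts contributing lag voxels per shell.
    """

    radii: np.ndarray       # shell centres, nm
    g: np.ndarray
    n_voxels: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"radius_nm": self.radii, "g": self.g,
                             "n_voxels": self.n_voxels})


def _autocorr_fft(arr: np.ndarray, shape) -> np.ndarray:
    f = sfft.rfftn(arr, shape)
    return sfft.irfftn(f * np.conj(f), shape)


def masked_autocorrelation(volume: VoxelVolume, mask: VoxelVolume
                           ) -> VoxelVolume:
    """Normalised autocorrelation of ``volume`` inside ``mask``.

    Computed with zero-padded FFTs (linear, not circular, correlation) on
    the mask bounding box:

        G(lag) = AC[f * m](lag) / (AC[m](lag) * mean_in_mask(f)^2)

    where ``m`` is the binary mask and ``f`` the image. Lags whose mask
    overlap falls below one voxel pair are set to NaN. The returned
    volume is centred: zero lag sits at ``shape // 2``.
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")

    # crop to the mask bounding box; lags beyond it carry no support
    sl = ndimage.find_objects(m.astype(np.int8))[0]
    m = m[sl]
    img = np.where(m, volume.data[sl], 0.0).astype(np.float64)
    mean_in = img.sum() / m.sum()
    if mean_in == 0.0 or not np.any(img[m] != 0):
        raise ValueError("in-mask signal is all zero; cannot normalise")

    pad_shape = [sfft.next_fast_len(2 * s) for s in m.shape]
    ac_img = _autocorr_fft(img, pad_shape)
    ac_mask = _autocorr_fft(m.astype(np.float64), pad_shape)

    # centre the zero lag; keep +-(n-1) lags per axis
    ac_img = np.roll(ac_img, [s - 1 for s in m.shape], axis=(0, 1, 2))
    ac_mask = np.roll(ac_mask, [s - 1 for s in m.shape], axis=(0, 1, 2))
    out_shape = tuple(2 * s - 1 for s in m.shape)
    ac_img = ac_img[tuple(slice(0, s) for s in out_shape)]
    ac_mask = ac_mask[tuple(slice(0, s) for s in out_shape)]

    g = np.full(out_shape, np.nan)
    supported = ac_mask > _MIN_OVERLAP
    g[supported] = ac_img[supported] / (ac_mask[supported] * mean_in ** 2)
    return VoxelVolume(g, volume.voxel_size)


def radial_average(ac_volume: VoxelVolume, shell_width: float | None = None
                   ) -> RadialAutocorr:
    """Average a centred autocorrelation volume in spherical lag shells.

    Shells are half-open ``[r, r + shell_width)`` in nm; the default
    shell width is one voxel. Shells containing no supported (non-NaN)
    lag voxels get ``g = NaN``.
    """
    if shell_width is None:
        shell_width = ac_volume.voxel_size
    if not shell_width > 0:
        raise ValueError("shell_width must be positive")
    data = ac_volume.data
    center = np.array([s // 2 for s in data.shape])
    grids = np.ogrid[tuple(slice(0, s) for s in data.shape)]
    r = np.sqrt(sum((g - c) ** 2.0 for g, c in zip(grids, center)))
    r = r * ac_volume.voxel_size

    n_shell = int(np.floor(r.max() / shell_width)) + 1
    idx = np.minimum((r / shell_width).astype(int), n_shell - 1)
    valid = np.isfinite(data)
    sums = np.bincount(idx[valid].ravel(), weights=data[valid].ravel(),
                       minlength=n_shell)
    counts = np.bincount(idx[valid].ravel(), minlength=n_shell)
    with np.errstate(invalid="ignore"):
        g = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = (np.arange(n_shell) + 0.5) * shell_width
    return RadialAutocorr(radii=radii, g=g, n_voxels=counts)
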