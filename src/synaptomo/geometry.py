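"""Synapse geometry containers: membranes, derived regions, vesicles.

A :class:`SynapseGeometry` bundles the voxel masks of one synapse in a
common physical frame. Only the raw pre/post membrane masks are required;
the classified AZ/PSD membrane masks and the intracellular region bands
are filled in by :mod:`synaptomo.ultra`. Synthetically generated synapses
additionally carry their ground truth (planted cluster centres, vesicle
placements, nominal cleft width) for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume, voxel_centers

__all__ = ["Vesicle", "GroundTruth", "SynapseGeometry"]


@dataclass
class Vesicle:
    """One synaptic vesicle in physical (nm) coordinates.

    ``min_az_distance`` is the minimum distance from the vesicle surface
    (or segmented voxels) to the AZ membrane; vesicles closer than 10 nm
    are the membrane-proximal ("docked/primed") population.
    """

    id: int
    center: np.ndarray              # (z, y, x) nm
    equivalent_diameter: float      # nm
    min_az_distance: float = float("nan")
    truncated: bool = False         # intersects the volume boundary

    PROXIMAL_CUTOFF_NM = 10.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.equivalent_diameter > 0:
            raise ValueError("equivalent_diameter must be positive")

    @property
    def radius(self) -> float:
        return self.equivalent_diameter / 2.0

    @property
    def is_proximal(self) -> bool:
        return bool(self.min_az_distance < self.PROXIMAL_CUTOFF_NM)


@dataclass
class GroundTruth:
    """Planted construction parameters of a synthetic synapse."""

    az_cluster_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    psd_cluster_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    cluster_sigma_nm: float = float("nan")
    cleft_width_nm: float = float("nan")
    contact_radius_nm: float = float("nan")
    alignment_offset_sd_nm: float = float("nan")
    # Analytic min surface-to-membrane distances per vesicle, same order as
    # SynapseGeometry.vesicles.
    vesicle_membrane_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    # Analytic voxel-centre points of the postsynaptic (PSD) membrane
    # surface layer, (N, 3) nm; the projection/randomisation domain.
    psd_surface_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


@dataclass
class SynapseGeometry:
    """Masks, vesicles and (optionally) ground truth for one synapse."""

    pre_membrane_mask: VoxelVolume | None
    post_membrane_mask: VoxelVolume | None
    vesicles: list[Vesicle] = field(default_factory=list)
    az_membrane_mask: VoxelVolume | None = None
    psd_membrane_mask: VoxelVolume | None = None
    az_region_mask: VoxelVolume | None = None
    psd_region_mask: VoxelVolume | None = None
    ground_truth: GroundTruth | None = None

    @property
    def voxel_size(self) -> float:
        for m in (self.pre_membrane_mask, self.post_membrane_mask):
            if m is not None:
                return m.voxel_size
        raise ValueError("geometry has no voxelized masks")

    def proximal_vesicles(self) -> list[Vesicle]:
        return [v for v in self.vesicles if v.is_proximal]

    def psd_membrane_points(self) -> np.ndarray:
        """Voxel-centre coordinates (nm) of the PSD membrane surface.

        Uses the classified PSD membrane mask when available, otherwise
        the analytic surface layer recorded at generation time.
        """
        if self.psd_membrane_mask is not None:
            return voxel_centers(self.psd_membrane_mask)
        if self.ground_truth is not None and len(self.ground_truth.psd_surface_points):
            return self.ground_truth.psd_surface_points
        raise ValueError("PSD membrane not classified and no analytic "
                         "surface recorded; run ultra.classify_synaptic_membranes")

    def vesicle_table(self):
        """Per-vesicle table (pandas DataFrame) in the package CSV layout."""
        import pandas as pd

        rows = [{
            "id": v.id,
            "z_nm": v.center[0], "y_nm": v.center[1], "x_nm": v.center[2],
            "diameter_nm": v.equivalent_diameter,
            "min_az_distance_nm": v.min_az_distance,
            "is_proximal": v.is_proximal,
            "truncated": v.truncated,
        } for v in self.vesicles]
        return pd.DataFrame(rows)
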