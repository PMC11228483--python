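"""Disk formats: MRC masks/fields, PLY meshes, CSV tables, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import SynapseGeometry
from .volume import VoxelVolume, write_mrc

__all__ = ["save_geometry", "save_cluster_table", "save_nnd_table",
           "save_report_json"]


def save_geometry(geometry: SynapseGeometry, outdir, *,
                  meshes=None) -> dict[str, Path]:
    """Write a synapse geometry package: MRC masks, CSV tables, PLY meshes.

    Returns a name -> path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("pre_membrane_mask", "post_membrane_mask",
                 "az_membrane_mask", "psd_membrane_mask",
                 "az_region_mask", "psd_region_mask"):
        vol = getattr(geometry, name)
        if vol is not None:
            p = outdir / f"{name}.mrc"
            write_mrc(p, VoxelVolume(vol.data.astype(np.float32),
                                     vol.voxel_size))
            written[name] = p
    p = outdir / "vesicles.csv"
    geometry.vesicle_table().to_csv(p, index=False)
    written["vesicles"] = p
    gt = geometry.ground_truth
    if gt is not None:
        import pandas as pd
        rows = []
        for kind, arr in (("AZ", gt.az_cluster_centers),
                          ("PSD", gt.psd_cluster_centers)):
            for i, c in enumerate(arr):
                rows.append({"id": i, "type": kind, "z_nm": c[0],
                             "y_nm": c[1], "x_nm": c[2]})
        p = outdir / "ground_truth_clusters.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written["ground_truth_clusters"] = p
    if meshes is not None:
        for name, mesh in meshes.items():
            p = outdir / f"{name}_membrane.ply"
            mesh.export(p)
            written[f"{name}_mesh"] = p
    return written


def save_cluster_table(cluster_set, path) -> None:
    cluster_set.to_frame().to_csv(path, index=False)


def save_nnd_table(result, path) -> None:
    """Per-test summary CSV for an envelope-test result."""
    import pandas as pd
    pd.DataFrame([{
        "observed_median_nm": result.median_observed,
        "simulated_median_nm": result.median_simulated,
        "mad": result.observed_mad,
        "p": result.p_value,
        "n_sims": result.n_sims,
    }]).to_csv(path, index=False)


def save_report_json(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
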