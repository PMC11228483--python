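"""End-to-end orchestration: synthetic cohorts -> analysis reports.

Two entry points mirror the figure-level analyses: an alignment run
(cluster detection or ground truth -> membrane projection -> NND ->
randomisation envelope tests -> nanocolumns) and a simulation run
(per-vesicle fusion events in random vs clustered receptor topographies
-> peaks, enhancement indices, per-synapse coefficients of variation,
and correlation tests). Every stochastic stage receives a sub-seed
derived from the global seed through ``numpy.random.SeedSequence``, and
the derived seeds are logged in the report, so a re-run with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cleftsim, nanocluster, stats, synth
from .alignment import (detect_nanocolumns, paired_alignment_test,
                        project_to_membrane)
from .kinetics import KineticScheme

__all__ = ["AlignmentRunConfig", "SimulationRunConfig", "derive_seed",
           "run_alignment_analysis", "run_simulation_analysis",
           "analyze_synapse_alignment", "simulate_synapse"]


def derive_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from a global seed."""
    import zlib
    h = zlib.crc32(stage.encode()) % (2 ** 20)
    ss = np.random.SeedSequence([int(global_seed) % (2 ** 31), h,
                                 int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# alignment runs

@dataclass
class AlignmentRunConfig:
    n_synapses: int = 10
    synth: synth.SynthParams = field(default_factory=synth.SynthParams)
    n_sims: int = 1000
    seed: int = 0
    use_detected_clusters: bool = False   # else ground-truth centres
    noise_sd: float = 0.33
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AlignmentRunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sp = synth.SynthParams(**d.pop("synth", {}))
        return cls(synth=sp, **d)


def analyze_synapse_alignment(geometry, n_sims: int, seed: int,
                              az_centers=None, psd_centers=None) -> dict:
    """Alignment battery for one synapse.

    Projects AZ/PSD cluster centres (and proximal vesicle centres) onto
    the postsynaptic membrane, runs the PSD->AZ and AZ->PSD envelope
    tests (randomising the moving type only), and detects nanocolumns.
    """
    gt = geometry.ground_truth
    if az_centers is None:
        az_centers = gt.az_cluster_centers
    if psd_centers is None:
        psd_centers = gt.psd_cluster_centers
    membrane = geometry.psd_membrane_points()
    az = project_to_membrane(az_centers, membrane, label="AZ")
    psd = project_to_membrane(psd_centers, membrane, label="PSD")
    rng = np.random.default_rng(seed)
    res = {}
    if len(psd) >= 2 and len(az) >= 1:
        res["psd_vs_az"] = paired_alignment_test(psd, az, membrane,
                                                 n_sims=n_sims, seed=rng)
    if len(az) >= 2 and len(psd) >= 1:
        res["az_vs_psd"] = paired_alignment_test(az, psd, membrane,
                                                 n_sims=n_sims, seed=rng)
    prox = [v for v in geometry.vesicles if v.is_proximal]
    if prox and len(az) >= 1:
        ves = project_to_membrane(np.array([v.center for v in prox]),
                                  membrane, label="vesicle")
        if len(ves) >= 2:
            res["vesicle_vs_az"] = paired_alignment_test(
                ves, az, membrane, n_sims=n_sims, seed=rng)
            if len(psd) >= 1:
                res["vesicle_vs_psd"] = paired_alignment_test(
                    ves, psd, membrane, n_sims=n_sims, seed=rng)
    res["nanocolumns"] = detect_nanocolumns(az, psd)
    res["n_az"], res["n_psd"] = len(az), len(psd)
    return res


def run_alignment_analysis(config: AlignmentRunConfig) -> dict:
    """Cohort-level alignment report over synthetic synapses."""
    report = {"config": _cfg_dict(config), "synapses": []}
    for i in range(config.n_synapses):
        sp = dataclasses.replace(config.synth,
                                 rng_seed=derive_seed(config.seed, "synth", i))
        geometry = synth.generate_synapse(sp)
        if config.use_detected_clusters:
            vol = synth.generate_density_volume(
                geometry, config.noise_sd,
                derive_seed(config.seed, "density", i))
            import synaptomo.ultra as ultra
            az_reg, psd_reg = ultra.define_regions(geometry)
            az_set = nanocluster.detect_nanoclusters(vol, az_reg, "AZ")
            psd_set = nanocluster.detect_nanoclusters(vol, psd_reg, "PSD")
            az_c, psd_c = az_set.centers(), psd_set.centers()
        else:
            az_c = psd_c = None
        res = analyze_synapse_alignment(
            geometry, config.n_sims, derive_seed(config.seed, "align", i),
            az_centers=az_c, psd_centers=psd_c)
        entry = {"synapse": i, "seed": derive_seed(config.seed, "align", i),
                 "n_az_clusters": res["n_az"], "n_psd_clusters": res["n_psd"],
                 "n_nanocolumns": len(res["nanocolumns"])}
        for key in ("psd_vs_az", "az_vs_psd", "vesicle_vs_az",
                    "vesicle_vs_psd"):
            if key in res:
                t = res[key]
                entry[key] = {"observed_median_nm": t.median_observed,
                              "simulated_median_nm": t.median_simulated,
                              "mad": t.observed_mad, "p": t.p_value,
                              "p_string": t.p_string}
        report["synapses"].append(entry)
    if config.outdir:
        _write_report(report, Path(config.outdir) / "alignment_report.json")
    return report


# ---------------------------------------------------------------------------
# simulation runs

@dataclass
class SimulationRunConfig:
    n_synapses: int = 10
    synth: synth.SynthParams = field(default_factory=synth.SynthParams)
    sim: cleftsim.SimConfig = field(default_factory=cleftsim.SimConfig)
    seed: int = 0
    max_vesicles: int | None = None     # cap on proximal vesicles per synapse
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "SimulationRunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sp = synth.SynthParams(**d.pop("synth", {}))
        sc = cleftsim.SimConfig(**d.pop("sim", {}))
        return cls(synth=sp, sim=sc, **d)


def simulate_synapse(geometry, sim_config: cleftsim.SimConfig,
                     scheme: KineticScheme | None = None,
                     max_vesicles: int | None = None) -> dict:
    """Fusion-event simulations for every proximal vesicle of a synapse.

    Each vesicle is run in both receptor topographies with the same
    sub-seeds, yielding per-vesicle peaks, enhancement indices and
    distances to the nearest PSD/AZ cluster (lateral, nm).
    """
    if scheme is None:
        scheme = KineticScheme.default()
    geom = cleftsim.simulation_geometry(geometry)
    gt = geometry.ground_truth
    prox = [v for v in geometry.vesicles if v.is_proximal]
    if max_vesicles is not None:
        prox = prox[:max_vesicles]
    records: list[stats.EnhancementRecord] = []
    traces = {}
    for v in prox:
        cfg = dataclasses.replace(sim_config,
                                  rng_seed=sim_config.rng_seed + v.id)
        tc_r = cleftsim.run_vesicle(geom, v, scheme, cfg, "random")
        tc_c = cleftsim.run_vesicle(geom, v, scheme, cfg, "clustered")
        lat = v.center[1:]
        d_psd = _min_lateral(lat, gt.psd_cluster_centers)
        d_az = _min_lateral(lat, gt.az_cluster_centers)
        records.append(stats.EnhancementRecord(
            vesicle_id=v.id, peak_open_random=tc_r.peak,
            peak_open_clustered=tc_c.peak,
            dist_to_psd_cluster_nm=d_psd, dist_to_az_cluster_nm=d_az))
        traces[v.id] = {"random": tc_r, "clustered": tc_c}
    out = {"records": records, "traces": traces}
    peaks_r = np.array([r.peak_open_random for r in records])
    peaks_c = np.array([r.peak_open_clustered for r in records])
    if len(records) >= 2 and peaks_r.mean() > 0 and peaks_c.mean() > 0:
        out["cv_random"] = stats.coefficient_of_variation(peaks_r)
        out["cv_clustered"] = stats.coefficient_of_variation(peaks_c)
        out["paired_t_p"] = stats.paired_t(peaks_c, peaks_r)
    return out


def _min_lateral(lat_yx: np.ndarray, centers: np.ndarray) -> float:
    if len(centers) == 0:
        return float("nan")
    d = np.hypot(centers[:, 1] - lat_yx[0], centers[:, 2] - lat_yx[1])
    return float(d.min())


def run_simulation_analysis(config: SimulationRunConfig) -> dict:
    """Cohort-level simulation report (peaks, EI, C.V., correlations)."""
    scheme = KineticScheme.default()
    report = {"config": _cfg_dict(config), "synapses": [], "vesicles": []}
    for i in range(config.n_synapses):
        sp = dataclasses.replace(config.synth,
                                 rng_seed=derive_seed(config.seed, "synth", i))
        geometry = synth.generate_synapse(sp)
        sc = dataclasses.replace(config.sim,
                                 rng_seed=derive_seed(config.seed, "sim", i))
        res = simulate_synapse(geometry, sc, scheme,
                               max_vesicles=config.max_vesicles)
        entry = {"synapse": i, "sim_seed": sc.rng_seed,
                 "n_vesicles": len(res["records"])}
        for key in ("cv_random", "cv_clustered", "paired_t_p"):
            if key in res:
                entry[key] = res[key]
        report["synapses"].append(entry)
        for r in res["records"]:
            report["vesicles"].append({
                "synapse": i, "vesicle": r.vesicle_id,
                "peak_random": r.peak_open_random,
                "peak_clustered": r.peak_open_clustered,
                "enhancement_index": r.enhancement_index,
                "dist_to_psd_cluster_nm": r.dist_to_psd_cluster_nm,
                "dist_to_az_cluster_nm": r.dist_to_az_cluster_nm,
            })
    ei = np.array([v["enhancement_index"] for v in report["vesicles"]])
    d_psd = np.array([v["dist_to_psd_cluster_nm"] for v in report["vesicles"]])
    d_az = np.array([v["dist_to_az_cluster_nm"] for v in report["vesicles"]])
    ok = np.isfinite(ei) & np.isfinite(d_psd)
    if ok.sum() >= 3 and len(np.unique(ei[ok])) > 1:
        rho, p = stats.spearman_permutation(
            d_psd[ok], ei[ok], seed=derive_seed(config.seed, "perm", 0))
        report["ei_vs_psd_cluster_distance"] = {"rho": rho, "p": p}
        ok2 = np.isfinite(ei) & np.isfinite(d_az)
        if ok2.sum() >= 3:
            rho2, p2 = stats.spearman_permutation(
                d_az[ok2], ei[ok2], seed=derive_seed(config.seed, "perm", 1))
            report["ei_vs_az_cluster_distance"] = {"rho": rho2, "p": p2}
    pr = [v["peak_random"] for v in report["vesicles"]]
    pc = [v["peak_clustered"] for v in report["vesicles"]]
    if len(pr) >= 2:
        report["mean_peak_random"] = float(np.mean(pr))
        report["mean_peak_clustered"] = float(np.mean(pc))
        report["all_vesicle_paired_t_p"] = stats.paired_t(pc, pr)
    if config.outdir:
        _write_report(report, Path(config.outdir) / "simulation_report.json")
    return report


# ---------------------------------------------------------------------------

def _cfg_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _write_report(report: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    serializable = {k: v for k, v in report.items() if k != "traces"}
    with open(path, "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True,
                  default=_default)
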