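"""Particle-based Monte Carlo simulation of cleft transmission.

A single vesicle fusion releases a bolus of glutamate as a point source
just under the presynaptic membrane; molecules diffuse inside the ~24 nm
cleft with specular reflection at both membranes, escape (and are
removed) once they cross the lateral cleft boundary, and activate AMPA
receptors that diffuse on the postsynaptic membrane while constrained to
the PSD region. Receptors follow a configurable kinetic scheme with two
sequential glutamate-binding steps before a single open state.

Numerical choices
-----------------
* Membrane reflection of glutamate uses triangle-wave folding of the z
  coordinate: the folded endpoint of a free Brownian step is exactly the
  specularly reflected endpoint, at any step size. Substeps therefore
  only refine escape timing and binding sampling (default 10 per us).
* Glutamate binding is reaction-limited for the configured rates: the
  Smoluchowski radius b = k_on / (4 pi D_glu) is ~4e-3 nm, far below any
  resolvable step, so a perfectly absorbing sphere of radius b is not a
  usable discretisation. Binding instead uses a capture hemisphere of
  radius ``capture_radius_nm`` on the membrane: each glutamate inside it
  independently triggers the binding step with probability
  ``k_on_vol * dt / V_hemisphere`` (the bound molecule is consumed).
  Averaged over a Poisson number of in-range molecules this reproduces
  the mass-action rate ``k_on * C`` exactly, which is what the
  master-equation fidelity check pins down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SynapseGeometry, Vesicle
from .kinetics import KineticScheme, M_INV_S_TO_NM3_PER_US, MOLAR_TO_PER_NM3

__all__ = [
    "SimConfig", "CleftGeometry", "TimeCourse",
    "smoluchowski_radius_nm", "vesicular_concentration_mM",
    "seed_receptors", "release_glutamate", "brownian_step",
    "unimolecular_step", "binding_step", "react",
    "run_single", "run_vesicle", "simulation_geometry",
    "simulate_well_mixed",
]


# ---------------------------------------------------------------------------
# configuration and geometry

@dataclass
class SimConfig:
    """Cleft simulation parameters (study defaults).

    Diffusion coefficients are in nm^2/us (3e-6 cm^2/s = 300 nm^2/us for
    glutamate; 5e-10 cm^2/s = 0.05 nm^2/us for receptors).
    """

    dt_us: float = 1.0
    t_total_ms: float = 10.0
    n_glutamate: int = 3500
    d_glu: float = 300.0                 # nm^2/us
    d_receptor: float = 0.05             # nm^2/us
    receptor_density_um2: float = 1500.0
    clustered_fraction: float = 0.75
    n_seeds: int = 50
    rng_seed: int = 0
    glu_substeps: int = 10
    capture_radius_nm: float = 5.0
    allow_reentry: bool = False          # escaped molecules may not return

    def __post_init__(self) -> None:
        if not self.dt_us > 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.clustered_fraction <= 1.0):
            raise ValueError("clustered_fraction must be in [0, 1]")
        if self.d_glu <= 0 or self.d_receptor <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.glu_substeps < 1:
            raise ValueError("glu_substeps must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total_ms * 1000.0 / self.dt_us))


@dataclass
class CleftGeometry:
    """Flattened analytic cleft used by the simulator.

    The cleft is the slab 0 <= z <= ``cleft_width`` (postsynaptic
    membrane at z = 0). Receptors are confined to the PSD disk of
    ``radius``; glutamate remains confined between the membranes out to
    ``radius + escape_apron`` (the membranes appose each other beyond
    the synaptic contact proper) and is removed once it crosses that
    lateral boundary. ``patches`` are the membrane footprints of PSD
    nanoclusters as (y, x, r) disks, used for clustered receptor
    seeding.
    """

    cleft_width: float                       # nm
    radius: float                            # nm
    patches: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    center_yx: np.ndarray = field(default_factory=lambda: np.zeros(2))
    escape_apron: float = 50.0               # nm beyond the PSD disk

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float).reshape(-1, 3)
        self.center_yx = np.asarray(self.center_yx, dtype=float)

    @property
    def psd_area_um2(self) -> float:
        return math.pi * self.radius ** 2 / 1e6

    def in_patch(self, yx: np.ndarray) -> np.ndarray:
        """Boolean: which (N, 2) membrane points lie inside any patch."""
        yx = np.atleast_2d(yx)
        if len(self.patches) == 0:
            return np.zeros(len(yx), dtype=bool)
        d2 = ((yx[:, None, 0] - self.patches[None, :, 0]) ** 2
              + (yx[:, None, 1] - self.patches[None, :, 1]) ** 2)
        return np.any(d2 <= self.patches[None, :, 2] ** 2, axis=1)


def simulation_geometry(geometry: SynapseGeometry,
                        patch_radius_nm: float | None = None) -> CleftGeometry:
    """Build the flat simulation cleft from a synthetic synapse.

    Uses the ground-truth contact radius and cleft width, and places one
    receptor patch per PSD nanocluster at its lateral (y, x) position.
    Patch radius defaults to twice the planted cluster sigma (the
    cluster's nominal radius).
    """
    gt = geometry.ground_truth
    if gt is None:
        raise ValueError("simulation_geometry requires a synthetic geometry; "
                         "build CleftGeometry directly for segmented data")
    if patch_radius_nm is None:
        patch_radius_nm = 2.0 * gt.cluster_sigma_nm
    centers = gt.psd_cluster_centers
    lat = centers[:, 1:] if len(centers) else np.empty((0, 2))
    patches = np.column_stack([lat, np.full(len(lat), patch_radius_nm)]) \
        if len(lat) else np.empty((0, 3))
    return CleftGeometry(cleft_width=gt.cleft_width_nm,
                         radius=gt.contact_radius_nm,
                         patches=patches,
                         center_yx=np.zeros(2) + _synapse_center_yx(geometry))


def _synapse_center_yx(geometry: SynapseGeometry) -> np.ndarray:
    gt = geometry.ground_truth
    if gt is not None and len(gt.psd_surface_points):
        return gt.psd_surface_points[:, 1:].mean(axis=0)
    ext = geometry.pre_membrane_mask.physical_extent()
    return np.array([ext[1] / 2.0, ext[2] / 2.0])


# ---------------------------------------------------------------------------
# elementary pieces

def smoluchowski_radius_nm(k_on_M_s: float, d_glu: float) -> float:
    """Diffusion-limited absorbing-sphere radius b = k_on / (4 pi D)."""
    return k_on_M_s * M_INV_S_TO_NM3_PER_US / (4.0 * math.pi * d_glu)


def vesicular_concentration_mM(n_molecules: int, diameter_nm: float) -> float:
    """Concentration (mM) of n molecules inside a sphere of given diameter."""
    vol_nm3 = math.pi / 6.0 * diameter_nm ** 3
    return n_molecules / (vol_nm3 * MOLAR_TO_PER_NM3) * 1e3


def brownian_step(pos: np.ndarray, diffusion: float, tau_us: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Free Gaussian displacement step, sigma^2 = 2 D tau per axis."""
    return pos + rng.normal(0.0, math.sqrt(2.0 * diffusion * tau_us),
                            size=pos.shape)


def _fold_slab(z: np.ndarray, width: float) -> np.ndarray:
    """Specular reflection into [0, width] by triangle-wave folding."""
    z = np.mod(z, 2.0 * width)
    return np.where(z > width, 2.0 * width - z, z)


def _reflect_disk(yx: np.ndarray, radius: float,
                  center: np.ndarray) -> np.ndarray:
    """Radial specular reflection of (N, 2) points into a disk."""
    rel = yx - center
    rho = np.hypot(rel[:, 0], rel[:, 1])
    out = rho > radius
    if np.any(out):
        rho_ref = rho.copy()
        r = rho[out]
        # fold the radial coordinate; loop handles (never-seen) huge steps
        for _ in range(8):
            r = np.where(r > radius, 2.0 * radius - r, r)
            r = np.abs(r)
            if np.all(r <= radius):
                break
        rho_ref[out] = r
        scale = np.where(rho > 0, rho_ref / np.maximum(rho, 1e-12), 1.0)
        rel = rel * scale[:, None]
    return center + rel


def seed_receptors(geom: CleftGeometry, config: SimConfig, mode: str,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Initial receptor positions on the PSD membrane.

    Total count is ``round(density * PSD area)``. In ``random`` mode all
    receptors are uniform over the PSD disk; in ``clustered`` mode
    ``round(clustered_fraction * N)`` (round-half-even) go uniformly into
    the nanocluster patches and the remainder uniformly outside them.
    Returns ``(positions_yx, in_cluster_flags)``; all receptors start in
    the resting state.
    """
    if mode not in ("random", "clustered"):
        raise ValueError("mode must be 'random' or 'clustered'")
    n_total = round(config.receptor_density_um2 * geom.psd_area_um2)
    if mode == "clustered":
        if len(geom.patches) == 0:
            raise ValueError("clustered mode requires at least one patch")
        if np.any(geom.patches[:, 2] <= 0):
            raise ValueError("zero-area patch in clustered mode")
    if n_total == 0:
        return np.empty((0, 2)), np.empty(0, dtype=bool)

    def _uniform_disk(n, radius, center):
        pts = np.empty((n, 2))
        got = 0
        while got < n:
            c = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 2))
            keep = c[np.einsum("ij,ij->i", c, c) <= radius * radius]
            take = min(len(keep), n - got)
            pts[got:got + take] = keep[:take] + center
            got += take
        return pts

    if mode == "random":
        pos = _uniform_disk(n_total, geom.radius, geom.center_yx)
        return pos, geom.in_patch(pos)

    n_in = round(config.clustered_fraction * n_total)
    n_out = n_total - n_in
    # inside patches: pick a patch weighted by area, then uniform in it,
    # rejecting points outside the PSD disk or in no patch (overlap edge)
    areas = geom.patches[:, 2] ** 2
    weights = areas / areas.sum()
    pos_in = np.empty((n_in, 2))
    got = 0
    while got < n_in:
        k = rng.choice(len(geom.patches), p=weights)
        cy, cx, r = geom.patches[k]
        p = _uniform_disk(1, r, np.array([cy, cx]))[0]
        if np.hypot(*(p - geom.center_yx)) <= geom.radius:
            pos_in[got] = p
            got += 1
    pos_out = np.empty((n_out, 2))
    got = 0
    while got < n_out:
        p = _uniform_disk(1, geom.radius, geom.center_yx)[0]
        if not geom.in_patch(p)[0]:
            pos_out[got] = p
            got += 1
    pos = np.vstack([pos_in, pos_out])
    flags = np.r_[np.ones(n_in, dtype=bool), np.zeros(n_out, dtype=bool)]
    return pos, flags


def release_glutamate(vesicle: Vesicle | np.ndarray, geom: CleftGeometry,
                      n: int = 3500) -> np.ndarray:
    """Point-source glutamate positions for one fusion event.

    All ``n`` molecules start at the presynaptic-membrane point directly
    under the vesicle centre, on the cleft side (z just below the
    presynaptic membrane). Only membrane-proximal vesicles fuse.
    """
    if isinstance(vesicle, Vesicle):
        if not vesicle.is_proximal:
            raise ValueError(f"vesicle {vesicle.id} is not membrane-proximal "
                             "(min AZ distance >= 10 nm)")
        yx = vesicle.center[1:]
    else:
        yx = np.asarray(vesicle, dtype=float)
    if np.hypot(*(yx - geom.center_yx)) > geom.radius + geom.escape_apron:
        raise ValueError("vesicle has no membrane projection inside the cleft")
    z0 = geom.cleft_width * (1.0 - 1e-6)
    pos = np.empty((n, 3))
    pos[:, 0] = z0
    pos[:, 1] = yx[0]
    pos[:, 2] = yx[1]
    return pos


# ---------------------------------------------------------------------------
# reaction machinery

def _binding_probability(k_on_M_s: float, dt_us: float,
                         capture_radius: float) -> float:
    """Per-molecule binding probability inside the capture hemisphere."""
    v_half = (2.0 / 3.0) * math.pi * capture_radius ** 3
    p = k_on_M_s * M_INV_S_TO_NM3_PER_US * dt_us / v_half
    if p > 1.0:
        raise ValueError("binding probability exceeds 1; decrease dt or "
                         "increase capture_radius_nm")
    return p


def unimolecular_step(states: np.ndarray, scheme: KineticScheme,
                      dt_us: float, rng: np.random.Generator) -> np.ndarray:
    """One exact-exponential step of all unimolecular transitions.

    Each receptor leaves its state with probability 1 - exp(-R dt) where
    R is the total unimolecular exit rate, choosing the destination in
    proportion to the branch rates.
    """
    p_leave, dsts, cums = scheme.unimolecular_tables(dt_us * 1e-6)
    leaving = np.nonzero(rng.random(len(states)) < p_leave[states])[0]
    if len(leaving) == 0:
        return states
    new = states.copy()
    for s_idx in np.unique(states[leaving]):
        idx = leaving[states[leaving] == s_idx]
        u = rng.random(len(idx))
        new[idx] = dsts[s_idx][np.searchsorted(cums[s_idx], u, side="right")]
    return new


def binding_step(states: np.ndarray, receptor_pos3: np.ndarray,
                 glu_pos: np.ndarray, scheme: KineticScheme, dt_us: float,
                 rng: np.random.Generator, capture_radius: float,
                 consume: bool = True
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Glutamate-binding transitions for one dt.

    Every glutamate molecule within the capture hemisphere of a
    binding-competent receptor fires that receptor's binding transition
    with probability ``k_on_vol * dt / V_hemisphere``; the first success
    per receptor wins and (optionally) consumes the molecule. Returns
    ``(new_states, consumed_glu_indices)``.
    """
    new = states.copy()
    consumed: list[int] = []
    binding_rates = np.array([scheme.binding_rate_of(s)
                              for s in range(scheme.n_states)])
    eligible = np.nonzero(binding_rates[states] > 0)[0]
    if len(eligible) == 0 or len(glu_pos) == 0:
        return new, np.array(consumed, dtype=int)
    # cheap prefilter: only molecules within capture reach of the
    # receptors' z range can possibly be in a capture hemisphere
    z = receptor_pos3[:, 0]
    cand = np.nonzero((glu_pos[:, 0] <= z.max() + capture_radius)
                      & (glu_pos[:, 0] >= z.min() - capture_radius))[0]
    if len(cand) == 0:
        return new, np.array(consumed, dtype=int)
    diff = receptor_pos3[eligible, None, :] - glu_pos[None, cand, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    in_range = d2 <= capture_radius ** 2
    hit_rows = np.nonzero(in_range.any(axis=1))[0]
    taken = np.zeros(len(glu_pos), dtype=bool)
    for row in hit_rows:
        r_idx = eligible[row]
        k_on = binding_rates[states[r_idx]]
        p = _binding_probability(k_on, dt_us, capture_radius)
        for g in cand[in_range[row]]:
            if consume and taken[g]:
                continue
            if rng.random() < p:
                new[r_idx] = scheme.binding_destination(states[r_idx])
                if consume:
                    taken[g] = True
                    consumed.append(int(g))
                break
    return new, np.array(consumed, dtype=int)


def react(states: np.ndarray, receptor_pos3: np.ndarray, glu_pos: np.ndarray,
          scheme: KineticScheme, dt_us: float, rng: np.random.Generator,
          capture_radius: float, consume: bool = True
          ) -> tuple[np.ndarray, np.ndarray]:
    """All receptor transitions for one dt (Strang-split).

    Unimolecular transitions advance half a step on either side of the
    binding step, so neither process systematically pre-empts the other
    and the splitting error is second order in dt.
    """
    states = unimolecular_step(states, scheme, dt_us / 2.0, rng)
    states, consumed = binding_step(states, receptor_pos3, glu_pos, scheme,
                                    dt_us, rng, capture_radius, consume)
    states = unimolecular_step(states, scheme, dt_us / 2.0, rng)
    return states, consumed


# ---------------------------------------------------------------------------
# full runs

@dataclass
class TimeCourse:
    """Open-receptor count versus time for one vesicle and configuration."""

    times_ms: np.ndarray
    open_count: np.ndarray          # mean over seeds (float) or one seed (int)
    vesicle_id: int = -1
    configuration: str = "random"
    per_seed: np.ndarray | None = None   # (n_seeds, n_times) if retained
    n_receptors: int = 0

    @property
    def peak(self) -> float:
        return float(self.open_count.max())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_ms": self.times_ms,
                             "open_count": self.open_count})

    def to_hdf5(self, path) -> None:
        """Write the time course (and per-seed traces if kept) to HDF5."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times_ms", data=self.times_ms)
            fh.create_dataset("open_count", data=self.open_count)
            if self.per_seed is not None:
                fh.create_dataset("per_seed", data=self.per_seed)
            fh.attrs["vesicle_id"] = self.vesicle_id
            fh.attrs["configuration"] = self.configuration
            fh.attrs["n_receptors"] = self.n_receptors


def run_single(geom: CleftGeometry, release_yx: np.ndarray,
               scheme: KineticScheme, config: SimConfig, mode: str,
               rng: np.random.Generator) -> np.ndarray:
    """One stochastic realisation; returns the open-count trace.

    Glutamate is conserved at every step (in-cleft + escaped + bound =
    n_glutamate, asserted), receptors never leave the PSD disk, and the
    trace has ``config.n_steps + 1`` samples including t = 0.
    """
    if config.capture_radius_nm > geom.cleft_width / 2.0:
        raise ValueError("capture radius exceeds half the cleft width")
    rec_pos, _ = seed_receptors(geom, config, mode, rng)
    n_rec = len(rec_pos)
    states = np.full(n_rec, scheme.resting_index, dtype=np.int64)
    glu = release_glutamate(np.asarray(release_yx), geom, config.n_glutamate)
    n_escaped = 0
    n_bound = 0
    trace = np.zeros(config.n_steps + 1, dtype=np.int64)
    open_idx = scheme.open_index
    tau = config.dt_us / config.glu_substeps
    sig_glu = math.sqrt(2.0 * config.d_glu * tau)
    sig_rec = math.sqrt(2.0 * config.d_receptor * config.dt_us)
    total_uni, _ = scheme.unimolecular_rates()
    r2 = (geom.radius + geom.escape_apron) ** 2

    rec_idle_steps = 0      # receptor motion deferred while no glutamate
    for step in range(1, config.n_steps + 1):
        if len(glu):
            for _ in range(config.glu_substeps):
                glu += rng.normal(0.0, sig_glu, size=glu.shape)
                rel = glu[:, 1:] - geom.center_yx
                inside = np.einsum("ij,ij->i", rel, rel) <= r2
                n_escaped += int(len(glu) - inside.sum())
                glu = glu[inside]
                if len(glu) == 0:
                    break
            if len(glu):
                glu[:, 0] = _fold_slab(glu[:, 0], geom.cleft_width)

        if n_rec:
            if len(glu):
                rec_pos += rng.normal(0.0, sig_rec, size=rec_pos.shape)
                rec_pos = _reflect_disk(rec_pos, geom.radius, geom.center_yx)
                pos3 = np.column_stack([np.zeros(n_rec), rec_pos])
                states, consumed = react(
                    states, pos3, glu, scheme, config.dt_us, rng,
                    config.capture_radius_nm)
                if len(consumed):
                    n_bound += len(consumed)
                    keep = np.ones(len(glu), dtype=bool)
                    keep[consumed] = False
                    glu = glu[keep]
                assert len(glu) + n_escaped + n_bound == config.n_glutamate, \
                    "glutamate leak detected"
            else:
                # positions no longer influence anything observable this
                # step; defer motion and apply one aggregate step at the
                # end (statistically identical endpoint)
                rec_idle_steps += 1
                states = unimolecular_step(states, scheme, config.dt_us, rng)
        count = int(np.count_nonzero(states == open_idx))
        trace[step] = count
        if len(glu) == 0 and count == 0 \
                and not np.any(states != scheme.resting_index):
            break   # nothing can ever change again; trace stays zero
    if n_rec and rec_idle_steps:
        sig = math.sqrt(2.0 * config.d_receptor
                        * config.dt_us * rec_idle_steps)
        rec_pos += rng.normal(0.0, sig, size=rec_pos.shape)
        rec_pos = _reflect_disk(rec_pos, geom.radius, geom.center_yx)
    assert n_rec == 0 or np.all(
        np.hypot(*(rec_pos - geom.center_yx).T) <= geom.radius + 1e-9), \
        "receptor escaped the PSD region"
    return trace


def run_vesicle(geom: CleftGeometry, vesicle: Vesicle | np.ndarray,
                scheme: KineticScheme, config: SimConfig, mode: str,
                keep_seeds: bool = False) -> TimeCourse:
    """Seed-averaged response to one vesicle fusion event.

    Runs ``config.n_seeds`` independent realisations (sub-seeded from
    ``config.rng_seed``) and averages the open-count traces.
    """
    if isinstance(vesicle, Vesicle):
        release = release_glutamate(vesicle, geom, 1)[0, 1:]
        ves_id = vesicle.id
    else:
        release = np.asarray(vesicle, dtype=float)
        ves_id = -1
    ss = np.random.SeedSequence([int(config.rng_seed) % (2 ** 31),
                                 max(ves_id, 0),
                                 0 if mode == "random" else 1])
    children = ss.spawn(config.n_seeds)
    traces = np.empty((config.n_seeds, config.n_steps + 1))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        traces[i] = run_single(geom, release, scheme, config, mode, rng)
    times = np.arange(config.n_steps + 1) * config.dt_us / 1000.0
    return TimeCourse(times_ms=times, open_count=traces.mean(axis=0),
                      vesicle_id=ves_id, configuration=mode,
                      per_seed=traces if keep_seeds else None,
                      n_receptors=round(config.receptor_density_um2
                                        * geom.psd_area_um2))


# ---------------------------------------------------------------------------
# well-mixed validation harness

def simulate_well_mixed(scheme: KineticScheme, glu_conc_M: float,
                        n_receptors: int, t_total_ms: float, dt_us: float,
                        seed: int, box_nm: float = 60.0,
                        capture_radius: float = 5.0,
                        record_every: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Receptor state occupancies in a well-mixed glutamate bath.

    Receptors sit on the floor of a cubic box whose glutamate content is
    held at ``glu_conc_M`` (binding does not deplete the bath); molecules
    diffuse with reflection at the floor/ceiling and periodic wrapping
    laterally. Exercises the same binding and unimolecular machinery as
    the cleft run, so the occupancy trajectories can be compared to an
    independently integrated master equation.

    Returns ``(times_ms, occupancy)`` with occupancy of shape
    ``(n_times, n_states)`` (fractions).
    """
    rng = np.random.default_rng(seed)
    n_glu = max(1, int(round(glu_conc_M * MOLAR_TO_PER_NM3 * box_nm ** 3)))
    glu = rng.uniform(0.0, box_nm, size=(n_glu, 3))
    # receptors scattered on the floor (z = 0); they do not move
    rec = np.column_stack([np.zeros(n_receptors),
                           rng.uniform(0.0, box_nm, size=(n_receptors, 2))])
    states = np.full(n_receptors, scheme.resting_index, dtype=np.int64)
    sig = math.sqrt(2.0 * 300.0 * dt_us)
    n_steps = int(round(t_total_ms * 1000.0 / dt_us))
    times = [0.0]
    occ = [np.bincount(states, minlength=scheme.n_states) / n_receptors]
    # per-state binding probability per in-range molecule
    p_bind = {s: _binding_probability(scheme.binding_rate_of(s), dt_us,
                                      capture_radius)
              for s in range(scheme.n_states) if scheme.binding_rate_of(s) > 0}
    dests = {s: scheme.binding_destination(s) for s in p_bind}

    for step in range(1, n_steps + 1):
        glu += rng.normal(0.0, sig, size=glu.shape)
        glu[:, 0] = _fold_slab(glu[:, 0], box_nm)
        glu[:, 1:] = np.mod(glu[:, 1:], box_nm)
        tree = cKDTree(glu, boxsize=[box_nm * 4, box_nm, box_nm])
        states = unimolecular_step(states, scheme, dt_us / 2.0, rng)
        frozen = states.copy()     # one binding transition per receptor per dt
        for s_idx, p in p_bind.items():
            here = np.nonzero(frozen == s_idx)[0]
            if len(here) == 0:
                continue
            counts = tree.query_ball_point(rec[here], capture_radius,
                                           return_length=True)
            fire = rng.random(len(here)) < -np.expm1(
                np.log1p(-p) * counts)      # 1 - (1-p)^n
            states[here[fire]] = dests[s_idx]
        states = unimolecular_step(states, scheme, dt_us / 2.0, rng)
        if step % record_every == 0:
            times.append(step * dt_us / 1000.0)
            occ.append(np.bincount(states, minlength=scheme.n_states)
                       / n_receptors)
    return np.asarray(times), np.asarray(occ)
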