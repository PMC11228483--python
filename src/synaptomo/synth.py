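"""Synthetic synapse geometries and density volumes with known ground truth.

The generator emulates the measured ultrastructure of glutamatergic
synapses imaged by cryo-ET: two membranes separated by a ~24.4 nm cleft,
a synaptic contact of ~0.1 um^2, a presynaptic cloud of hard-sphere
vesicles with mean diameter 48.7 nm (a handful of them membrane-proximal,
i.e. < 10 nm from the active-zone membrane), and scaffold nanoclusters in
the intracellular bands on both sides whose trans-synaptic lateral offset
is controllable. Every placement is recorded as ground truth so the
downstream analysis stages can be tested for recovery without any
tomogram downloads.

Geometry convention: the z axis is normal to the membranes, the
postsynaptic compartment at low z and the presynaptic terminal at high z.
The membrane "surface" used for analytic distances is the voxel-centre
plane of the cleft-facing (for cleft width) or cytosol-facing (for
vesicle distances) shell layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import GroundTruth, SynapseGeometry, Vesicle
from .volume import VoxelVolume, voxel_centers

__all__ = [
    "SynthParams", "PlacementError",
    "generate_synapse", "generate_density_volume", "generate_csr_points",
]

#: contact radius giving a 0.1 um^2 (= 1e5 nm^2) circular contact
_DEFAULT_CONTACT_RADIUS = math.sqrt(1e5 / math.pi)

#: membrane shell thickness, in voxels
SHELL_VOXELS = 2


class PlacementError(RuntimeError):
    """Raised when bounded rejection sampling cannot place all objects."""


@dataclass
class SynthParams:
    """Parameters of one synthetic synapse.

    Defaults are the study conditions: per-synapse means measured across
    the tomogram dataset (cleft width 24.4 nm, contact area 0.1 um^2,
    94 vesicles of which ~8 are membrane-proximal, ~5 nanoclusters per
    side, voxel size 1.36 nm). ``alignment_offset_sd`` is the SD of the
    lateral AZ->PSD cluster-pair offset; ``inf`` (or ``None``) means the
    PSD clusters are placed independently of the AZ clusters.
    """

    cleft_width: float = 24.4               # nm
    contact_radius: float = _DEFAULT_CONTACT_RADIUS  # nm
    vesicle_count: int = 94
    vesicle_diameter_mean: float = 48.7     # nm
    vesicle_diameter_sd: float = 6.0        # nm; per-vesicle spread, free knob
    n_proximal: int = 8
    n_az_clusters: int = 5
    n_psd_clusters: int = 5
    cluster_radius_mean: float = 30.0       # nm; blob sigma = radius / 2
    cluster_min_spacing: float = 80.0       # nm between same-type centres
    # extra placement-domain radius for unpaired PSD clusters beyond
    # (contact_radius - cluster_radius): the default of two cluster radii
    # lets boundary clusters overhang the rim so receptor-patch coverage
    # is uniform across the PSD; set 0 to confine centres to the contact
    # (e.g. for alignment cohorts, where the randomisation null lives on
    # the membrane domain)
    psd_cluster_overhang: float = 60.0      # nm
    alignment_offset_sd: float = 15.0       # nm; inf = unaligned
    vesicle_alignment_mode: str = "random"  # {"aligned", "random"}
    membrane_curvature: float = 0.0         # 1/nm; 0 = flat planes
    noise_sd: float = 0.33                  # default for density rendering
    voxel_size: float = 1.36                # nm
    rng_seed: int = 0
    lateral_margin: float = 30.0            # nm of empty border around contact
    max_place_attempts: int = 500           # per object, before PlacementError
    voxelize: bool = True                   # rasterise membrane masks

    def __post_init__(self) -> None:
        if self.alignment_offset_sd is None:
            self.alignment_offset_sd = float("inf")
        for name in ("cleft_width", "contact_radius", "vesicle_diameter_mean",
                     "cluster_radius_mean", "voxel_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_proximal > self.vesicle_count:
            raise ValueError("n_proximal cannot exceed vesicle_count")
        if self.vesicle_alignment_mode not in ("aligned", "random"):
            raise ValueError("vesicle_alignment_mode must be aligned|random")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.membrane_curvature < 0:
            raise ValueError("membrane_curvature must be >= 0")

    @property
    def contact_area_um2(self) -> float:
        return math.pi * self.contact_radius ** 2 / 1e6

    @property
    def cluster_sigma(self) -> float:
        return self.cluster_radius_mean / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# placement helpers

def _sample_in_disk(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    """Uniform (y, x) samples in a disk of ``radius`` centred at 0."""
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 2))
        keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius * radius]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def _dart_throw_disk(rng, n, radius, min_spacing, max_attempts):
    """n points in a disk with pairwise spacing >= min_spacing."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts > max_attempts * n:
            raise PlacementError(
                f"cannot place {n} points with spacing {min_spacing:.1f} nm "
                f"in disk of radius {radius:.1f} nm")
        p = _sample_in_disk(rng, radius)[0]
        attempts += 1
        if all(np.hypot(*(p - q)) >= min_spacing for q in pts):
            pts.append(p)
    return np.array(pts) if pts else np.empty((0, 2))


# ---------------------------------------------------------------------------
# membrane surfaces

def _membrane_height(params: SynthParams, rho: np.ndarray, z0: float) -> np.ndarray:
    """z of the membrane mid-surface at lateral radius rho.

    Flat plane for zero curvature, otherwise a spherical cap of radius
    1/curvature bulging toward the presynaptic side.
    """
    c = params.membrane_curvature
    if c == 0:
        return np.full_like(np.asarray(rho, dtype=float), z0)
    R = 1.0 / c
    rho = np.minimum(rho, R * 0.999)
    return z0 + (R - np.sqrt(R * R - rho * rho))


def _layout(params: SynthParams) -> dict:
    """Physical z landmarks and grid shape of the synthetic volume."""
    vx = params.voxel_size
    shell = SHELL_VOXELS * vx
    pad_below = 110.0                      # room for the 100 nm PSD band
    # snap the cleft-facing voxel-centre planes to the grid so the
    # realised separation is round(cleft_width / vx) voxels
    k_post = int(round(pad_below / vx - 0.5))
    z_post_inner = (k_post + 0.5) * vx     # cleft-facing centre plane, post
    z_pre_inner = z_post_inner + round(params.cleft_width / vx) * vx
    z_pre_outer = z_pre_inner + (SHELL_VOXELS - 1) * vx
    # presynaptic vesicle-cloud height sized for ~18% packing, low enough
    # that sequential hard-sphere insertion essentially never jams
    mean_vol = math.pi / 6.0 * params.vesicle_diameter_mean ** 3
    area = math.pi * params.contact_radius ** 2
    cloud = max(3.0 * params.vesicle_diameter_mean,
                params.vesicle_count * mean_vol / (0.18 * area))
    z_top = z_pre_outer + cloud + 10.0
    lateral = 2.0 * (params.contact_radius + params.lateral_margin)
    shape = (int(math.ceil(z_top / vx)),
             int(math.ceil(lateral / vx)),
             int(math.ceil(lateral / vx)))
    center_yx = np.array([shape[1], shape[2]], dtype=float) * vx / 2.0
    return dict(z_post_inner=z_post_inner, z_pre_inner=z_pre_inner,
                z_pre_outer=z_pre_outer, shell=shell, shape=shape,
                center_yx=center_yx, cloud_top=z_top - 10.0)


def _voxelize_membranes(params: SynthParams, lay: dict):
    vx = params.voxel_size
    nz, ny, nx = lay["shape"]
    zc = (np.arange(nz) + 0.5) * vx
    yc = (np.arange(ny) + 0.5) * vx - lay["center_yx"][0]
    xc = (np.arange(nx) + 0.5) * vx - lay["center_yx"][1]
    rho = np.hypot(yc[:, None], xc[None, :])
    in_disk = rho <= params.contact_radius

    pre = np.zeros((nz, ny, nx), dtype=bool)
    post = np.zeros((nz, ny, nx), dtype=bool)
    # per-column surface layer index, then a SHELL_VOXELS-deep stack of
    # layers extending away from the cleft
    k_post = np.round(_membrane_height(params, rho, lay["z_post_inner"])
                      / vx - 0.5).astype(int)
    k_pre = np.round(_membrane_height(params, rho, lay["z_pre_inner"])
                     / vx - 0.5).astype(int)
    for off in range(SHELL_VOXELS):
        kp = np.clip(k_post - off, 0, nz - 1)
        kq = np.clip(k_pre + off, 0, nz - 1)
        jj, ii = np.nonzero(in_disk)
        post[kp[in_disk], jj, ii] = True
        pre[kq[in_disk], jj, ii] = True
    return pre, post


# ---------------------------------------------------------------------------
# main generators

def generate_synapse(params: SynthParams) -> SynapseGeometry:
    """Generate one synthetic synapse with recorded ground truth.

    Returns a :class:`SynapseGeometry` whose pre/post membrane masks are
    voxelized 2-voxel shells over the contact disk, with vesicles as hard
    spheres (no interpenetration of each other or the membranes) and
    planted AZ/PSD nanocluster centres stored in ``ground_truth``.
    Identical ``params`` (including ``rng_seed``) give identical output.
    """
    rng = np.random.default_rng(params.rng_seed)
    lay = _layout(params)
    vx = params.voxel_size
    if params.voxelize:
        pre_mask, post_mask = _voxelize_membranes(params, lay)
    else:
        pre_mask = post_mask = None

    # --- nanocluster centres -------------------------------------------------
    # same-type spacing keeps planted clusters individually resolvable at
    # the local-density window scale; ~5 clusters over 0.1 um^2 have mean
    # nearest-neighbour spacing well above 100 nm, so 80 nm is a floor
    sep = params.cluster_min_spacing
    dom = max(params.contact_radius - params.cluster_radius_mean, 1.0)
    az_yx = _dart_throw_disk(rng, params.n_az_clusters, dom, sep,
                             params.max_place_attempts)
    n_pair = min(params.n_az_clusters, params.n_psd_clusters)
    psd_yx_list = []
    for i in range(params.n_psd_clusters):
        if i < n_pair and np.isfinite(params.alignment_offset_sd):
            for _ in range(params.max_place_attempts):
                p = az_yx[i] + rng.normal(0.0, params.alignment_offset_sd, 2)
                # paired clusters only need half the same-type spacing;
                # the trans-synaptic offset, not packing, dominates here
                if np.hypot(*p) <= dom and all(
                        np.hypot(*(p - q)) >= 0.5 * sep for q in psd_yx_list):
                    break
            else:
                raise PlacementError("cannot place paired PSD cluster")
            psd_yx_list.append(p)
        else:
            # unpaired PSD clusters: centres uniform over the contact disk
            # dilated by psd_cluster_overhang, so the membrane coverage of
            # the resulting receptor patches is uniform across the whole
            # PSD (edge clusters overhang the rim, as real PSD-boundary
            # clusters do)
            dom_psd = dom + params.psd_cluster_overhang
            for _ in range(params.max_place_attempts):
                p = _sample_in_disk(rng, dom_psd)[0]
                if all(np.hypot(*(p - q)) >= sep for q in psd_yx_list):
                    break
            else:
                raise PlacementError("cannot place PSD cluster")
            psd_yx_list.append(p)
    psd_yx = (np.array(psd_yx_list) if psd_yx_list else np.empty((0, 2)))

    # z placement: scaffolds hug their membranes inside the 100 nm bands;
    # the offset floor of one cluster radius (= 2 sigma) keeps the planted
    # blob essentially untruncated by the membrane, so the recorded centre
    # is the centroid of the planted signal
    def _z_off(n):
        return rng.uniform(1.0, 1.5, n) * params.cluster_radius_mean

    z_pre_surface = lay["z_pre_outer"]      # cytosol-facing centre plane, pre
    z_post_surface = lay["z_post_inner"] - (SHELL_VOXELS - 1) * vx
    az_centers = np.column_stack([
        _membrane_height(params, np.hypot(az_yx[:, 0], az_yx[:, 1]),
                         z_pre_surface) + _z_off(len(az_yx)),
        az_yx + lay["center_yx"],
    ]) if len(az_yx) else np.empty((0, 3))
    psd_centers = np.column_stack([
        _membrane_height(params, np.hypot(psd_yx[:, 0], psd_yx[:, 1]),
                         z_post_surface) - _z_off(len(psd_yx)),
        psd_yx + lay["center_yx"],
    ]) if len(psd_yx) else np.empty((0, 3))

    # --- vesicles ------------------------------------------------------------
    from scipy import stats as sstats

    mu, sd = params.vesicle_diameter_mean, params.vesicle_diameter_sd
    if sd > 0:
        lo = max(20.0, mu - 3.0 * sd)
        hi = mu + 3.0 * sd
        diam = sstats.truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd,
                                    loc=mu, scale=sd,
                                    size=params.vesicle_count, random_state=rng)
    else:
        diam = np.full(params.vesicle_count, mu)

    vesicles: list[Vesicle] = []
    surf_d: list[float] = []
    placed: list[tuple[np.ndarray, float]] = []   # (center zyx, radius)

    def _ok(center, radius):
        return all(np.linalg.norm(center - c) >= radius + r
                   for c, r in placed)

    # membrane-proximal vesicles first: surface-to-membrane distance U[0,10)
    for i in range(params.n_proximal):
        r = diam[i] / 2.0
        d = rng.uniform(0.0, Vesicle.PROXIMAL_CUTOFF_NM)
        for _ in range(params.max_place_attempts):
            if params.vesicle_alignment_mode == "aligned" and len(az_yx):
                j = i % len(az_yx)
                yx = az_yx[j] + rng.normal(0.0, 5.0, 2)
            else:
                # release sites cover the whole contact uniformly; rim
                # vesicles overhang it (the membranes continue outward)
                yx = _sample_in_disk(rng, params.contact_radius)[0]
            zm = float(_membrane_height(params, np.hypot(*yx), z_pre_surface))
            center = np.array([zm + d + r, *(yx + lay["center_yx"])])
            if _ok(center, r):
                break
        else:
            raise PlacementError(f"cannot place proximal vesicle {i}")
        placed.append((center, r))
        surf_d.append(d)
        vesicles.append(Vesicle(id=i, center=center, equivalent_diameter=diam[i],
                                min_az_distance=d))

    # remaining cloud vesicles: uniform in the presynaptic cylinder
    for i in range(params.n_proximal, params.vesicle_count):
        r = diam[i] / 2.0
        for _ in range(params.max_place_attempts):
            yx = _sample_in_disk(rng, max(params.contact_radius - r, 1.0))[0]
            zm = float(_membrane_height(params, np.hypot(*yx), z_pre_surface))
            # cloud vesicles stay out of the proximal (<10 nm) band so the
            # proximal census equals n_proximal exactly
            z = rng.uniform(zm + r + Vesicle.PROXIMAL_CUTOFF_NM,
                            lay["cloud_top"] - r)
            center = np.array([z, *(yx + lay["center_yx"])])
            if _ok(center, r):
                break
        else:
            raise PlacementError(f"cannot place vesicle {i}")
        placed.append((center, r))
        d = center[0] - r - float(_membrane_height(params, np.hypot(*yx),
                                                   z_pre_surface))
        surf_d.append(d)
        vesicles.append(Vesicle(id=i, center=center, equivalent_diameter=diam[i],
                                min_az_distance=d))

    gt = GroundTruth(
        az_cluster_centers=az_centers,
        psd_cluster_centers=psd_centers,
        cluster_sigma_nm=params.cluster_sigma,
        cleft_width_nm=params.cleft_width,
        contact_radius_nm=params.contact_radius,
        alignment_offset_sd_nm=params.alignment_offset_sd,
        vesicle_membrane_distances=np.array(surf_d),
        psd_surface_points=_psd_surface_points(params, lay),
    )
    geom = SynapseGeometry(
        pre_membrane_mask=VoxelVolume(pre_mask, vx) if pre_mask is not None else None,
        post_membrane_mask=VoxelVolume(post_mask, vx) if post_mask is not None else None,
        vesicles=vesicles,
        ground_truth=gt,
    )
    return geom


def _psd_surface_points(params: SynthParams, lay: dict) -> np.ndarray:
    """Voxel-centre (z, y, x) points of the cleft-facing PSD surface layer."""
    vx = params.voxel_size
    _, ny, nx = lay["shape"]
    yc = (np.arange(ny) + 0.5) * vx - lay["center_yx"][0]
    xc = (np.arange(nx) + 0.5) * vx - lay["center_yx"][1]
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    rho = np.hypot(yy, xx)
    keep = rho <= params.contact_radius
    z_surf = _membrane_height(params, rho[keep], lay["z_post_inner"])
    z_snap = (np.floor(z_surf / vx) + 0.5) * vx
    return np.column_stack([z_snap,
                            yy[keep] + lay["center_yx"][0],
                            xx[keep] + lay["center_yx"][1]])


def membrane_meshes(params: SynthParams):
    """Triangle meshes (trimesh) of the two membrane mid-surfaces."""
    import trimesh

    lay = _layout(params)
    n = 64
    g = np.linspace(-params.contact_radius, params.contact_radius, n)
    yy, xx = np.meshgrid(g, g, indexing="ij")
    rho = np.hypot(yy, xx)
    meshes = {}
    for name, z0 in (("pre", lay["z_pre_inner"]), ("post", lay["z_post_inner"])):
        zz = _membrane_height(params, rho, z0)
        verts = np.column_stack([
            (xx + lay["center_yx"][1]).ravel(),
            (yy + lay["center_yx"][0]).ravel(),
            zz.ravel(),
        ])
        faces = []
        for j in range(n - 1):
            for i in range(n - 1):
                if rho[j, i] <= params.contact_radius:
                    a = j * n + i
                    faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
        meshes[name] = trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                                       process=False)
    return meshes["pre"], meshes["post"]


def _add_blob(data: np.ndarray, center_vox: np.ndarray, sigma_vox: float,
              amplitude: float) -> None:
    """Add an isotropic Gaussian blob, rendered in a +-4 sigma window."""
    r = int(math.ceil(4.0 * sigma_vox))
    lo = np.maximum(np.round(center_vox).astype(int) - r, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + r + 1, data.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
        amplitude * np.exp(-d2 / (2.0 * sigma_vox ** 2)))


def _add_shell(data: np.ndarray, center_vox: np.ndarray, radius_vox: float,
               amplitude: float, thickness_vox: float) -> None:
    """Add a spherical shell (membrane-like vesicle signal)."""
    r = int(math.ceil(radius_vox + 3.0 * thickness_vox))
    lo = np.maximum(np.round(center_vox).astype(int) - r, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + r + 1, data.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center_vox)))
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
        amplitude * np.exp(-(d - radius_vox) ** 2 / (2.0 * thickness_vox ** 2)))


def _add_ball(data: np.ndarray, center_vox: np.ndarray, radius_vox: float,
              amplitude: float) -> None:
    """Add a solid sphere of constant amplitude (vesicle lumen contrast)."""
    r = int(math.ceil(radius_vox)) + 1
    lo = np.maximum(np.round(center_vox).astype(int) - r, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + r + 1, data.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
        amplitude * (d2 <= radius_vox ** 2))


def generate_density_volume(geometry: SynapseGeometry, noise_sd: float,
                            seed: int, *, blob_amplitude: float = 1.0,
                            include_vesicles: bool = True,
                            include_membranes: bool = True,
                            baseline: float = 1.0) -> VoxelVolume:
    """Render a noisy scalar density volume from a synthetic geometry.

    Bright-signal/dark-background contrast: planted nanoclusters become
    positive Gaussian blobs at their ground-truth centres, vesicles become
    spherical shells, membranes bright shells, on a constant positive
    baseline with additive Gaussian noise of SD ``noise_sd``. The planted
    blob SNR is ``blob_amplitude / noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if geometry.ground_truth is None:
        raise ValueError("density rendering requires a synthetic geometry "
                         "with ground truth")
    if geometry.pre_membrane_mask is None:
        raise ValueError("geometry was generated with voxelize=False")
    vx = geometry.voxel_size
    shape = geometry.pre_membrane_mask.shape
    data = np.full(shape, float(baseline))
    gt = geometry.ground_truth
    sigma_vox = gt.cluster_sigma_nm / vx
    for c in np.vstack([gt.az_cluster_centers, gt.psd_cluster_centers]):
        _add_blob(data, c / vx - 0.5, sigma_vox, blob_amplitude)
    if include_membranes:
        data[geometry.pre_membrane_mask.data] += blob_amplitude
        data[geometry.post_membrane_mask.data] += blob_amplitude
    if include_vesicles:
        # bright membrane shell around a lumen darker than the cytosol,
        # the contrast Wiener-filtered tomograms show
        for v in geometry.vesicles:
            c = v.center / vx - 0.5
            _add_shell(data, c, v.radius / vx, blob_amplitude, 2.0 / vx)
            _add_ball(data, c, 0.85 * v.radius / vx,
                      -0.3 * blob_amplitude * baseline)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=shape)
    return VoxelVolume(data, vx)


def generate_csr_points(n: int, region, min_spacing: float,
                        seed) -> np.ndarray:
    """Complete-spatial-randomness points over a voxel region.

    ``region`` is either a boolean mask :class:`VoxelVolume` or an
    ``(N, 3)`` array of candidate (z, y, x) positions in nm (e.g. membrane
    voxel centres). Points are drawn uniformly over the candidates subject
    to a pairwise ``min_spacing`` (nm), by bounded dart throwing.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if isinstance(region, VoxelVolume):
        cand = voxel_centers(region)
    else:
        cand = np.asarray(region, dtype=float)
    if cand.ndim != 2 or cand.shape[1] != 3:
        raise ValueError("region candidates must be (N, 3)")
    if len(cand) == 0:
        raise ValueError("region is empty")
    if n <= 0:
        return np.empty((0, 3))

    if min_spacing <= 0:
        idx = rng.integers(0, len(cand), size=n)
        return cand[idx]

    chosen = np.empty((n, 3))
    got = 0
    attempts = 0
    stalled = 0
    max_attempts = 500 * n + 1000
    while got < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"cannot place {n} CSR points with spacing "
                f"{min_spacing:.1f} nm in a {len(cand)}-voxel region")
        p = cand[rng.integers(0, len(cand))]
        attempts += 1
        if got == 0 or np.min(np.linalg.norm(chosen[:got] - p, axis=1)) >= min_spacing:
            chosen[got] = p
            got += 1
            stalled = 0
        else:
            stalled += 1
            if stalled >= 200:
                # earlier picks can make tight spacings infeasible;
                # restart the whole configuration rather than give up
                got = 0
                stalled = 0
    return chosen
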