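# Methods

`synaptomo` re-implements, as a tested pipeline, the quantitative analyses
applied to cryo-electron tomograms of glutamatergic synapses: per-synapse
ultrastructure metrics, masked spatial autocorrelation, local-density
nanocluster segmentation, trans-synaptic alignment statistics with
randomisation nulls, and a particle-based Monte Carlo simulation of
glutamate release and AMPA receptor activation in the cleft. Because the
tomograms themselves are multi-hundred-gigabyte external deposits, every
stage is exercised on synthetic synapse geometries with recorded ground
truth; this note states what those geometries emulate, the numerical
choices made where the published description leaves freedom, and what the
synthetic results do and do not establish about real data.

## Coordinate and unit conventions

Voxel arrays are ordered `(z, y, x)` with 0-based half-open indexing; the
centre of voxel `(k, j, i)` is at `(k+0.5, j+0.5, i+0.5) * voxel_size`
nm from the volume corner. All distances are reported in nm, areas in
um^2, volumes in nm^3, rates in s^-1 (binding rates in M^-1 s^-1),
diffusion coefficients in nm^2/us. The default voxel size is 1.36 nm
(the bin-8 pixel size of the source tomograms); analyses are
scale-parameterised and several validation suites run at 2.72 nm (bin-2
of that grid) purely to reduce problem size — the note on problem sizes
below lists where.

## Synthetic synapse generator

The generator (`synaptomo.synth`) emulates the dataset-mean
ultrastructure of a cultured-hippocampal-neuron synapse:

| parameter | default | meaning |
|---|---|---|
| `cleft_width` | 24.4 nm | separation of the cleft-facing membrane voxel-centre planes |
| `contact_radius` | 178.4 nm | circular contact, area 0.1 um^2 |
| `vesicle_count` | 94 | hard-sphere vesicles in the presynaptic cloud |
| `vesicle_diameter_mean` / `_sd` | 48.7 / 6 nm | truncated normal (±3 SD, floor 20 nm) |
| `n_proximal` | 8 | vesicles with surface-to-AZ-membrane distance drawn U[0, 10) nm |
| `n_az_clusters` / `n_psd_clusters` | 5 / 5 | planted scaffold nanoclusters per side |
| `cluster_radius_mean` | 30 nm | planted blob sigma = radius/2 |
| `cluster_min_spacing` | 80 nm | same-type centre spacing floor |
| `alignment_offset_sd` | 15 nm | lateral SD of AZ→PSD pair offsets; `inf` = unaligned |
| `membrane_curvature` | 0 | spherical-cap curvature, 1/nm |
| `noise_sd` | 0.33 | additive Gaussian noise (planted blob SNR = 1/noise_sd) |

Membranes are parametric surfaces (flat planes or spherical caps)
voxelized as two-voxel-thick shells over the contact disk; the surface
planes are snapped to the voxel grid so the realised cleft is
`round(cleft_width / voxel_size)` voxels. Measured cleft width
(symmetric mean of directed membrane distances) therefore carries a
positive bias of about half a voxel from shell thickness — at 1.36 nm
voxels the default geometry measures ≈25.2 nm against the nominal
24.4 nm, inside the dataset SD.

Vesicle diameter SD is a free parameter (the source data report only the
mean); 6 nm reproduces a realistic per-vesicle spread without violating
the 20 nm floor. Vesicles are placed by bounded rejection sampling with
hard-sphere exclusion against each other and the membranes; the cloud
height is sized for ~18 % packing so sequential insertion essentially
never jams, and an explicit `PlacementError` is raised (never silent
truncation) when parameters are infeasible. Cloud vesicles are kept out
of the proximal (<10 nm) band so `n_proximal` is exact.

Planted nanoclusters are isotropic Gaussian blobs (sigma =
`cluster_radius_mean`/2) in the intracellular bands, at depths of 1.0 to
1.5 cluster radii from the membrane. The depth floor keeps the blob
essentially untruncated by the band, so the recorded ground-truth centre
is the centroid of the planted signal — the condition under which
centre-of-mass recovery is a meaningful detector test. The spacing floor
of 80 nm reflects that ~5 clusters on a 0.1 um^2 contact have mean
nearest-neighbour spacings well above 100 nm; at spacings much below
~2.5 cluster radii the fixed detection chain (below) cannot separate
neighbours even noiselessly, so tighter packing would test the generator,
not the detector.

Two placement-domain choices matter for the simulation comparison (see
*Receptor topography comparison* below): vesicle release sites cover the
whole contact disk uniformly, and unpaired PSD clusters are drawn from
the disk dilated by `psd_cluster_overhang` (default 60 nm) so the
receptor-patch coverage they induce is uniform across the PSD, with edge
patches overhanging the rim as real PSD-boundary clusters do. Alignment
cohorts set the overhang to zero so that observed cluster centres and the
randomisation null live on the same membrane domain.

Density volumes render the geometry with bright-signal/dark-background
contrast: planted blobs, bright membrane shells, and vesicles as bright
membrane shells around lumens darker than the cytosol (the contrast
Wiener-filtered tomograms show), plus a positive baseline and additive
Gaussian noise. The generator does **not** model tomographic artifacts
(missing wedge, CTF, denoising residues); consequences are discussed
under *Limitations*.

## Ultrastructure analysis

Distance fields are Euclidean distance transforms with physical sampling.
The AZ membrane is the presynaptic membrane at a postsynaptic-membrane
distance strictly inside (10, 40) nm; the PSD membrane is the mirror.
Cleft width is the symmetric mean of the two directed mean distances
(the direction is not specified in the source; the symmetric choice
removes the arbitrary ordering). Intracellular 100 nm region bands are
cut from the two distance fields; the presynaptic/postsynaptic side of a
membrane is decided by requiring the *opposite* membrane to be at least
one cleft width farther away, which excludes the cleft itself including
its membrane-adjacent voxels. Membrane-proximal vesicle volumes are
subtracted from the AZ region. Membrane area is the lateral voxel
footprint of the classified membrane (exact for near-planar shells,
underestimating steeply inclined membranes). Vesicles are measured from
label volumes: volume-equivalent sphere diameter, minimum of the
AZ-membrane distance field over the vesicle's voxels, proximal flag at
<10 nm; vesicles touching the volume boundary are flagged and excluded
from diameter statistics. The vesicle-proximity histogram uses half-open
bins and is normalised to counts per 0.1 um^2 of AZ membrane.

## Masked autocorrelation

The autocorrelation of the masked image is computed with zero-padded
FFTs on the mask bounding box and normalised by the autocorrelation of
the binary mask times the squared in-mask mean. This normalisation is
*fixed by a calibration property*: a spatially uncorrelated field inside
the mask must give G(r) = 1 at all supported nonzero lags (verified over
100 noise realisations to within ±0.02). Lags with less than one voxel
pair of mask support are NaN ("absent", never zero), and radial shell
averages (half-open shells, default width one voxel) propagate that
flag. On synthetic vesicle-cloud volumes, G(r) shows the two physical
scales: a peak at the vesicle diameter (the antipodal membrane
correlation, which requires the dark-lumen contrast — with uniformly
bright vesicle interiors it degenerates to a shoulder ending at the
diameter) and a peak at the packing spacing.

## Nanocluster detection

Protein voxels are thresholded at mean + 1.5 SD of the in-region
intensity. Local density is the percentage of protein voxels in a
spherical window (diameter 21 voxels ≈ 28.6 nm at the default grid; the
window is taken as spherical, a choice the source leaves open), with the
denominator restricted to the region — the boundary correction that
makes a fully protein region score 100 even at its edge. Seeds are
26-connected components at ≥2.5× the mean in-region density.

The proprietary propagating-contour growth is re-implemented with
defined semantics: a marker-controlled watershed on the priority surface
`w·(−density) + (1−w)·|∇density|` (both min–max normalised, `w` =
`intensity_weight` = 0.5) partitions the region among seeds; territories
whose separating saddle is too shallow are merged — a pair stays split
only if `min(peak_i, peak_j) − saddle > edge_sensitivity ×
(min(peak) − region minimum)` with `edge_sensitivity` = 0.5, which
operationalises "visually separable peaks are not merged"; each cluster
is then limited to `propagation_time` = 10 geodesic dilation steps from
its seed (the maximum growth radius reading of a propagation time); and
clusters below a tenth of the window volume are dropped as noise (the
source states no minimum size; this is a documented deviation knob).
Cluster volumes are voxel counts times voxel volume, centres of mass are
unweighted voxel means.

## Trans-synaptic alignment

Cluster and proximal-vesicle centres are projected to the nearest
postsynaptic-membrane voxel centre (ties broken lexicographically in
(z, y, x) for determinism); nearest-neighbour distances between
projected sets are 3D Euclidean (no geodesic surface distance — the
projection makes them primarily lateral). The randomisation null
re-places one point type at a time: CSR draws over the PSD membrane
voxel centres, constrained to the observed same-type minimum spacing,
with the other type held fixed; 1,000 simulations by default. The MAD
envelope test evaluates exact empirical CDFs on the pooled distance grid
(no binning), references the mean CDF over *all* trials (observed plus
simulated), and reports p as the fraction of simulations whose MAD
reaches the observed MAD. Ties count toward p, making the degenerate
all-identical case come out as MAD 0, p 1; a p of exactly zero is
reported as "< 1/n_sims". Under an exchangeable CSR null the test is
calibrated (type-I error 0.05 ± 0.02 at nominal 0.05); note that the
plug-in minimum-spacing constraint makes the *procedure as published*
slightly anticonservative when the observed spacing is itself a random
draw, which is a property of the method, not of this implementation.
Nanocolumns are mutually nearest AZ/PSD pairs separated by <100 nm;
synapse-centre distances use the PSD-membrane centre of mass.

## Cleft simulation

The simulator (`synaptomo.cleftsim`) releases 3,500 glutamate molecules
(≈100 mM in a 48 nm vesicle) as a point source just under the
presynaptic membrane and follows them with Brownian dynamics
(D = 300 nm^2/us) between reflective membranes. Reflection uses
triangle-wave folding of z — the folded endpoint of a free Gaussian step
*is* the specularly reflected endpoint, exactly, at any step size — so
the `glu_substeps` = 10 substeps per 1 us step only refine escape timing
and binding sampling, not reflection fidelity. Molecules crossing the
lateral boundary (the contact radius plus a 50 nm `escape_apron`,
because the membranes appose each other beyond the synaptic contact)
are removed; escaped plus bound plus in-cleft counts are asserted to
equal the release count at every step. Receptors (density 1,500 um^-2,
D = 0.05 nm^2/us) diffuse on the postsynaptic membrane with radial
reflection at the PSD-disk boundary.

Receptor gating follows a six-state scheme — two sequential
glutamate-binding steps, one open state reachable only from the doubly
bound state, and a long-lived desensitized state off each bound state —
with rates shipped as an editable YAML config (transcribed from the
Jonas/Major/Sakmann hippocampal AMPAR model as reduced for Monte Carlo
use). For the configured association rates the Smoluchowski radius
k_on/(4πD) is ~4×10^-3 nm, i.e. binding is strongly reaction-limited
and a literal absorbing sphere of that radius can never be resolved by a
discrete walk. Binding is therefore implemented as a capture hemisphere
(radius 5 nm, configurable; a configuration error is raised if it
exceeds half the cleft) in which each molecule independently triggers
the binding step with probability `k_on_vol·dt / V_hemisphere`; averaged
over a Poisson number of in-range molecules this reproduces the
mass-action rate k_on·C *exactly*, which is what the master-equation
fidelity check pins down (well-mixed occupancies within 3 SE of the
independently integrated ODE at 10^4 receptors). Unimolecular
transitions use exact exponential leave probabilities with
rate-proportional branching, advanced in half-steps on either side of
the binding step (Strang splitting) so neither process systematically
pre-empts the other. Each receptor makes at most one binding transition
per dt; the double-transition probability within 1 us is O(10^-4).

Traces are averaged over `n_seeds` = 50 independent sub-seeded runs per
vesicle and configuration (10 ms at 1 us steps by default). Receptor
topographies: `random` seeds all receptors uniformly over the PSD disk;
`clustered` seeds 75 % (round-half-even) uniformly into the membrane
footprints of the PSD nanoclusters and the rest uniformly outside, all
free to diffuse across patch boundaries afterwards.

### Receptor topography comparison

The clustered-vs-random comparison rests on a translation-invariance
argument: with the total receptor count fixed, the *expected* peak
response averaged over uniformly placed vesicles is independent of the
receptor arrangement whenever (i) the response kernel does not vary
across the PSD and (ii) patch coverage is uniform over the PSD. Two
geometry artifacts break this in a naive disk model and were removed by
construction rather than calibration: an absorbing escape boundary at
the PSD rim starves rim receptors (hence the escape apron), and patch
centres confined to the disk interior over-cover the centre (hence the
overhang placement). With both in place, the simulated cohorts reproduce
the expected behaviour: no mean difference between configurations
(paired t), higher within-synapse coefficient of variation with
clustered receptors, and an enhancement index (clustered/random peak
ratio) that falls with vesicle-to-PSD-cluster distance (permutation
Spearman). The printed full-scale C.V. pair from the source study (0.38
clustered / 0.26 random) belongs to the deposited tomogram geometries
and is not reproduced here; the synthetic cohorts yield the same
ordering with magnitudes that depend on seed count and vesicle number.

## Statistics

Coefficient of variation uses the sample (n−1) SD over the mean (the
denominator convention is unstated in the source). The permutation
Spearman test permutes one variable 10,000 times, uses midranks for
ties, counts permutation ties toward p, and floors p at 1/n_perm. The
paired t test handles zero-variance differences per contract: all-zero
differences give p = 1, a constant nonzero difference is degenerate and
returned as the p → 0 limit for the caller to flag.

## Determinism and seeds

Every stochastic stage takes a seed; cohort runs derive per-stage,
per-item sub-seeds from the global seed through `SeedSequence` with a
CRC-based stage hash (logged in reports), so an identical configuration
reproduces byte-identical reports, and all derived seeds stay below
2^31.

## Problem sizes used in validation

The validation suites run scaled-down but structurally complete
problems, chosen as the package's own test design: oracle equivalence on
≤12^3 volumes and ≤20-point sets; calibration of the envelope test with
500 replicates of 6-vs-5 points at 200 simulations; nanocluster recovery
on 20 volumes (K = 2..8) at 2.72 nm voxels with an 11-voxel window
(≈30 nm, the published physical window); alignment power/null on 100
synthetic synapses each at 200 simulations; kinetics fidelity at 10^4
receptors for 3 ms; and the topography comparison on 10 synapses × 10
vesicles × 10 seeds at 5 ms (peaks occur within ~2 ms). The acceptance
script re-runs the same workflow at comparable sizes.

## Limitations

* The generator omits tomographic artifacts (missing wedge, CTF,
  denoising residues), membrane undulations beyond a spherical cap, and
  non-spherical vesicles; passing recovery tests show the detectors work
  on clean geometry at realistic SNR, not that they are robust to
  reconstruction artifacts.
* Membrane area by lateral footprint underestimates steeply inclined or
  highly curved membranes.
* The simulation flattens the cleft (curvature ignored), treats release
  as instantaneous, and omits NMDA receptors, transporters and fusion
  pore dynamics; escaped glutamate cannot re-enter.
* The kinetic rate set is a named, editable configuration; all
  rate-dependent results are defined relative to the configured scheme,
  not to absolute published values.
* The MAD test's plug-in spacing constraint inherits the mild
  anticonservatism of the published procedure discussed above.
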