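# Methods

`bnctcam` models in-vivo dosimetry imaging for Boron Neutron Capture Therapy
(BNCT): the 10B(n, alpha)7Li capture reaction leaves an excited 7Li recoil
that emits a 478 keV prompt gamma, so the spatial distribution of these
gammas traces the boron dose. A two-layer Compton camera observes them, and
the package implements the full desk-scale chain from photon emission to
segmentation scores.

## Simulation model

**Geometry.** Units are mm and keV; axes are right-handed with the camera on
+Z. The phantom is a solid cylinder (default 30 mm radius, 100 mm height)
approximating a mouse body. Its axis runs along **Y** — radius in the XZ
plane — so the detector can approach to one phantom radius (the closest
study distance, 30 mm) without entering tissue; nothing else in the
pipeline depends on this orientation choice. The
camera is two adjacent CZT layers, each 20 x 20 x 5 mm^3 (density
5.78 g/cm^3), face-centered on the Z axis; `distance` is measured from the
source center (the coordinate origin) to the front face of layer 1. The
layers touch by default (`layer_gap = 0`).

**Sources.** Either a sphere of 10 mm radius (tumor surrogate) or five
point emitters 6 mm apart. The five points are laid out as a cross in the
XY plane (center plus four points at +-6 mm on X and Y); only the spacing is
prescribed by the setup, the arrangement is this package's choice. All
gammas are emitted isotropically at 478 keV.

**T/N background.** In a treatment, healthy tissue also carries boron at a
tumor-to-healthy concentration ratio T/N. Emission rate is taken
proportional to boron concentration, so a gamma starts in the tumor with
probability `p_T = (T/N * V_tumor) / (T/N * V_tumor + V_healthy)` and
otherwise uniformly in the healthy cylinder volume. For the default
geometry, `V_healthy / V_tumor ~ 66`, so T/N = 2 means only ~3% of emitted
gammas are tumor gammas — the background regime the low-T/N studies probe.
Point-like sources have zero volume; using them with a finite T/N requires
an explicit `emission_volume`.

**Transport.** A photon survives its chord L through tissue with
probability `exp(-mu L)`; `mu = 0.0105 /mm` for soft tissue near 478 keV, 0
for air. Photons that would scatter inside the phantom are discarded rather
than tracked — consistent with the observation that tissue dispersion is
not appreciable at this energy — and no detector energy or position
blurring is applied (ideal detector). Detection is idealized by default:
every geometric layer-1 hit Compton-scatters exactly once (interaction
depth uniform along the chord through the 5 mm layer) and every geometric
layer-2 hit of the scattered ray photoabsorbs. A crude cross-section mode
(`idealized_detection=False`) instead accepts interactions with
`1 - exp(-chord/lambda_eff)` using effective CZT interaction lengths; it
changes efficiency, not image formation, and is off by default because only
*true events* (scatter in layer 1 + absorption in layer 2) are ever
reconstructed.

**Scattering angle.** The polar angle is rejection-sampled from the
Klein-Nishina differential cross-section at 478 keV (envelope = the forward
peak value); the azimuth is uniform. Energies then follow the Compton
formula `E2 = E / (1 + (E/511)(1 - cos theta))`, with a complement fix-up
iteration so that `e1 + e2 == 478.0` holds bit-exactly, as an ideal
detector implies.

**Determinism.** All randomness flows through one seeded generator, and all
per-photon draws are made in a fixed order *before* any geometric
acceptance test. Two consequences: identical configs give bit-identical
event lists, and runs differing only in phantom material consume identical
random streams, making the tissue run's true events an exact subset of the
air run's (attenuation only removes photons).

## Reconstruction

**Cones.** Each event defines a cone: apex at the layer-1 hit, axis from
the layer-2 hit toward the layer-1 hit, half-angle from
`cos theta = 1 - 511 (1/E2 - 1/E_gamma)`. Splits beyond the backscatter
limit `E2 < E_gamma / (1 + 2 E_gamma / 511) ~ 166.5 keV` are kinematically
forbidden and rejected as corrupt input.

**Grid.** All images live on a 100^3 grid over [-60, 60] mm per axis
(1.2 mm cubic voxels), evaluated at voxel centers only.

**Back-projection.** A voxel at angular residual `delta` from an event's
cone surface accumulates `exp(-delta^2 / (2 sigma_a^2))`. The angular
kernel width `sigma_a` (default 2 degrees) is the package's resolution
knob — a hard cone shell on a 1.2 mm grid would alias badly. Images are
max-normalized.

**List-mode MLEM.** The iterative update is the standard multiplicative
one: `lambda_j <- lambda_j / s_j * sum_i t_ij / (sum_k t_ik lambda_k)` over
the M measured events. The system matrix element `t_ij` is the same
Gaussian angular kernel (optionally damped by the inverse squared apex
distance), floored to 0 below 1e-12. Sensitivity `s_j` is uniform by
default — the sources of interest are small and near-axis — with a
solid-angle mode (exact rectangular-plate solid angle of the layer-1 face)
available. Initialization is a flat positive image; stopping is a fixed
iteration count (50 for routine images, 250 for the stretching analysis).
Forward projections below 1e-30 contribute nothing (0/0 guard).

*Implementation.* Enumerating cone-band voxels by scanning all 10^6 voxels
per event is wasteful; instead each (x, y) grid column is intersected with
the two boundary cones `delta = theta +- cutoff * sigma_a` (a quadratic in
z), and only segments whose midpoint lies in the band are visited. This is
exact — the residual is continuous in z, so it enters or leaves the band
only at a boundary root — and is verified against a brute-force dense
evaluation in the tests. The matrix is truncated at `cutoff_sigmas` (default
3, i.e. kernel values below ~1.1e-2 of peak are dropped) and stored as CSR,
float64 for small problems and float32 for large ones; iterations run in a
fused forward/back-projection numba kernel. At ~10^5 band voxels per event,
memory is the binding constraint (~1.2 GB per 1000 events), which sets the
study sizes below.

**Granularity.** MLEM pushed far past convergence concentrates intensity
into speckle. The package quantifies this as the coefficient of variation
of the intensity inside the source region of the central XY slice; it grows
monotonically with iterations and motivates stopping near 50.

## Profiles and the stretching study

Axis profiles through the origin come in two modes: the single central
voxel line, and the integrated projection (sum over the perpendicular
plane). **Projection is the default used by the studies**: at desk-scale
event counts the reconstruction is speckled, and a 1-voxel line through a
speckle field yields unstable Gaussian widths (fitted sigmas fluctuating by
factors of 2-3 between X and Y for an isotropic source), while the
projection is statistically robust. Gaussian fits use nonlinear least
squares initialized from the peak and half-width (A = max, mu = argmax,
sigma = HWHM/1.177, offset = min) with sigma bounded to (0.1, 120) mm.

The stretching study simulates the sphere at detector distances 30-100 mm,
reconstructs each with 250 iterations, and reports the fitted sigma_Z per
distance. The camera constrains the source transversally but poorly along
its own axis, and the angular aperture shrinks with distance, so sigma_Z
grows with distance while sigma_X does not — the basis for estimating
source depth from the image.

## Segmentation and scoring

Segmentation operates on the central XY slice of the back-projection image:
binarize (fixed fraction of the maximum, default 0.5, or Otsu), then cycles
of erosion/dilation with a configurable structuring element (3x3 square by
default). The truth mask is the geometric source projected on the slice
grid: the sphere becomes a ~10 mm disk (216 px), each point emitter a
single voxel. Scores are pixel counts:
`accuracy = 100 TP/(TP+FP)`, `sensitivity = 100 TP/(TP+FN)`.

The four benchmark scenarios (all detector at 60 mm) are: case1 sphere/air,
case2 sphere/tissue T/N=2, case3 sphere/tissue T/N=5, case4 five
points/air. Morphological filtering inherently needs per-case supervision,
and the per-case parameters in `CASE_MORPH_PARAMS` reflect that: the air
sphere separates at a 0.60 threshold with a mild opening; the T/N cases sit
on a strong healthy-tissue pedestal (background mean 0.54-0.60 of peak) and
need thresholds of 0.90-0.925 plus, for T/N=2, a deeper triple-erode/
triple-dilate opening; the five-point case merges into one blob at any
threshold, which is precisely its documented failure mode (sensitivity
100%, accuracy < 20%). The T/N cases also use 16000 events for the
back-projection (vs 4000 for the air cases) so that pedestal fluctuations
sit below threshold.

## Problem sizes

The studies are deliberately desk-scale; the sizes are stated here as the
package's own defaults:

- default generator target: ~2 x 10^4 true events (~5 x 10^6 emissions at
  60 mm in air);
- MLEM studies (localization, granularity, stretching, tissue comparison):
  800 true events, 250 iterations, snapshots every 50;
- T/N contrast runs: 1000 true events, 50 iterations;
- segmentation back-projections: 4000 events (air cases) / 16000 events
  (T/N cases).

These counts are one to two orders of magnitude below a full simulation
campaign. They are enough for every qualitative conclusion (localization to
~2 mm, speckle growth, stretching monotonicity, contrast ordering,
segmentation bands), but absolute fitted widths and scores carry a few
percent of statistical scatter, and MLEM speckle sets in earlier than it
would with more events.

## What the generator does and does not emulate

Emulated: true-event geometry and energetics, Klein-Nishina statistics,
solid-angle efficiency, exponential tissue attenuation, T/N emission
weighting, both source shapes. Not emulated: Doppler broadening, detector
energy/position resolution, in-phantom scatter that reaches the detector
(scatter background), random coincidences, neutron transport and boron
kinetics. Passing tests therefore validate the reconstruction and analysis
chain under ideal-detector assumptions, not detector hardware performance.

## Numerical choices and edge cases

- `m_e c^2 = 511.0 keV`; prompt gamma 478.0 keV.
- Kernel truncation at 3 sigma_a (band-edge weight exp(-4.5) ~ 1.1e-2);
  the 1e-12 floor applies inside the band too. The truncation is part of
  the stored matrix, and the small-grid oracle tests disable it to compare
  against the pure definition.
- Voxels coincident with a cone apex get weight 0 (undefined direction);
  solid-angle sensitivity clamps voxels at/behind the detector plane to the
  maximum finite value and floors at 1e-12 for division safety.
- Gaussian angular kernel everywhere (back-projection and t_ij share
  sigma_a): one knob, and smooth images on the 1.2 mm grid.
- The origin-containing voxel line/slice uses the voxel whose half-open
  interval contains 0 (index 50 on the default grid).
- CSV round trips are exact: event files use full float precision
  (`repr`), the 8-field image CSV stores intensity to float precision and
  indices exactly.

## Known limitations

- Uniform sensitivity is an approximation; it is accurate near the axis
  but overweights off-axis voxels in principle. The solid-angle mode
  exists but is not the study default.
- The morphological benchmark parameters are calibrated per case at the
  stated event counts and seeds; they are not expected to transfer to
  other statistics unchanged — which is the method's documented weakness
  (each case must be studied separately).
- At 800-1000 events the granularity onset is early; iteration counts in
  the studies should be read as positions on the speckle-growth curve, not
  as convergence claims.
- Five-point sources with finite T/N require an explicit emission volume.
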