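# Methods

`spivolve` implements a complete single-particle imaging (SPI) analysis
chain: from stacks of 2D photon-count diffraction frames recorded at an
X-ray free-electron laser to a 3D electron density with structure metrics
and a resolution estimate. Because experimental SPI data sets are not
generally redistributable, the package carries a first-class synthetic
data generator that emulates the statistical structure such an experiment
produces, and every stage is validated against it.

## Geometry and conventions

A single flat panel sits at distance `L` downstream of the interaction
region. A pixel at transverse offset `r` scatters at `2θ = atan(r/L)` and
maps to momentum transfer `|q| = (4π/λ) sin θ` (nm⁻¹); real-space
resolution is `d = 2π/q`. Photon energy converts to wavelength through
`λ = hc/E` with `hc = 1.239842 keV·nm`; 1.7 keV photons have λ = 0.729 nm.
Two pixel-to-q mappings are provided: the physically correct curved-Ewald
mapping (q vectors on the sphere through the origin; the default) and a
flattened variant with the same |q| and `q_z = 0`, useful for tests where
a frame should be an exact central cut. The beam center is stored in
fractional pixel units so sub-pixel refinement is representable. Dead
detector regions (e.g. the half panel of a two-panel detector with one
panel out) are expressed purely through a mask which every algorithm
honours.

Pattern stacks are HDF5 containers with a CXI-like tree
(`/entry/data/counts`, `/entry/geometry/*`, `/entry/mask`,
`/entry/annotations/*`); real-space densities are MRC/CCP4 maps (written
through gemmi, voxel size in the header); reciprocal-space volumes carry a
per-voxel validity flag and use a small HDF5 layout.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
tested:

- **Phantom.** A solid sphere or an icosahedral shell (flat facets from
  the 20 face planes, vertex-to-vertex outer diameter, shell of given
  thickness, interior filled at a fraction of the shell density — the
  default 0.4 emulates particles with reduced core density). Voxelization
  uses a half-voxel partial-volume ramp, so phantom volumes are accurate
  to well under a percent.
- **Rendering.** The diffraction volume is |FFT|² of the zero-padded
  phantom. The default 4× zero-padding is deliberate: trilinear slicing
  through a merely 2×-oversampled volume fills the sharp form-factor
  minima and destroys fringe contrast in the sampled frames.
- **Frames.** Each non-blank frame draws a uniformly random orientation
  (unit quaternion) and an apparent size from a truncated (±3.5σ)
  Gaussian jitter around the nominal diameter — size jitter stands in for
  hydration-layer and beam-focus variation, the two size-broadening
  causes the experiment exhibits; no separate hydration layer is
  modelled. Expected counts are `fluence_scale` × the interpolated Ewald
  slice, normalized so `fluence_scale` is the peak (central-speckle)
  photons per pixel of a noise-free hit; counts are Poisson. The default
  `fluence_scale = 2000` puts frames in the bright-hit regime with about
  six visible fringes, which the classification stage requires.
- **Corruption.** A configurable fraction of frames becomes
  multi-particle hits (incoherent sums of 2–3 single-particle frames),
  all frames gain a constant Poisson background (carrier-gas scattering),
  fixed per-pixel Gaussian baseline offsets with per-sample Gaussian
  readout noise (so the per-pixel zero-photon peak has finite width —
  the property the offset correction estimates), and the detector mask is
  applied. All randomness flows from one seed; identical configurations
  give bit-identical stacks.

What the generator does *not* model: atomistic structure, radiation
damage, pulse-duration effects, detector saturation, or structured
(non-constant) instrumental background. Passing tests therefore show the
algorithms are correct under idealized-but-realistic photon statistics,
not that they are robust to every artifact of beamline data.

## Preprocessing

*Hit finding* counts unmasked pixels at or above a lit threshold
(default 2 photons) and keeps frames with at least `min_lit_pixels`
(default 300, tuned on the generator's default conditions). A 1-photon
threshold was rejected: at realistic diffuse-background levels the
Poisson tail of blank frames dominates single-photon counts and no pixel
count separates hits from blanks.

*Per-pixel baseline correction* assumes each pixel's zero-photon value
distribution is Gaussian with mean zero. Values below 0.5 photon
equivalents isolate the zero-photon peak (excluding the 1-photon peak);
its mean and width are estimated with one trimming refinement pass, and
the fitted mean is subtracted — a pure per-pixel shift that cannot alter
relative frame differences.

*Beam-center refinement* maximizes the masked Pearson correlation between
the mean pattern and its point reflection (Friedel symmetry) over a
half-pixel search lattice with quadratic sub-pixel interpolation.

## Particle sizing

Each frame's azimuthally averaged profile (PSD) is fitted with the solid
sphere form factor `[3(sin qR − qR cos qR)/(qR)³]²` over diameters
30–300 nm (0.5 nm grid plus parabolic refinement), in log10 intensity
with the scale profiled out by a median offset. Bins carrying fewer than
5 photons are dropped and the model is floored per bin at the one-photon
counting level — measured minima cannot fall below counting statistics.
This makes the fit deliberately scale-*aware*: multiplying a PSD by a
constant changes which bins clear the floor, so scale invariance holds
only approximately (~1 nm).

The fidelity score is the goodness ratio of the best sphere fit over a
featureless least-squares power law: `FS = rmse_powerlaw / rmse_sphere`
on log10 intensity, with success requiring `FS > 1.05` strictly. (A
correlation ratio was considered and rejected: Pearson correlation
against a fitted power law is 0/0-degenerate on featureless profiles.)
Frames passing FS are filtered to the expected size window (55–84 nm by
default, inclusive).

For shell-like (virus) particles the solid-sphere model matches only the
first few fringes; the pipeline therefore fits in the low-q band
(default 0.06–0.2 nm⁻¹), where fringe spacing encodes the outer
diameter. Fitted sizes are biased a few nanometres below the
vertex-to-vertex diameter for icosahedral shells — expected, since the
equivalent sphere lies between the inscribed and circumscribed spheres.

## EM classification

Frames are resampled onto a polar grid about the beam center so an
in-plane rotation is a cyclic shift of the angle axis: the rotation group
acts exactly on the grid and the E-step reduces to matrix products.
Expectation-maximization over classes × in-plane rotations uses the
Poisson log-likelihood `Σ_t K_t log W_t − W_t` over valid polar pixels,
softmax responsibilities with class occupancies, and an M-step that
back-rotates responsibility-weighted frames (mask back-rotated
alongside). Class models carry an additive floor of 1e-10 inside logs;
convergence is a relative log-likelihood change below 1e-4; hard
assignments take the maximum responsibility with ties to the lowest
class id.

Class selection is by explicit id list (the expert-selection path). An
automatic helper — a heuristic not taken from any reference procedure —
proposes classes whose model's radial profile shows at least 3 fringe
pairs with visibility ≥ 0.2. Repeating the clustering from independent
seeds and intersecting the per-run frame selections gives the stable
single-hit set; intersection can only remove frames, so its precision is
never below the best single run's.

## Orientation recovery (EMC)

Expand–maximize–compress iterations assemble classified single hits into
a 3D intensity on a cubic grid whose center voxel is q = 0: Expand
extracts model slices on the (curved) Ewald surface at each rotation
sample by trilinear interpolation; Maximize computes per-frame Poisson
posteriors over rotations and accumulates posterior-weighted photons per
rotation; Compress scatters the tomograms back with the exact adjoint
trilinear weights and normalizes. Friedel symmetry is imposed after every
compress; voxels that never receive interpolation weight stay invalid.
Rotation samples come from the super-Fibonacci spiral (deterministic,
quasi-uniform); the mean orientation information of the posteriors (bits)
serves as the convergence diagnostic. The grid default (voxel ≈ 1/4 of
the fringe period) matters: coarser grids fill fringe minima at
insertion.

Grid sampling quantizes orientations to the cover's radius, which blurs
azimuthal structure at high |q|. A controlled experiment (inserting
frames at their *true* orientations) showed this quantization — not
interpolation, noise, or the downstream stages — limits the final
morphology at desk-scale rotation counts (≲ 2500). The package therefore
adds continuous per-frame refinement after EMC: starting from each
frame's maximum-posterior rotation, a simplex search maximizes the
Poisson likelihood over a local rotation perturbation (optionally jointly
with a per-frame log q-scale, which normalizes apparent-size jitter —
the diffraction of a particle scaled by `s` samples the reference at
`q·s`), and the volume is rebuilt by hard-assignment insertion. This is
the SPI analogue of local angular refinement in cryo-EM.

## Background and contrast

The constant background is the mean of the valid voxels in a high-q
window (default: the outermost 10% of the valid q range, presumed free of
particle scattering; configurable). Subtraction clips negatives to zero,
and the band outside `[q_low, q_high]` (defaults 0.12–0.93 nm⁻¹,
configurable) is invalidated; the central invalid ball is the gap the
phasing stage must handle. Fringe visibility is
`γ_i = (P_max,i − P_min,i)/(P_max,i + P_min,i)` for each PSD local
maximum and the following minimum (extrema of the 3-bin-median-smoothed
profile, boundary samples excluded), averaged over the first N = 6 pairs.

## Phase retrieval

Classic alternating projections on the centered grid: the Fourier
projection imposes √intensity on valid voxels and leaves invalid voxels
free; real space alternates hybrid input-output (feedback β = 0.9) and
error reduction, with shrink-wrap support re-estimation (Gaussian blur
σ = 1.5 voxels, threshold 0.2 of the blurred maximum) at a configurable
interval. The field is complex by default; an optional `real_positive`
constraint projects onto real non-negative values inside the support —
appropriate for a real electron density, and necessary in practice when
the magnitudes carry reconstruction error (below). Divergent runs are
flagged, not discarded. Richardson–Lucy deconvolution with a periodic
Gaussian kernel (non-negativity- and flux-preserving) is available for
contrast enhancement of profiles or volumes, with the kernel width chosen
by maximizing ⟨γ⟩ when requested.

**Central gap.** The spec'd free-evolution fill (runs with the gap
unconstrained, gap replaced by the mean model intensity) reproduces the
gap well for solid particles, but for shell particles with a reduced core
the band data do not constrain the total-density (DC) term: free complex
fills settle at a fraction of the true central speckle while remaining
mutually consistent — agreement among runs is not evidence of
correctness here. The pipeline therefore uses an anchored two-stage
scheme: (1) fill the gap with the solid-sphere form-factor extrapolation
of the *fitted particle size*, level-matched at the innermost measured
shell; (2) phase a first ensemble; (3) re-fill the gap from that
ensemble's mean model intensity (restoring the particle's own
non-spherical speckle); (4) phase the final ensemble. Multi-start
ensembles resolve the trivial ambiguities against the lowest-residual
run: conjugate-inversion twin by correlation, translation to sub-voxel
precision by upsampled phase cross-correlation, global phase by inner
product.

## Modes and metrics

The ensemble density matrix ρ(r,r′) = ⟨ρ(r)ρ*(r′)⟩ is eigendecomposed
through the n×n Gram matrix of the aligned fields (snapshot method,
verified against the explicitly formed density matrix); normalized
eigenvalues β_n are the mode weights and a dominant β₀ indicates the
retrievals agree. The consensus density is |mode₀|, normalized to max 1
and band-limited upsampled (Nyquist-split zero-padding, exact on the
original samples). An optional error-reduction polish of the consensus
against the measured magnitudes restores edge sharpness the ensemble
average blurs.

Sizes are measured at the 0.2 iso-level of the normalized density: along
each axis through the density-weighted centroid, the size is the distance
between the outermost threshold crossings. Vertex (6) and facet (10)
axis families are auto-detected by template-matching the support's
directional extent against a regular icosahedron's support function over
a rotation search — far more robust on imperfect densities than picking
extremal directions, and reducing to an arbitrary (harmless) orientation
for near-spherical supports. Elongation is α = 100·(D_max − D_min)/D_mean
per family. Capsid thickness is the mean FWHM (2√(2 ln 2)·σ) of Gaussian
fits to the outermost radial shell peak over a direction fan; profiles
whose peak does not stand out from the interior plateau are rejected.

Resolution uses Fourier shell correlation between densities from
independent odd/even half-dataset reconstructions, with the half-bit
threshold `T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)` at
Friedel-halved independent sample counts and linear interpolation at the
first downward crossing. (Note the formula reaches its asymptote slowly:
T(10⁶) = 0.1730, still 1.5·10⁻³ above the n→∞ limit 0.1716.)

## Pipeline, determinism, and problem sizes

The `spivolve run` pipeline executes simulate → preprocess → sizing →
EM classification → EMC (+ refinement) → background → phasing → modes &
metrics from one YAML configuration, records every stage's seed, counts
and parameter digest in a manifest, and resumes from intact outputs on
re-run. Every stochastic stage derives its generator from the master
seed, so identical configurations reproduce all artifacts bit-identically
on one platform.

Default desk-scale problem sizes (the package's own choice of test
conditions): a 64×64-pixel panel of 150 µm pixels at 0.075 m (a 2×2
binning of a pnCCD-style half panel, covering q ≤ 0.77 nm⁻¹), 450 frames
of a 70 nm icosahedral-shell phantom with 10% multi-particle and 10%
blank frames, 72³ reciprocal grids, 700 rotation samples with 3
refinement passes, and 6 + 8 phase retrievals. A full pipeline run takes
a few minutes on one CPU.

## Known limitations

- At the default desk scale the end-to-end reconstruction slightly
  rounds the icosahedral morphology: measured vertex sizes come out
  4–8% low (tips erode below the 0.2 iso-level) and the vertex/facet
  ratio compresses to ≈ 1.13–1.15 versus ≈ 1.2 for the ideal phantom
  measured the same way. Controls that bypass orientation recovery
  (phasing the true intensity, or inserting frames at true orientations)
  recover 68–69 nm vertices and ratios of 1.19–1.21 with the identical
  downstream code, isolating residual grid-EMC orientation error as the
  cause; production EMC implementations address this with one to two
  orders of magnitude more rotation samples than the desk-scale defaults
  use. The real experiment shows the same signature (a 63 nm measured
  vertex size for a nominally ~70 nm virus).
- The fidelity score and the automatic class-selection rule are
  documented stand-ins for procedures whose original definitions are not
  public; both are config-exposed.
- The free-evolution gap fill is unreliable for shell particles (DC
  ambiguity, see above); prefer the anchored scheme whenever a size
  estimate exists.
- Orientation refinement assumes single-particle frames; multi-particle
  hits that survive classification degrade the volume as an incoherent
  haze rather than being modelled.
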