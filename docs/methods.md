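# Methods

`gfb3d` re-creates, on synthetic data, the quantitative chain of a multiscale
3D electron-microscopy study of the glomerular filtration barrier (GFB):
tilt-series acquisition and weighted back-projection (WBP) of a thick
section, beam-shrinkage estimation from gold fiducials, autocorrelation-based
glycocalyx fibre-spacing estimation, and stain segmentation with
urinary-space morphometry.  No real image volumes are available, so every
stage runs on phantoms whose ground truth is retained; what the tests
demonstrate is therefore the *internal consistency* of the chain — that each
estimator recovers the generator's truth under the stated imaging model —
not the biological accuracy of any number.

## Coordinate and unit conventions

All volumes are scalar grids indexed `(z, y, x)`, 0-based, voxel-centre
coordinates, with per-axis voxel sizes in nanometres.  The electron beam at
zero tilt runs along z; tilt axis 0 is y, tilt axis 1 is x.  MRC2014 is the
interchange format (cell dimensions in Angstrom are converted on read);
missing pixel-size metadata is an error, never a silent default.

## The phantom family

**Layered GFB section.**  Along z: capillary lumen, glycocalyx slab,
fenestrated endothelium, basement membrane (GBM), podocyte foot processes
with filtration slits.  Intensities emulate inverted backscatter / stained
TEM contrast (stain 200, membranes 130, cytoplasm 100, resin and lumen 50,
arbitrary units).  The glycocalyx is a fibre matrix: quasi-parallel cylinders
along the membrane normal (z), tilt-jittered with a half-Gaussian of 5°
clipped at 15°, radius 3 nm.  Stained-fibre radius and
orientation spread are package defaults, chosen so a reconstruction
slice cuts the fibre forest transversely.

**Fibre positions.**  Fibre base points follow a Poisson hard-core
(dart-throwing) process.  The exclusion radius is `r0 = d (1 − 1.5 cv)` and
the point count is calibrated numerically (up to ten redraws) until the
empirical mean nearest-neighbour (NN) distance matches the requested spacing
`d` within 0.5%.  Ground truth for `d` is the mean centre-to-centre NN
distance.  A jittered lattice was rejected: at cv = 0.2 its pair-correlation
peak (what the autocorrelation estimator measures) sits 10–12% above the
mean NN distance, because the NN distance is a minimum over four jittered
neighbours.  The hard-core process keeps the correlation peak close to the
mean NN distance; its realised NN coefficient of variation is ≈ 0.24 at the
default `cv = 0.2` and has no long-range lattice order.

**Defaults as study conditions.**  Fibre spacing 20 nm, cv 0.2, glycocalyx
thickness 120 nm (within the 100–400 nm range the staining reveals;
tomography-scale coverage is 100–200 nm), fenestration diameter 60 nm at
130 nm pitch, slit width 40 nm.  The default section is 128 × 160 × 160
voxels at 1.5 nm — a 192 nm-thick, 240 nm-wide field.  The real sections are
300 nm thick with micrometre fields; the scaled size keeps a dual-axis
1°-increment study tractable on one CPU while leaving > 6 fibre spacings per
analysis window.  The headline spacing analysis widens the field to
224 × 224 pixels and pools two independent sections (~400 fibres), because
the dominant uncertainty of a per-section spacing estimate is the finite
fibre realisation, not the per-window noise.  Section thickness must NOT be
scaled down aggressively: the missing-wedge streak artefacts of a fibre of
length L land laterally at ~tan(30°) · L/2, and for sections thinner than
~150 nm they fall straight into the 10–30 nm analysis band and lock the
estimate to a geometry artefact.

**Noise model.**  Projections receive Poisson shot noise with expected
counts `intensity × 0.05 × dose_rate × exposure(θ)` (≈ 1000 counts per pixel
at typical path lengths, a realistic CCD dose) plus additive Gaussian read
noise (σ = 5).  Phantom volumes themselves carry only the Gaussian term.

**Fiducials.**  10 nm gold beads rendered as antialiased spheres of
intensity 2 × 10⁴ (gold is far denser than stained resin), centred half a
diameter inside each surface, ≥ 2 diameters apart in plane, kept away from
the lateral edges so that beads remain in the field at 45° tilt.

**Urinary-space phantom.**  Each requested sub-podocyte space (SPS) is a
cavity under a podocyte body sitting on the GBM, opened to a shared exterior
urinary space through a wall aperture whose z-height is the requested exit
width (the adjacent cavity column is flared when the exit is taller than the
cavity, mirroring exits "approximately the same as the height of the SPS").
Sealed spaces (exit 0) are voxel-disconnected from the exterior.

## Tomography model

**Exposure.**  `t(θ) = t0 + k (sec θ − 1)` with `k` chosen so the extreme
angle receives the configured maximum — the secant is the section thickness
factor along the beam.  Defaults 2.0 s at 0°, 3.2 s at ±60°.

**Projection.**  Parallel-beam line integrals by trilinear resampling
(`scipy.ndimage.affine_transform`) with the beam axis enlarged so no mass is
clipped while rotating; the detector keeps the in-plane grid, so content near
the lateral field edge can leave the detector at high tilt, as in a real
camera.  Nearest-neighbour interpolation is available for exact small-case
oracles.  Dose-dependent shrinkage enters as a linear z-scale in cumulative
exposure, composed into the same affine map.

**WBP.**  Each projection is ramp-filtered along the detector direction with
a raised-cosine roll-off starting at 0.9 of Nyquist (the standard choice of
weighting for back-projection), then
smeared along its beam direction with bilinear detector interpolation and
summed over angles with a Δθ weight.  An unfiltered mode exists solely for
the direct-sum oracle test.  Dual-axis combination works in 3D frequency
space: each reconstruction's sampled wedge (`atan2(|k_z|, |k_inplane|) ≤
θ_max`) is read from the reconstruction metadata; exclusive regions take the
covering axis, all other regions average the two.  The operation is
symmetric and idempotent.

**What the missing wedge destroys.**  Structure that varies only along z
(the layer profile) lives on the k_z axis, inside the pyramid that *neither*
tilt axis samples: it is unrecoverable by any ±60° acquisition.  The
noiseless end-to-end fidelity property is therefore asserted on the
in-plane structure (voxelwise correlation > 0.8 inside the section after
removing per-slice means; measured 0.89), which is what the downstream
spacing analysis consumes.  The depth-resolution bookkeeping
`z_res = xy_res × dual_tilt_factor × (1 + s)` reproduces the printed
1.8 × 2 × 1.25 = 4.5 nm; the alternative `/(1 − s)` convention (giving
4.8 nm) is implemented but not the default, because the multiplicative form
matches the printed arithmetic.

## Shrinkage estimation

The pre-shrink protocol: 60 one-second exposures at a fixed 45° tilt, the
section thinning linearly in cumulative exposure to 75% of its thickness.
Beads are localised per frame by an iterative intensity-weighted centroid on
a Gaussian-high-passed image (≤ 0.15 px error on noiseless frames), linked
by gated nearest-neighbour matching, and assigned to surfaces by the sign of
their displacement along the tilt direction — top- and bottom-surface beads
drift in opposite senses as the section thins.  With zero shrinkage there is
no movement and the assignment is genuinely undetermined; tracks are then
labelled `unknown` and surface labels must come from ground truth.

Top/bottom beads are paired by nearest in-plane neighbour after
de-projecting the image x coordinate (the two surfaces are offset by
`±(t/2) sin θ` in the image).  The estimate aggregates as a ratio of means,
`s = mean(sep₀ − sep₁) / mean(sep₀)`: the per-pair in-plane offset cancels
exactly in the numerator and averages out in the denominator.  Averaging
per-pair ratios instead would inflate `s` by ~6–7% relative (a Jensen
effect), which simulation shows breaks ±0.02 recovery at 20 beads per
surface.  `original thickness = mean(sep₀)/sin θ`; the standard error comes
from the per-pair scatter.

## Fibre-spacing estimation

Windows of 150 × 150 nm are taken on a fixed in-plane grid, emitted for
every reconstruction slice in which ≥ 80% of the window carries the
glycocalyx label.  Each window is tapered to its mean by a raised-cosine
over the outer 10% of each edge, mean-subtracted, zero-padded ×2, and
autocorrelated through the power spectrum; the map is normalised to 1 at
zero lag.  The radial profile averages the map within ±15° of the
membrane-parallel direction (folded over ±r); in this en-face geometry the
membrane-parallel plane is the slice plane itself and the direction defaults
to x.  Profile curvature is the central second difference of the 3-bin
moving-average-smoothed profile; peaks are local maxima with negative
curvature, refined to sub-bin positions by parabolic interpolation.

**Correlogram corrections.**  Three standard refinements proved necessary
on full-pipeline tests.  (1) *Slice-block averaging*: consecutive
reconstruction slices of one window position see the same fibres under
independent noise, so correlation profiles are averaged over blocks of 16
slices before peak detection; per-slice profiles at these fibre densities
are pair-shot-noise dominated and their first peak is unstable.  (2) *Noise
autocovariance subtraction*: the autocovariance of ramp-filtered
reconstruction noise is a deterministic function (sharp zero-lag peak,
negative ring at 5–12 nm) that does not average out and distorts exactly the
15–20 nm peak region; the mean absolute profile of the blank-reconstruction
windows estimates it and is subtracted from tissue profiles.  (3) *Unbiased
correlogram*: profiles are divided by the taper window's own autocorrelation,
removing the geometric droop that otherwise drags peak positions down, more
strongly for larger spacings.  The peak search is capped at one third of the
window side — a 150 nm window supports at least three repeats only up to
50 nm — and at lags above 8 nm (≈ 2× the corrected depth resolution), where
the filter's noise ringing ends.

**Acceptance threshold.**  Calibrated on control (blank resin) windows that
have passed through the *same* acquisition and reconstruction as the tissue,
block-averaged the same way, so the control noise carries the
reconstruction's correlation structure.  The threshold is the 95th
percentile of the per-window maximum curvature magnitude — per-window maxima
rather than pooled candidates, so that at most ~5% of blank windows can
yield any accepted peak by construction.  Curvature is compared in absolute
covariance units (normalised curvature × window intensity variance): in
normalised units a blank threshold is scale-free and rejects nearly all
tissue peaks, because blank windows are normalised by a tiny variance.  The
absolute form acts as a noise floor, and the estimator remains exactly
invariant to global intensity scaling and offset because threshold and
windows scale together.

**Aggregation and validity regime.**  A window's predominant spacing is its
smallest accepted peak radius; the headline statistic is the mean of
predominant spacings over contributing windows (the mean over all accepted
peaks is also exposed).  Recovery on full dual-axis reconstructions is
within 10% for spacings of 15–30 nm provided the fibre diameter stays below
roughly 0.3× the spacing: the correlation peak rides on the fibre's own
autocorrelation, and a 6 nm-wide fibre at 15 nm spacing smears the
hard-core rise upward by ~15% even on noiseless data.  The recovery sweep
therefore scales the phantom fibre radius as min(3 nm, 0.15 d).  The
residual few-percent bias at d = 20 nm reflects the gap between the
pair-correlation mode and the mean NN distance of a disordered process and
is reported, not corrected.

## Segmentation and morphometry

Backscatter inversion is `min + max − I` (involutive).  Stain thresholding
is global Otsu (bimodal content) or a fixed level; on the five-level phantom
the stain is isolated by a fixed level midway between the membrane and stain
intensities (Dice ≥ 0.95 at default noise).  Connected components use 26- or
6-connectivity (26 default: filtrate paths are tortuous and corner
connections count), labelled in decreasing size.  Thickness maps walk each
surface-normal column: unstained gap first, then the contiguous stained run.
Exit widths are the largest inscribed-circle diameter of the exit interface
patch (Euclidean distance transform with anisotropic sampling), which is
exact for even apertures and at most one voxel high for odd ones; length is
the longest in-plane bounding-box extent; depth the median per-column z
extent — median rather than mean for robustness to the flared exit column.
SPS coverage casts rays along the barrier-surface normal and takes the
fraction whose first urinary-space label is SPS.

## Problem sizes

The default test and acceptance runs use scaled geometries chosen as the
package's own study design: dual-axis series at 2° increments for recovery
sweeps and 1° for the headline run, 48–128-slice sections, and two
independent 504 nm-field sections pooled for the headline spacing estimate
(realisation scatter of a single-section mean is ≈ 0.5 nm; pooling two
sections brings the per-run spread comfortably inside the 10% contract).
The shrinkage sweep uses 12-exposure series (the estimator uses the first
and last frames); the printed-protocol 60-exposure series is used for the
headline shrinkage number.

## Known limitations

- No CTF, no alignment errors, planar membranes only; beam damage is a
  single linear z-shrinkage, not a physical model.
- The phantom's contrast model is piecewise-constant with simple noise; real
  LaDy GAGa contrast is graded and spatially correlated.
- The spacing estimator's accuracy statement is tied to the phantom's fibre
  process; on patterns whose correlation mode differs strongly from the mean
  NN spacing (strong lattices, fractal clustering) the mean-NN ground truth
  and the estimate will diverge.
- Shrinkage is estimated along z only; lateral anisotropy is out of scope.
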