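# Methods

`rodspt` implements the computational analysis of single-molecule tracking
data in rod-shaped bacteria: where molecules sit in the cell (membrane vs
cytoplasm), how fast they move, whether they cluster, and how quickly the
mRNAs they act on decay. Because raw microscopy movies are large and
instrument-specific, the package ships a synthetic-data generator with known
ground truth; every analysis stage is validated by parameter recovery
against it.

## Coordinate normalization (spotNorm)

A rod cell is described by its outline polygon, a pole-to-pole centerline,
length L and half-width R (from bright-field segmentation, in pixels). A
localization (x, y) is projected onto the centerline; the arc-length
position divided by L gives yNorm ∈ [0, 1], and the signed perpendicular
distance divided by R gives xNorm ∈ [−1, 1], with the sign taken from the
cross product of the local tangent with the offset (positive = left of the
direction of increasing yNorm; the convention is arbitrary since only
|xNorm| is modeled). Spots outside all cell outlines are discarded; a rigid
per-movie shift between outlines and fluorescence (mean over cells of
outline-center minus spot-centroid, applied only above 0.5 px) corrects
stage drift between the bright-field exposure and tracking.

Only the cylindrical mid-region R < y < L − R enters the transverse
analysis; hemispherical endcaps would distort the projection. Histograms of
|xNorm| use bin width 0.04. Each track contributes only localizations from
its first 4 frames, and tracks shorter than 4 localizations are dropped
(the tracking step guarantees a 4-frame minimum). Two details matter and
were found by recovery testing:

* short track fragments caused by detection flicker near the focal cutoff
  must be discarded, or molecules near the cutoff depth are over-counted;
* the first-frames rule must select by the track's frame span, not "the
  first 4 surviving spots": a spot rejected at the cell boundary is lost,
  which preserves the per-localization boundary truncation the projection
  model assumes. Replacing it with a later spot piles mass into the
  outermost bin and inflates the fitted membrane fraction by ~2 points.

Spots with |xNorm| > 1 (noise past the boundary) are rejected, never
clipped — clipping would concentrate mass at the membrane bin. The
bootstrap SEM resamples tracks, not spots, respecting the 4-points-per-track
dependence.

## Projected mixture model and MB%

In the circular cross-section of radius r, a molecule on the membrane
projects onto the transverse axis with the arcsine density 1/(π√(r²−x²));
one uniform in the disk projects with the semicircle density
2√(r²−x²)/(πr²). The observed density is the mixture
m·P_memb + (1−m)·P_cyto — m is the membrane-bound percentage (MB%) — with
two imaging distortions:

* defocus: signal below depth −f is lost; density at depth z is weighted by
  Φ((f+z)/σ) (both ±z branches for the membrane; integrated over depth for
  the cytoplasm);
* localization blur: convolution with a Gaussian of width σ in x.

Parameters are tied to bright-field geometry: r = R/dilF (dilF ≥ 1, the
fluorescent label sits inside the detected boundary), f = R − fCut (fCut = 0
when the view is unobstructed), σ = locErr/1000 µm with locErr in nm. The
axial (z) softness of the defocus edge is taken equal to the localization
error — the same assumption under which the weight Φ((f+z)/σ) is derived.
The cytoplasmic defocus integral uses the depth-dependent integrand
Φ((f+u)/σ); the depth-independent variant is available as `eq9_literal`
for comparison (the two differ by up to a few 10⁻⁴ per bin).

Numerics: per-grid-cell masses with exact arcsine/semicircle antiderivatives
(the arcsine edge singularity is integrable and handled in closed form),
grid step R/400 (halving the step changes bin probabilities by < 10⁻⁴),
blur as a mass-preserving discrete convolution, and conditioning on
|x| ≤ R with per-component renormalization — the mirror of the pipeline's
rejection of out-of-bounds spots. Both components are therefore observed
(post-detection) distributions, and m is the mixture weight of the observed
histogram; with the default generator the observed and true membrane
fractions differ by ≲ 1 point.

### MCMC fit

The absolute-xNorm histogram (25 bins) is fit with a Gaussian error model
on bin probabilities whose observation variance is itself sampled — a
conjugate inverse-gamma refresh around the mean-squared-error objective —
with uniform priors on intuitive bounds: m ∈ [0,1], dilF ∈ [1, 1.6],
locErr ∈ [0, 80] nm, fCut ∈ [0, R]. Two numerical choices matter, both
driven by the shape of the least-squares landscape, which has a narrow
global basin beside a broad shallow (m, locErr, fCut) plateau:

* the chain is initialized at the global optimum found by a Sobol scan
  with multistart Nelder–Mead refinement (population optimizers and
  locally initialized chains are reliably captured by the plateau);
* the variance prior is informative, anchored at the histogram's measured
  sampling scale — the bootstrap SEM when available, else the multinomial
  variance from n_spots — with 20·n_bins pseudo-observations. The
  bootstrap estimates that scale to a few percent, so the anchor encodes
  real knowledge; a freely floating scale inflates under misfit until the
  plateau outweighs the basin by sheer prior volume.

The sampler is an adaptive random-walk Metropolis chain (proposal
covariance re-estimated from the history every 200 steps, scaled by
2.4²/d), 20 000 steps with 10% burn-in. MB% is the posterior mean of 100·m
with a central 95% credible interval; convergence is checked by a
split-chain diagnostic on m (threshold 1.05) and the acceptance rate is
flagged outside [5%, 95%].

## Diffusion

Per track (≥ 12 frames), the time-averaged MSD over overlapping windows is
fitted by ordinary least squares over its first three lags with
MSD = 4Dτ + b, where b = −4DΔt/3 + 4σ² combines the dynamic error from
motion blur during the exposure and the static localization error. Negative
fitted D are retained (truncation would bias ensemble means); results are
reported as mean ± SEM over tracks. D histograms can be decomposed into one
or two Gaussian populations (density-normalized, Freedman–Diaconis bins),
optionally fixing the slow-population fraction to an independently measured
MB%. The maximum linking radius for track building is
ceil(2√(4·D₅pix·Δt)/pixel) pixels, which switches 1→2 at 0.0737 µm²/s and
2→3 at 0.295 µm²/s for Δt = 21.7 ms and 160 nm pixels.

A geometric caveat: lateral diffusion on the curved membrane surface,
projected to the imaging plane, has an apparent short-lag D of ~0.75·D
(the transverse component is compressed by the projection, E[sin²θ] = ½).
Estimator validation therefore uses unconfined planar tracks
(`simulate_free_tracks`), which isolate the estimator from geometry.

## Clustering

Per cell, Ripley's K̂(r) = A/(n(n−1))·Σ 1(d_ij ≤ r) with A the projected
spherocylinder footprint, L(r) = √(K/π), H(r) = L(r) − r. No analytic edge
correction is applied: the null reference is complete spatial randomness
simulated on the same cell — points uniform by area on the 3D
spherocylinder surface (cylinder wall + hemispherical caps), projected to
2D — so edge and projection effects cancel in H_data − H_CSR. The per-cell
readout is the trapezoidal integral of that difference over r (default
grid: R/50 to R in 50 steps; 20 CSR replicates), positive under clustering;
the spread of the replicate null integrals calibrates its null scale. Cells
need ≥ 300 spots (configurable).

## Decay kinetics

mRNA time courses are fitted by log-linear least squares of ln(abundance)
against time inside two windows — [150, 210] s (co-transcriptional rate
k_d1) and [300, 600] s (post-transcriptional k_d2), edges inclusive, both
exposed as options — giving one rate per replicate; strains are summarized
as mean ± SD and compared with a pooled-variance two-sample t-test
(two-tailed default, left-tailed option, 5% level; degenerate zero-variance
input returns p = 1 for equal means).

## Synthetic data: what it emulates, and what it does not

Cells are straight, axis-aligned spherocylinders (length and half-width
truncated-normal; defaults 3.0 ± 0.5 µm and 0.45 ± 0.03 µm, typical of
exponential-phase rods), emitted as ≥ 40-vertex outlines in 160 nm pixels.
The emitted outline plays the role of a bright-field segmentation and is
dilated relative to the physical membrane by `dilF_true` (default 1.15):
bright-field boundaries enclose the fluorescently labeled membrane, which
is exactly what the model's dilF parameter describes, and placing the
true dilation inside the prior range [1, 1.6] rather than on its boundary
keeps the fit well identified. Each molecule is membrane-bound with
probability `m_true` (default 0.93) diffusing laterally on the cylinder
wall (radius R_outline/dilF_true) in the flattened (arc-length, axial)
chart at `D_mem` (default 0.0184 µm²/s), reflecting at the cap junctions,
or cytoplasmic at `D_cyto` (default 0.09 µm²/s, ~5× faster) diffusing in
3D with specular reflection at the membrane. Frames are
21.7 ms; the recorded position is the mean of 10 substep positions (motion
blur) plus 20 nm isotropic localization noise; a frame is detected with
probability Φ((f_depth + z̄)/σ_z) (defaults f_depth = 0.35 µm from the
midplane, σ_z = 20 nm, matching the analysis model's assumption that the
defocus softness is set by the localization error); undetected frames split
records into separate tracks, as gap-free tracking would. Track lifetimes
are geometric via a per-frame bleaching probability (default 0.125, mean
8 frames). Decay curves are piecewise exponentials, continuous at a 255 s
junction between the two rate regimes, with mean-one lognormal noise
(CV 0.1, qPCR-like).

Not emulated: camera noise (localization error is the abstraction),
blinking, curved cells, nucleoid exclusion, z-dependent localization
precision, and polymerase-dependent early decay kinetics. Passing recovery
tests therefore show the estimators are correct under the model's own
assumptions, not that real data satisfy them. One real-data feature the
generator does reproduce — detection flicker near the focal cutoff,
correlated over consecutive frames — is not representable by the static
projection model, and it enters the histogram through the first-frames
rule in two ways. First, a track's first frame is conditioned on the
molecule (re-)crossing the detection boundary, so run starts oversample
positions near the focal cutoff depth; second, fast-diffusing molecules
rarely sustain the four consecutive detections a track requires, so deep
positions are suppressed beyond the per-frame defocus weight. Both are
properties of any tracking pipeline with a minimum track length and no
gap closing — real data included — and neither can be expressed by the
model's static per-localization weight. Their net effect here is a
systematic MB% bias of about −2 points for mostly membrane-bound data,
and an apparent membrane component of roughly 10% for purely cytoplasmic
data (measured cytoplasmic controls in real experiments likewise report
small nonzero MB%). Because the bias is systematic, 95% credible
intervals — which quantify only within-dataset sampling uncertainty —
cover the true simulation value in fewer than 95% of replicate
simulations; the package reports the interval as defined rather than
inflating it.

## Problem sizes

Recovery suites use 200 cells × ~500 localizations (≈ 10⁵ spots) per
dataset for MB%, 3–8 × 10³ tracks for diffusion, 10⁴ points per pattern
with 20 CSR replicates for the clustering null, and 3 replicates × 43 time
points for decay — sizes at which every recovery tolerance is several
standard errors wide.
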