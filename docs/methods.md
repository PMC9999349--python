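# Methods

This note records the models, estimators and numerical choices behind
`macnet`, the assumptions they rest on, and what validation on the
synthetic generator does and does not demonstrate about real data.

## Coordinate and unit conventions

Images are row-major 2D arrays. The physical origin sits at the center
of the top-left pixel; x increases rightward (columns), y downward
(rows). Lengths are micrometers, times seconds. Orientation angles are
measured from the +x axis in radians and are π-periodic in [0, π)
wherever they describe filament or nematic direction (a filament has no
head or tail).

## Synthetic micrograph generator (`synthgen`)

The generator emulates a quasi-2D network of fluorescent actin
filaments bound to a supported lipid bilayer, imaged in epifluorescence.

**Geometry.** Filaments are straight segments by default: the
persistence length of actin (~10–17 µm) exceeds the default filament
length (8 ± 2 µm) at this field of view, so curvature within one
filament is a second-order effect. An optional worm-like-chain mode
(`wlc_persistence_um`) adds tangent-angle diffusion with variance
ds/ℓp per arc step for studies of flexible polymers; it is off by
default. Filament centers are uniform over the field; segments are
clipped at the borders (Liang–Barsky).

**Orientation statistics.** The field is tiled into Voronoi director
domains (`n_director_domains` seed points, each with a director angle,
optionally pinned via `domain_directors`). A filament's orientation is
drawn by sampling 2θ from a von Mises law centered on the doubled
domain director with concentration κ and halving — the standard
π-periodic wrapped construction that respects nematic (headless)
symmetry. κ = 0 yields orientations exactly uniform on [0, π); large κ
collapses onto the director. The truth record stores the analytic order
parameter ⟨cos 2(θ − director)⟩ of the sampled angles, which the
order-estimation tests use as their recovery target.

**Rendering.** Each filament contributes a ridge whose intensity is a
Gaussian of the perpendicular distance to the segment with SD
`psf_sigma_um` (the line-spread function) and peak amplitude
`line_amplitude × multiplicity`; contributions add. Evaluation is
truncated at 6σ, keeping the truncation error below 10⁻⁶ of the peak.
Bundles are rendered as intensity multiplicity on a single centerline
rather than as resolvable parallel filaments, matching how the bundling
factor reads intensity at skeleton pixels; diffraction-limited imaging
cannot separate bundled filaments anyway.

**Noise model.** Shot noise is Poisson on (signal + background), then
additive Gaussian read noise, then clipping at zero — the standard
sCMOS camera model, in that order.

**Ground-truth crossings.** Node coordinates are the exact pairwise
segment intersections (cross-product solve per segment pair); the test
suite checks them against an independent computational-geometry oracle.

**Contraction series.** Aster-driven flow is kinematic, not
force-based: the analysis pipeline needs realistic flow signatures, not
mechanics. Filament vertices within `capture_radius_um` of the nearest
aster move toward it at `v0_um_per_s` (with overshoot clamped at the
center); in `partial` mode only the left image half moves; `none`
imposes no flow. Integrated fluorescence per filament is conserved as
it compacts: a ridge of length L and peak W integrates to
W(√(2π)·σ·L + 2πσ²) (straight section plus end caps), so the peak
amplitude is rescaled by the ratio of the original to the current
integral factor. Without this, converging vertices would delete label
from the image; with it, total intensity is conserved to < 1% once
border-clipped tails have entered the field (the first movement step
pulls previously off-grid ridge tails of border filaments onto the
grid, a border-clipping effect of ~1%). The myosin channel accumulates
Gaussian puncta (SD 2× the line spread) around each aster at a Poisson
rate per frame; photobleaching multiplies both channels by
(1 − bleach_rate) per frame.

**Canonical scenarios.** `contraction_scenario(mode, seed)` fixes the
study conditions used by the classification suite: 256² px at
0.2 µm/px (51.2 µm field), 80 filaments, 15 frames at 10 s intervals,
v0 = 0.2 µm/s. `global` places four asters (one per quadrant, capture
40 µm) so that every filament converges and the network quiets within
~8 frames; `partial` one aster of 18 µm capture in the left half;
`none` no asters. These sizes keep a 60-series suite within minutes on
one CPU while leaving each PIV window ~10 px of per-lag displacement —
well inside the coarse-to-fine search range.

**FRAP traces.** Recovery follows the closed-form solution for free 2D
diffusion into a uniformly bleached disc of radius r, observed as the
mean intensity inside the disc: f(t) = e⁻ˣ[I₀(x) + I₁(x)] with
x = r²/(2Dt), computed with exponentially scaled Bessel functions for
stability. The trace is 1 pre-bleach, drops to 1 − β at the pulse, and
recovers to 1 − φβ (bleach depth β, immobile fraction φ). A
finite-difference explicit-Euler diffusion oracle in the test suite
confirms the closed form to < 1% RMS.

## Tube filter (`tubefilter`)

The skeletonization pipeline is CLAHE → Gaussian smoothing → Hessian
ridge response → adaptive threshold → thinning. The method text behind
this pipeline fixes CLAHE and the Gaussian before the Hessian but not
their mutual order; both orders are selectable (`clahe_first`, default
CLAHE first, the order as listed).

- **CLAHE**: square tiles (`tile_px`, default 32) and normalized clip
  limit (default 0.01); output in [0, 1]. A constant image maps to a
  constant. With one tile and a large clip limit the transform reduces
  to plain (rescaled-CDF) histogram equalization, which is how the unit
  test pins it to a direct histogram oracle.
- **Hessian ridge response**: the image is smoothed at `hessian_sigma_px`
  and the Hessian taken with exact central differences ([1, −2, 1] and
  the cross term from two first differences). Sampled
  Gaussian-derivative kernels were rejected: near σ ≈ 0.5 px the
  discrete order-2 kernel no longer sums to zero, so a constant image
  would produce a nonzero "ridge" response and amplitudes are wrong by
  large factors. λ₂ is the algebraically smaller eigenvalue — the
  minimal surface curvature, strongly negative across a bright ridge —
  and the response is max(−λ₂, 0), exactly linear in input intensity.
  Default scale 1.5 px ≈ half the rendered filament width, the
  matched-scale choice; borders use reflective padding to avoid
  spurious edge ridges.
- **Adaptive threshold**: foreground where the response exceeds its
  Gaussian-weighted local mean (block 51 px, window SD (block−1)/6)
  plus an offset. The default offset is computed from the data as
  3 × the robust (MAD-based) SD of the response, which caps the
  false-positive skeleton density on signal-free images below 0.005
  while true ridges sit far above the noise floor; a fixed offset
  (including 0, the literal local-mean rule) can be set in the config.
- **Thinning**: `skimage.morphology.skeletonize` (two-subiteration,
  8-connectivity, topology-preserving); idempotent, component-count
  preserving, and a subset of the threshold mask.

On noiseless synthetic fields of 20 filaments, ≥ 95% of true centerline
pixels lie within 2 px of the skeleton and vice versa.

## Network metrics (`netmetrics`)

Skeleton density is foreground count over pixel count. A node pixel is
a skeleton pixel with more than two foreground 8-neighbors; 8-connected
clusters of node pixels are merged into one intersection (cluster
centroid), since the raw pixel rule over-counts X-crossings. Both the
raw node-pixel count and the merged count are reported, as the source
method does not state which it uses. Nodes within 2 px of the border
are discarded (thinning artifacts). Node density is merged count over
field area in µm².

**Known limitation — junction localization.** Topology-preserving
thinning displaces the junction of an acute crossing along the angle
bisector by roughly the ridge half-width divided by tan(angle/2),
sometimes splitting one X-crossing into two Y-junctions. On noiseless
60-filament fields, ~77% of well-separated true crossings are recovered
within 3 px and ~88% within 5 px; shallow-angle crossings dominate the
tail. Counting statistics (node density trends) are unaffected, but
sub-3-px localization of individual intersections should not be
expected from a thinning-based skeleton.

**Bundling factor.** Mean actin intensity at skeleton pixels, after
subtracting the per-image median of the non-skeleton pixels (a
background estimate that makes the factor invariant to additive
offsets; subtraction can be disabled to mirror a plain masked mean),
normalized by the same quantity averaged over a designated reference
condition in which bundling is assumed rare. The reference condition
therefore scores exactly 1 by construction, and a field of multiplicity-m
bundles scores m within a few percent on noiseless renders.

## Nematic order (`nematic`)

**Orientation estimation.** Non-overlapping square windows; per window
the structure tensor (Gaussian-derivative gradients at scale
window/4, outer products summed over the window) gives the dominant
orientation as the direction of least gradient variance (the ridge
direction, perpendicular to the principal gradient axis) and a
coherence (λ₁ − λ₂)/(λ₁ + λ₂). Windows whose gradient energy falls
below 5% of the median window energy are invalid — background windows
would otherwise contribute noise orientations.

**Local order parameter.** q = 2⟨cos²θ − 1/2⟩ = ⟨cos 2θ⟩ over the
valid windows of a centered 5×5 kernel, with θ each neighbor's
alignment difference to the local director. When the center window is
valid, it defines the director and is excluded from its own average;
q = 1 exactly when all orientations coincide ("no difference in
alignment"), and E[q] = 0 for orientations uniform on [0, π).
The alternative — director from the kernel's mean nematic tensor —
was rejected because the resultant length has a positive finite-sample
bias (≈ 0.18 for 25 windows), which would make the maximal-disorder
limit q = 0 unreachable by construction; that definition is retained
only as the fallback for kernels whose center window is invalid.
Windows with fewer than 3 valid neighbors are undefined (NaN).
`q_mean` averages defined windows; counting undefined windows as q = 0
is available but off by default.

**Window sweep.** Because q depends strongly on window size, `q_mean`
is computed over a size grid and an operating size selected as the
smallest window inside the 1–2 µm band where the step-to-step change
falls below 0.02 (a plateau rule); a fixed size (default 1.5 µm) can
override. Perfect alignment is scale-free (curve flat at 1); isotropic
fields decay toward 0 as windows grow.

Note that an isotropic *filament* field still yields q_mean ≈ 0.2–0.5
at µm-scale windows: individual straight filaments align neighboring
windows locally. The estimator is therefore validated as a monotone,
strongly correlated (r > 0.9) readout of the generating concentration
κ, not as an unbiased estimator of the sampled-orientation order.

## Dynamics (`dynamics`)

**Registration.** Translation-only (thermal drift has no rotation or
scaling), against a running reference (the previously registered
frame). The correlation peak is found on the Hann-windowed FFT
cross-correlation and refined by a 3-point Gaussian/parabolic fit; the
search is bounded (default ±15 px per frame) so that self-similar
structure — e.g. regularly spaced asters — cannot capture the drift
estimate, which unbounded phase correlation demonstrably does on
contracted networks. Imposed uniform drifts are recovered to < 0.05 px
per frame on synthetic series.

**Correlation traces.** Plain Pearson correlation over all pixels, for
frame pairs (n, n+1) within one channel and for synchronized
actin/myosin frames. Undefined (raised) for zero-variance images.

**PIV.** In-repo implementation: square interrogation windows (default
final 32 px, 50% overlap), coarse-to-fine (default two passes starting
at 64 px, the second pass offsetting the search window by the rounded
previous-pass prediction), FFT cross-correlation of mean-subtracted
windows with the peak restricted to ±window/3, 3-point Gaussian
sub-pixel refinement (parabolic fallback for non-positive neighbors),
and Westerweel normalized-median validation (ε = 0.1, threshold 2.0)
with invalidated vectors excluded from statistics but median-filled for
the next pass's predictor. Pure translations up to a quarter window are
recovered to < 0.2 px. Velocities are displacement × pixel size / lag;
the default lag is 10 s.

**Velocity distributions.** Gaussian KDE over valid vector magnitudes
with the normal-reference (Silverman) bandwidth, reflected at zero
speed so the density integrates to 1 on [0, ∞).

**Contraction classification.** The three-way call is built from four
evidence scalars: the lag-1 dip depth Δdown = max(early trace) −
min(trace) and recovery Δup = final − min(trace); the early high-speed
weight w (fraction of early-frame speeds above the 90th percentile of
pooled late-frame speeds); and the converging-area fraction f —
the fraction of valid PIV cells whose smoothed early-flow divergence
lies below −3 robust SDs of the late-frame divergence (the quiescent
noise reference), after a 5×5 morphological closing that absorbs the
thin divergent ridge lines separating adjacent aster basins (vectors
locally separate on a basin boundary even though both sides contract).
"Early" is the first 3 analyzed lags after t = 0, "late" the last 3.
Decision rule: contracting if Δdown ≥ 0.05 and Δup ≥ 0.03 and f ≥ 0.5;
noncontracting if Δdown < 0.05 and w < 0.2; otherwise partially
contracting. All thresholds live in `ClassifierConfig`; the synthetic
suite is their calibration surface, on which the defaults score 59/60
over 20 seeds per scenario. The published classification this rule
replaces is qualitative; these numbers are a package decision.

## Interface physics (`layerphys`)

RIfS reports the optical thickness ΔOT = n·d of an adsorbed layer;
dividing by the protein refractive index n_prot = 1.455 gives the
physical thickness. Binding amplitudes are median(plateau) −
median(baseline) over disjoint index windows of ≥ 5 samples.

The FRAP fitter performs least squares on the post-bleach trace with
the uniform-disc recovery model I(t) = pre − β + β(1 − φ)f(t; D),
fitting D, the immobile fraction φ and the bleach depth β (initialized
from the trace). This spot-averaged model replaces frequency-domain
image-stack methods deliberately: only the spot trace is modeled, and
the observables (D, φ) are the same. The fit assumes the trace is
already corrected for acquisition bleaching and normalized to a
pre-bleach level of 1, and a uniform-disc initial bleach profile (no
bleach-profile calibration is attempted). A trace with no measurable
recovery (< 2% of the bleach depth) makes D unidentifiable: the fitter
raises with a diagnostic and a model-free immobile fraction
(1 − (plateau − min)/(pre − min)) is available separately. Round-trip
bias is ≤ 10% for D ∈ {1, 3, 10} µm²/s at 2% trace noise.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that each estimator recovers the generating
truth under the generator's assumptions: straight filaments, Gaussian
line spread, Poisson + Gaussian noise, kinematic radial flow, uniform
bleach discs. Real micrographs add out-of-focus background, labeling
heterogeneity, filament curvature at long lengths, depletion and
photodamage, optical aberrations and mechanically coupled (not
prescribed) flow; none of these are emulated, so quantitative accuracy
on real data must be established per dataset. Free parameters of the
preparation that the source work does not report (filament length
distribution, labeling density) are generator defaults chosen as
field-typical values, not calibrated to any experiment.
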