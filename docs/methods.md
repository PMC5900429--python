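# Methods

This note records the models, numerical choices and limitations behind the
package, in the spirit of the methods documentation of mature scientific
toolkits: enough detail that a user can judge what a passing test suite does
and does not demonstrate about their own recordings.

## Coordinate and map conventions

Image coordinates are 0-based `(row, col)` with the origin at the top-left
and pixel centers at integers. ST maps are stored with row 0 = time 0 at the
top and time increasing downward; there is no consensus in the field about
which axis should be vertical, so orientation is a render-time option only —
the stored CSV never changes with it. The default frame interval is 1/15 s,
the standard video rate for phasic smooth-muscle contraction; faster events
(e.g. fast phasic colonic contractions) need faster acquisition, and slow
tonic changes need frame down-sampling (see drift, below). Missing values
are NaN throughout, serialized as empty CSV cells, and are never silently
interpolated; interpolation is always an explicit call.

## Edge detection and diameter maps

The organ is assumed brighter (or darker, by a polarity flag) than a uniform
background, as in organ-bath preparations. Each pixel column's profile is
smoothed with a 1-D Gaussian (σ = 1 px default) and the **outermost
half-maximum crossings** are localized to sub-pixel precision by linear
interpolation between the bracketing pixels. The half-maximum criterion is
unbiased for symmetric edge blur, which is why the simulator renders
coverage-weighted (anti-aliased) edges: the rendered half-maximum coincides
with the geometric edge, making sub-pixel accuracy testable. Columns whose
profile never crosses the level are invalid; columns with more than one
bright band use the outermost pair and are flagged ambiguous (overlapping
bowel loops in situ are out of scope). A Sobel-style derivative-of-Gaussian
detector is available behind the same contract.

The D-map value is the sub-pixel edge-to-edge distance, not an inclusive
pixel count; historical implementations are ambiguous on this point and the
two differ by a constant ~1 px, which cancels in all differential
quantities. R-maps split the diameter at a user-supplied midline (a constant
row or per-column profile, e.g. a taenia); columns where the midline leaves
the edge envelope are invalidated in both maps, since a midline defined by
the edges themselves cannot disambiguate independent wall motion. Arcuate
D-maps sample rays at 1-px radial steps by bilinear interpolation and apply
the same half-maximum logic radially; a flag rescales the angular axis to
arc length at a stated radius so linear propagation velocity can be read
off.

## Window matching and sub-pixel refinement

Local motion is measured by minimizing the mean-removed SSD between a
(2h+1)² reference window (default h = 10, i.e. 21×21 px) and displaced
windows over an integer search grid (default ±15 px). The window means are
recomputed for every displaced window, making the cost insensitive to
uniform illumination differences between frames. The literature often calls
this family "cross-correlation"; the minimized quantity is an SSD, whose
minimizer coincides with the maximizer of the corresponding mean-removed
correlation. An SAD variant is provided; experience in the field is that
the choice is not critical.

Ties among equal integer minima are broken toward the smallest displacement
magnitude, then smallest column shift, then smallest row shift — a bias
toward the null hypothesis of no motion. The integer minimum is refined by
fitting a bicubic spline (`RectBivariateSpline`, kx = ky = 3) to the full
cost surface and minimizing it with bounded L-BFGS-B within ±1 px of the
integer node. Two guards apply: a minimum on the search border is returned
unrefined and flagged invalid; and a numerically perfect match (cost ≤
1e-12 · window area · window variance) returns the integer node directly,
because zero cost identifies the displacement exactly and a cubic
interpolant can only overshoot below it. Quality is reported as the minimum
cost normalized by the reference-window variance — used only for optional
sample rejection, never for localization.

Measured accuracy on band-limited speckle is ~0.01 px per pair; residual
biases are texture-dependent spline-model error, the analogue of
peak-locking in PIV.

## LOI tracking, L-maps, displacement and shunt correction

A line of interest is an ordered polyline resampled to exactly 1-px
arc-length spacing. Tracking is **material**: after each frame pair the
window is re-centered on the advected position, so a sample follows tissue,
not a fixed frame location. The tangential velocity component feeds the
strain rate; the normal component is retained as a diagnostic only, since
LOI strain is a tangential quantity. Consequence of material tracking:
per-pair errors accumulate as a random-walk over long sequences. For slow
tonic change (per-frame displacement far below the jitter floor) the remedy
is less frequent sampling: the stride parameter. The suite demonstrates a
caecal-style slow elongation recovered within 10% at stride 15 and not at
stride 1.

The L-map is the arc-length derivative of tangential velocity × 100
(%·s⁻¹), computed with a Savitzky–Golay derivative filter (local quadratic,
5-sample support by default). Differentiating a tracked velocity is noise
amplifying; the filter support is the resolution/noise trade-off knob.
Negative strain rate cannot distinguish active contraction from elastic
recovery after stretch — an inherent ambiguity of strain-rate mapping, not
an implementation limit.

Displacement maps are cumulative sums of v·Δt per sample: each tracked
velocity sample is itself a displacement increment over exactly one pair
interval, so the cumulative sum is the exact integral at pair boundaries
(no additional quadrature error). Invalid samples carry the last valid
velocity forward and are logged. Shunt correction resamples each D-map row
by linear interpolation from laboratory columns to material coordinates
ξ ↦ ξ + u(ξ, t); columns where the lab mapping folds over (non-monotonic,
physically tissue overlap in projection) are flagged invalid rather than
resolved.

## Area strain rate and derived summaries

A tracking grid (default 5-px spacing — windows at every pixel are
redundant, since adjacent 21×21 windows overlap almost completely) is
matched between frame pairs inside a region of interest. The displacement
components are smoothed over the grid (Gaussian, σ = 1 grid unit,
NaN-aware normalized convolution) before gradients are formed: strain is a
derivative of a noisy measurement and unregularized per-node differences
are jitter-dominated when per-pair motion is small. Stretch ratios are
λ_L = 1 + ∂u_x/∂x and λ_D = 1 + ∂u_y/∂y and the area strain rate is
(λ_L·λ_D − 1)/Δt × 100. The product form is used rather than the sum of
strains; the sum is its first-order equivalent at small strain. Fields are
bilinearly upsampled to pixel resolution for overlays and density plots.

Spatial resolution: a localized contraction patch is smeared by roughly the
window half-width plus the gradient support (~15 px with defaults), so
occupancy statistics are exact in a patch core but graded at its flanks —
visible in the density plots as a halo around the true patch.

Density plots count, per pixel, the percentage of sampled fields **strictly
below** the threshold (default −4 %·s⁻¹, matching the conventional
"<−4 %·s⁻¹" phrasing), over the valid fields only; a subsampling stride for
the field sequence is exposed without a claimed default. Patch metrics
follow the FRAGSTATS raster conventions: 8-connected components; perimeter
as boundary edge count; shape index 0.25·P/√A (1.0 for a square; a
rasterized disk gives 2/√π ≈ 1.13 because the taxicab perimeter of a
digital circle is 8r); perimeter–area fractal dimension 2/b with b the
least-squares slope of ln A on ln P pooled over ≥2 patches. Core area % is
the thresholded fraction of the valid ROI.

## Analytics

FFT frequency estimation removes the mean (optional), takes the argmax of
the non-DC power bins, and reports NaN for spectra with no non-DC content;
resolution is 1/(N·Δt), and all frequency assertions in the suite are at
one-bin tolerance. Per-column frequency profiles flag steps larger than 1.5
bins as candidate phase dislocations (fusion/bifurcation points of bands).
Correlograms are per-lag Pearson correlations over the valid overlap,
computed by direct summation; this normalization puts the autocorrelogram
center at exactly 1, keeps values in [−1, 1], and is point-symmetric under
lag negation for autocorrelograms. Map subtraction requires congruent grids
and identical units and propagates NaN.

Event detection on diameter-type maps uses a per-column rolling-median
baseline (robust to slow tonic drift; window configurable, default 61
rows), a constriction mask at value < (1 − f)·baseline (f = 0.2 default),
and 8-connected components above a minimum area. The ridge is the per-row
position of the component minimum; velocity is the least-squares slope of
the ridge with a Theil–Sen fallback when the linear fit is poor (bands that
fuse or bifurcate), and ridge points pinned at the map borders — waves
entering or leaving the field of view — are excluded from the fit. Contraction
amplitude is defined here as the fractional reduction from the rolling
baseline at the deepest cell; the literature offers no operational
definition. Phase offsets use the single Fourier component nearest the
stated frequency, with a resolvability gate (component power ≥ 5× the
median spectral power in both series); a positive offset means the first
series leads.

I-maps sample frames bilinearly at the LOI points, with no detrending (an
optional per-row mean subtraction helps visualization over uneven
illumination). Caveat for quantitative use: under oblique illumination the
bright ridge of an I-map follows the specular highlight rather than the
tissue, so propagation speeds read from I-maps are not a true estimate of
wall-movement speed and should be checked against D- or L-maps.

## The simulator

The simulator is the package's oracle: every scene is rendered from
closed-form fields that are returned as ground truth.

Tube scenes render the diameter field D(x, t) = D₀(1 − A·g(x, t)) with
pattern envelopes chosen for closed-form tractability: a Gaussian wave
train for peristalsis (waves launched at the programmed frequency from the
proximal end); linear-ramp onset sweeping proximally→distally with release
sweeping distally→proximally for mass peristalsis (the classic triangular
D-map footprint); a standing spatial sinusoid gated by a temporal sinusoid
for segmentation; and a standing displacement wave u = A·sin(2πft)·sin(πx/L)
for pendular motion. Longitudinal coupling modes: `none`; `incompressible`
(wall-area conservation, strain = D₀/D − 1, displacement by cumulative
trapezoid); `prescribed` (spatially uniform strain rate — the scene used
for L-map calibration). A traveling band of longitudinal shortening can be
programmed to lead the circular constriction by a set time, emulating the
physiological ordering in peristalsis, and a rigid bulk oscillation
reproduces shunting. Rendering is anti-aliased (coverage-weighted edges) so
sub-pixel edge claims are testable; markers are dark Gaussian blobs
(σ ≈ 2.5 px, emulating ~100 µm carbon/glitter particles) at Poisson-disc
(dart-throwing) positions, dense enough (default 60 per 100×100 px) that
every 21×21 window contains texture; markers advect with the longitudinal
field and scale radially with the local diameter. Sensor noise is additive
Gaussian, clipped to [0, 255], applied last, fully seed-controlled;
identical (scene, program, seed) triples are bit-identical.

Sacculate scenes render a disc silhouette with markers; each contracting
patch scales tissue radially about its (possibly translating) center by
√(1 + s·Δt) per axis per frame while active, so the programmed area strain
rate s is exact in the patch core, with a cosine taper at the rim; the
per-pixel ground-truth field uses the exact radial Jacobian. Duty cycles
are phase-gated with a rounding guard so the active fraction is exact for
frame-aligned periods.

What the simulator does **not** emulate: perspective and surface curvature
(the known underestimation of strain at the periphery of large curved
organs), illumination gradients and specular reflection, lumen contents and
fluid coupling, out-of-plane motion and sagging, overlapping organ loops,
and marker loss. Passing tests therefore demonstrate algorithmic
correctness against known kinematics, not robustness to these real-world
effects.

## Validation problem sizes

The acceptance script runs each pipeline at desk scale, chosen to keep the
whole battery around a minute while leaving every estimate comfortably
inside its tolerance: 50 window pairs for the matching-function oracle;
four sub-pixel shifts; three 30-frame tubes for D-map fidelity; one 900-frame
(60 s) peristalsis run for wave recovery; 12-frame strain and 6-frame
translation scenes for L-map calibration; 3-frame analytic compressions for
the A-field; a 61-frame duty-cycled patch sampled at stride 3 for density
calibration (stride-aligned so the programmed 30% active fraction is exact,
and because per-frame displacements at −6 %·s⁻¹ and 15 fps sit below the
tracking jitter floor — the down-sampling prescription for slow change);
a 46-frame shunting scene; and analytic series for phase/periodicity. The
density-plot occupancy is evaluated in the patch core (patch radius minus
the ~20-px measurement smear) and well clear of the patch, per the
resolution analysis above.
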