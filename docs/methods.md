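# Methods

This note documents the models, numerical choices and validation scope of
`dorsitrack`. It is the design record: every empirical statement here is
computed by the test suite or the acceptance script, not asserted.

## 1. The synthetic imaging model

### Image formation

B-mode speckle arises from sub-resolution scatterers; the phantom emulates
its *statistics*, not its acoustics. A Poisson-random scatterer field
(default 8 scatterers/mm², exponential echo amplitudes) is splatted
bilinearly onto the pixel grid, convolved with a Gaussian point-spread
(σ = 0.3 mm, roughly a 12 MHz linear-array resolution cell at this
pixel size), scaled by a fixed gain so mean brightness is independent of
density, offset by a uniform background (0.12), clipped to [0, 1] and
stored as 8-bit grayscale with fresh additive Gaussian noise per frame
(σ = 0.02). Zero density degenerates to a uniform background frame, which
the tracker correctly refuses to track (textureless windows are flagged).

### Geometry and motion

Five muscle layers occupy disjoint depth bands (TR 2–8 mm … MF 30–36 mm,
1 mm connective gaps) in a 40 × 38 mm field of view at 0.2 mm pixels.
Motion is a per-layer stretch along the fiber (lateral) axis about the
image midline: layer *l* at time *t* has strain
`s_l(t) = a_l/100 · w(τ)`, where `a_l` is the signed peak amplitude (%)
and `w` the cycle waveform. The through-depth strain profile is constant
inside each layer and linearly interpolated across gaps. A rigid
sinusoidal sway (default 0.1 mm axial) is superimposed to stress the
tracker; it carries no strain.

The default waveform is a raised cosine `w(τ) = (1 − cos 2πτ)/2`: each
2-s rotation cycle starts and ends at zero deformation and peaks
mid-cycle, matching a reach-and-return rotation paced at 30 beats/min
(one beat out, one beat back). A `biphasic` sine option exists for
curves that cross zero within a cycle. Ten cycles are rendered at
50 frames/s; a contact-switch channel emits start/reach/stop events per
cycle, and the tenth cycle is the analyzed segment, as in the emulated
protocol.

Frames are rendered by inverse-mapping the reference frame with bilinear
interpolation, so the warp that moves the speckle is *identical* to the
bookkeeping that defines ground truth: advecting two in-layer points and
measuring their separation reproduces the true deformation to < 1e-6 %
(tested). Determinism is bit-exact for a fixed seed; per-subject seeds
derive from the master seed via CRC-stamped `SeedSequence` spawn keys.

### Cohort effect structure

No per-muscle strain magnitudes are published for this task, so the
cohort defaults are package choices, fixed once: control peak amplitudes
4/5/6/7/8 % (TR/SP/Scap/Scerv/MF — deeper layers deform more in
rotation), between-subject SD 1.5 %, and a WAD deficit of 1.5/2.0/2.0 %
on Scap/Scerv/MF in right rotation only. That plants the qualitative
case–control structure (reduced deep-muscle deformation toward the
painful side, ≥ 1 between-subject SD) that the inference stages are
expected to recover; validation is therefore *parameter recovery*, not
reproduction of any published F statistics, which depend on the original
recordings. Amplitudes are drawn independently per subject × muscle ×
direction × timepoint; real data would add subject-level correlation,
which the mixed models tolerate but the generator does not emulate.

With the one-signed raised cosine, a muscle's curve stays on one side of
the 0 % line, so one of the under/over areas is structurally zero for
most subjects; the multivariate stage drops such zero-variance columns
with a log entry rather than silently scaling them.

### Statistics-level simulation

`simulate_feature_table` skips rendering and tracking: the drawn
amplitudes are converted to exact analytic single-cycle curves and pushed
through the *real* curve and area code. This is the feature table an
error-free tracker would produce and is what the cohort-scale calibration
tests use (2000-replicate type-I error, 100-replicate power); rendering
68 videos per replicate would add only tracking noise already
characterized separately.

## 2. Tracking

The point stage is pyramidal Lucas–Kanade: per measuring point, the
frame-k window (half-size 8 px) is matched in frame k+1 by Gauss–Newton
descent on the SSD, coarse-to-fine over 3 pyramid levels, up to 30
iterations, convergence at 0.01 px. Gradients use Sobel kernels
(normalized by 8). A point is invalidated when its gradient structure
tensor is near-singular (texture gate, applied at full resolution only —
pyramid blurring shrinks gradients at coarse levels, where the gate would
misfire), when it diverges out of the image, or when the final mean
squared residual per pixel exceeds 0.01 (on [0, 1] intensities; correct
tracking on the default phantom sits near 2·noise² ≈ 8e-4, pure noise an
order of magnitude higher).

Displacements of the valid points (≥ 50 % of the 15 required) are
projected on the ROI axis and fitted with displacement =
translation + strain·(position − centroid); ordinary least squares by
default, with an optional single-pass trimmed refit (drop the worst 20 %)
for outlier robustness. All points are advected by the *fitted* linear
map (raw per-point displacements would accumulate independent jitter),
plus the mean lateral displacement. Length accumulates multiplicatively,
which makes `∏(1+ε_k) = L_n/L_0` an exact identity and avoids the drift
bias of additive accumulation at large cumulative strain. Invalid frames
carry the previous length forward and are masked downstream; more than 25
consecutive invalid frames raise a tracking-lost error rather than
returning quietly corrupt curves.

Measured performance on the default full-scale phantom (tested): peak
deformation of the tenth cycle recovered within max(0.5 points, 10 %
relative) for layer strains from −10 % to +10 %, pure translation reads
as < 0.2 % deformation, and one subject (5 ROIs × 1011 frames) tracks in
well under a minute on one CPU.

## 3. Curves and areas

Deformation is referenced to the first frame of the analyzed cycle (the
midline start event): the emulated protocol defines deformation "from
rest", and the cycle start is the per-cycle rest proxy; the reference
frame is configurable. Rates use central differences (one-sided at the
ends) on the raw curve — no smoothing is applied by default because none
is described for the emulated analysis; a mask on any stencil sample
masks the rate sample.

The split trapezoid is exact for piecewise-linear curves because zero
crossings are inserted as nodes before integrating the clipped positive
and negative parts. Conventions, stated once: **over** = elongation area
above the 0 % line, **under** = magnitude of the shortening area below
it, **total** = over + under (sum of elongation and shortening
magnitudes), **difference** = over − under, which always equals the
signed integral (tested invariant). RMS of the rate uses valid samples
only. All areas are %·s on the tenth-cycle segment only; no per-cycle
averaging.

## 4. Univariate inference

The split-plot model is computed by least-squares model comparison with
effect-coded (sum-to-zero, Type III) factors, in two orthogonal strata:
between-subject effects on subject means (group, plus sex as an additive
between-subject factor — "sex-adjusted" is implemented as a blocking
factor with no interactions, switchable by passing `adjust=None`), and
within-subject effects (muscle, muscle × group) on deviations from
subject means. Balanced-design F values match `pingouin` exactly; under
group imbalance the group and interaction F still match, while the
muscle main effect is the Type III (unweighted-means) estimand, the
convention of the mainstream commercial packages. Every F, df and
partial η² also matches an independent projection-matrix oracle to 1e-8
(tested on 200 random designs).

Mauchly's W uses the pooled within-cell contrast covariance (residual df
n − number of groups) with the standard χ² approximation;
Greenhouse–Geisser ε = (tr S)² / ((k−1) tr S²) is clamped to
[1/(k−1), 1] and applied to the within-stratum dfs only when Mauchly's
p < 0.05, with α fixed at 0.05 throughout. The 0/0 no-variance case is
guarded to F = 0 using a tolerance scaled to the data's total sum of
squares (1e-12 relative), so constant inputs and exactly-identical
repeated measures report null effects instead of round-off ratios.

Post-hoc contrasts collapse muscles to three anatomical levels
(superficial TR+SP, middle Scap, deep Scerv+MF); each pairwise contrast
is the between-group test on the within-subject level difference score,
Bonferroni-corrected over the family of exactly three contrasts.

## 5. Multivariate inference

Columns are mean-centered and unit-variance scaled (the chemometric
default; disable with `scale=False`); zero-variance columns are dropped
with a log entry. PCA is a plain SVD with a deterministic sign convention
(largest-magnitude loading element positive).

OPLS-DA uses a centered ±1 class dummy: orthogonal components — X-weight
structure orthogonal to the predictive direction — are peeled off
iteratively (default 1, configurable; with 0 the model reduces exactly to
1-component PLS-DA, a tested equivalence), then one predictive component
is fitted on the filtered matrix. Cross-validation is stratified
leave-out-p with 7 folds (p ≈ n/7, fold sizes within one, seeded
round-robin across classes). The jackknife SE per variable is
`sqrt((g−1)/g · Σ(p_i − p̄)²)` over the g = 7 sub-model predictive
loadings (sign-aligned to the full model), and the 95 % CI is the
full-model loading ± t₀.₉₇₅,₆ · SE; significance = CI excludes zero.
Held-out predictions give the reported CV accuracy. Proprietary
diagnostics of commercial implementations (Q², CV-ANOVA) are out of
scope.

## 6. What a green test establishes — and what it does not

The synthetic world validates the *machinery*: exact area algebra,
unbiased strain recovery under controlled speckle statistics, calibrated
type-I error (5 % ± 1.5 % over 2000 null cohorts), and the power to
recover a planted ≥ 1 SD deep-muscle deficit by both inference routes
(≥ 80 % of replicates, with the unaffected direction at the null rate).
It does not validate robustness to out-of-plane motion, anisotropic
speckle decorrelation, probe pressure, anatomical variation in layer
geometry, or operator-dependent ROI placement — all properties of real
recordings that no warping phantom can certify.
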