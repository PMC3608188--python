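# Methods

## Tracking model

The tracker estimates, for every pair of consecutive frames, one displacement
per contour point by minimizing the sum of (i) a windowed brightness-constancy
term per point and (ii) a global penalty on the distance of the displaced
configuration from the affine shape space of the initial contour.  Both terms
are quadratic in the displacements, so the minimizer solves a single
symmetric `2n×2n` linear system; there is no iterative warping, pyramid, or
contour evolution.  The assumptions are those of any local optical-flow
method — brightness constancy between frames and an intensity structure
smooth enough that a first-order expansion holds over the actual motion —
plus the shape assumption that heart-wall motion is dominated by a global
affine deformation (rotation, contraction/expansion, shear, translation)
with only small non-affine residuals.

Key numerical choices:

* **Coordinates** are `(x, y) = (column, row)`, 0-based, `y` downward.
  Positions are kept at subpixel precision throughout; images, gradients and
  temporal differences are sampled at non-integer window positions by
  bilinear interpolation of per-frame integer-grid fields.
* **Derivatives.** The temporal derivative is the two-frame forward
  difference.  The spatial gradient is the *average* of the two frames'
  central-difference gradients: centering the gradient between the frames
  makes the linearization error second-order in the displacement, which is
  what lets a single solve handle the larger (5–9 px) inter-frame motions
  near end-diastole.  With one-sided gradients those motions were
  systematically underestimated by several pixels.
* **Window convention.** The window is a 21×21 Gaussian, σ = 5 px, with
  *peak-normalized* weights (center weight 1, total ≈ 150).  The weight
  scale trades off one-for-one against `λ`, so this convention fixes the
  meaning of every quoted `λ`; divide by the total weight to convert to
  unit-sum-window values.  Windows clipped at the image border keep the full
  window's total weight (the surviving weights are rescaled), so the
  data-term scale, and hence the `λ` trade-off, stays comparable near edges.
  A point entirely outside the image contributes no data term and is carried
  by the shape prior alone.
* **Solver.** Dense symmetric direct solve.  If the condition estimate
  exceeds 1e12 (e.g. textureless windows at `λ = 0`), a diagonal bump of
  `1e-8 · trace/(2n)` is added with a warning.  At `λ = 0` the system is
  block-diagonal and reproduces per-point Lucas-Kanade to ~1e-15 px.

## Self-calibration of λ

With reference displacements `u_j` (manual annotations or simulator ground
truth) on a frame pair, the statistic

    λ̃ = ‖ stacked (AᵀWA u_j + AᵀWb)_j ‖ / ‖ stacked shape residuals ‖

is a ratio of Frobenius norms of the stacked per-point Lucas-Kanade
residuals and shape-space residuals, built from λ-free local terms.  The
normalization is forced by consistency: at a stationary point of the
tracking energy each LK residual equals `−λ` times its shape residual, so
reference displacements generated by the tracker at some `λ` return exactly
that `λ` (a ratio of *squared* norms would return `λ²`, which could not be
fed back in as the weight).  This recovery is exact in the implementation
(137 → 137.0) and is covered by a test.

Per-sequence `λ` is the mean of per-transition `λ̃` over the annotated
transitions.  On simulated sweeps of the tissue/blood contrast,
`log10 λ̃` is close to linear in `ln(contrast)` (R² ≈ 0.97 on the default
sweep), so a contrast-based look-up (`choose_lambda_from_law`) can replace
per-sequence annotation.

## Synthetic scenes

The simulator produces apical-view sequences with exact dense ground truth.

* **Speckle.** Per pixel the echo envelope is Rayleigh with a per-class
  scale (`sigma_tissue = 5`, `sigma_blood = 1.5` by default; the cavity and
  background share the blood scale).  Log compression
  `I = α₁ ln A + α₂` turns the intensity density into the Fisher-Tippett
  (doubly-exponential) law; this is verified by a change-of-variables test
  against quadrature of the stated density.  Intensities are clipped to the
  nonnegative display range before a final Gaussian low-pass
  (`smooth_sigma = 1.5` px), so weak-signal nulls render black as on a
  B-mode display.  Optionally the envelope is the modulus of a PSF-filtered
  complex Gaussian field (`psf_sigma > 0`), which adds the spatial
  correlation of real speckle while keeping the per-pixel marginal exactly
  Rayleigh.  A frame is the average of `looks = 9` independent realizations
  (spatial compounding), which reduces texture variance ninefold while
  leaving anatomy unchanged — the display then resembles a compounded,
  low-gain clinical image (default intensities occupy roughly 0–45 of the
  0–255 range; the scale is pinned by the λ̃ operating point below).
* **Anatomy.** A U-shaped cavity (half-ellipse from annulus over the apex)
  inside a myocardial band whose thickness grows linearly from 20 to 25 px
  over the sequence.  Three echogenic structures that real apical views
  contain were found necessary for the motion to be *observable* to a
  windowed tracker and are part of the default scene: (i) a broad
  valve-plane/atrial ramp spanning the cavity below the annulus chord
  (blurred by `valve_sigma = 10` px — a sharp interface there would defeat
  the linearization at the 9 px basal motions); (ii) papillary/trabecular
  relief, one blurred blob just inside the border at each interior tracking
  point, carrying along-wall motion information symmetrically about each
  point; (iii) both contours extended two segments beyond the annulus, the
  extensions moving with the per-frame affine fit of the tracked nodes plus
  each end node's own residual, so tissue below the valve plane moves
  coherently with the base instead of being pinned to the static background.
  Class boundaries in the Rayleigh-scale map can be blurred (`edge_sigma`,
  default half the PSF width) since the imaging PSF mixes backscatter across
  interfaces.
* **Motion and warping.** Endocardial points move as a per-frame
  interpolation toward a cumulative affine contraction
  `(a₁..a₆) = (0.92, −0.03, −0.01, 0.89, 20, 6)` with interpolation
  fractions `(0, 0.3, 0.75, 1)`, plus an i.i.d. uniform free-form
  perturbation of ±0.1 % of each coordinate.  Epicardial nodes are re-offset
  along the border normals at each frame's wall thickness.  Frames are
  rendered by Delaunay piecewise-affine warping of the base speckle image
  along the node trajectories (stationary anchors on the frame boundary keep
  the mesh defined everywhere); every frame is warped directly from the base
  frame with cubic resampling so interpolation blur does not compound, and
  the warp maps each node *exactly* to its target position, making the node
  trajectories exact ground truth.
* **Dropout.** Rib shadowing is modeled as a static image-space region in
  which the envelope is attenuated by a factor `d` on every frame
  (equivalently the compressed intensity shifts by `α₁ ln d`, clipping to
  black for small `d`); the tissue keeps moving beneath the static shadow.
* **Reference fixture.** `table1_fixture()` drives the 13 endocardial nodes
  verbatim along a published 4-frame integer coordinate table whose
  consecutive differences are the published displacement table; everything
  else (epi offsets 20→25 px, speckle, structures) follows the defaults.

The speckle/compression defaults were fixed in a single calibration pass so
that the per-transition λ̃ of the reference fixture centers on 300 — the
operating point at which the published weight `λ = 300` is the
self-calibrated choice.  They were then frozen and are regression-pinned in
the tests.

What the simulator does **not** model: polar scan-line geometry and
depth-dependent resolution, attenuation and time-gain compensation, electronic
noise, out-of-plane motion, and valve dynamics.  Passing tests on these
scenes therefore demonstrate correctness of the algorithmic chain and its
qualitative robustness ordering, not clinical-grade accuracy.

## Evaluation

* Contours are interpolated through the tracking points by a natural cubic
  spline under chord-length parameterization (open by default — an apical
  border runs annulus to annulus; a periodic mode exists) and densely
  resampled (default ≈ 500 samples) before the symmetric Hausdorff distance
  is computed.
* The forward-backward error tracks through a palindromic sequence (the
  cycle followed by its time reversal; `T` frames → `2T − 1`) and reports
  the mean over points of the *squared* distance between initial and
  returning positions, as the quantity is conventionally defined; an RMS
  variant (a distance in pixels) is available behind a flag.

## Known limitations and the worst-case error on the reference table

A single linear solve per frame pair bounds the recoverable motion by the
intensity-structure scale; the simulator's structures are sized so the 5–9 px
basal motions stay within the linear range, but on arbitrary data large
inter-frame motion will be underestimated (the usual remedy — iterative
re-warping — is deliberately out of scope to keep the per-frame cost one
matrix solve).

On the reference fixture the tracked displacements match the published table
with mean error ≈ 0.4 px, but the worst of the 39 point-transitions
fluctuates around 1 px (0.88–1.22 px over seeds 0–4).  This floor is a
property of the *table*, not the tracker: the published coordinates are
integers, so the warp that drives the scene inherits rounding of up to
0.5 px per coordinate, with second differences between neighboring nodes of
up to 2 px.  Any finite-aperture tracker low-passes that rounding field, and
the affine prior pulls toward a configuration that deviates from the printed
targets by up to the targets' own off-affine rounding residual (≈ 0.87 px at
the worst entry).  The same tracker compared against the *smooth* motion
that the table discretizes (affine + 0.1 % free-form) is accurate to well
under half a pixel.  For the same reason the per-transition λ̃ of the
fixture spreads by about a factor 2 around its mean of ≈ 300 (the shape
residuals in its denominator are dominated by per-transition rounding
realizations), wider than the ≈ 1.4× spread quoted for smooth references.

The qualitative robustness claim is reproduced as stated: with a dropout
sector over part of the border, the coupled tracker's forward-backward error
(≈ 0.8–2 px²) is an order of magnitude below windowed LK and both
block-matching baselines (≈ 4–16 px²) on every tested seed.
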