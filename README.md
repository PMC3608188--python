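# lvtrack

Shape-constrained speckle tracking of the left-ventricle (LV) endocardial
border in 2D echocardiography.

Tracking the LV border frame to frame from its speckle pattern fails locally
wherever the signal drops out (rib shadowing, indistinguishable texture):
individual points wander off the border and distort the contour.  `lvtrack`
implements a tracker that couples per-point windowed Lucas-Kanade optical
flow with a global shape prior — the displaced points must stay close to an
*affine transform* of the initial contour — in a single direct linear solve
per frame pair.  It is intended for researchers developing or evaluating
myocardial motion estimation: it ships the conventional baselines, a
self-calibration rule for the regularization weight, a ground-truthed
synthetic echo simulator, and the evaluation metrics, behind both a Python
API and a small CLI.

## Model

Let `r*_1..r*_n` be the initial tracking points and `r_i(t)` their current
positions.  Each step minimizes over the displacements `U = (u_1..u_n)`

```
E(U) = 1/2 Σ_i [ ∫ w(r − r_i) ( u_i·∇I + ∂I/∂t )² dr
                 + λ | r_i + u_i − (A(U) r*_i + b(U)) |² ]
```

where `w` is a 21×21 Gaussian window (σ = 5 px) and `(A(U), b(U))` is the
least-squares affine map of the initial points onto the displaced points —
equivalently, the second term penalizes the distance of `R + U` from the
affine shape space `W = {Φ C}`, with `Φ = [x*, y*, 1]` and projector
`P = Φ(ΦᵀΦ)⁻¹Φᵀ`.  The stationarity conditions assemble into one symmetric
`2n×2n` system

```
[ Λ − λP    B    ] [U]   [ −Ξ + λP X ]
[   B     Γ − λP ] [V] = [ −Π + λP Y ]
```

solved directly (no contour evolution, no warping iterations).  `λ = 0`
decouples the system into plain per-point Lucas-Kanade; `λ → ∞` forces a
pure affine motion of the whole contour.

The weight `λ` is self-calibrated: given annotated displacements on a few
frames, `λ̃` = (stacked LK residual norm) / (stacked shape residual norm)
recovers exactly the `λ` whose tracker would have produced those
displacements, and depends mainly on the tissue/blood contrast of the
recording (log-linearly), giving a contrast-based choice rule.

Quoted `λ` values assume the package's window convention (Gaussian weights
with peak 1; a 21×21, σ = 5 window has total weight ≈ 150).  Under unit-sum
weights every `λ` must be divided by that total.

## Worked example

Track the built-in reference sequence — four synthetic apical-view frames in
which 13 endocardial points follow a published coordinate table under a
global contraction — and compare against its reference displacements:

```python
import numpy as np
import lvtrack as lt

scene = lt.table1_fixture(seed=1)
window = lt.gaussian_window(21, 5.0)

# self-calibrate the regularization weight from annotated transitions
est = lt.lambda_for_sequence(scene.frames, lt.TABLE1_POINTS, window)
print("lambda-tilde per transition:", np.round(est.per_pair, 1))
print("chosen lambda:", round(lt.choose_lambda(est.per_pair), 1))

traj = lt.track_sequence(scene.frames, lt.TABLE1_POINTS[0],
                         lt.TrackerConfig(lam=300.0, window=window))
err = np.linalg.norm(traj.displacements - lt.TABLE1_DISPLACEMENTS, axis=2)
print("displacement error (px): mean %.2f  max %.2f" % (err.mean(), err.max()))
```

prints

```
lambda-tilde per transition: [385.3 320.5 174.8]
chosen lambda: 293.6
displacement error (px): mean 0.43  max 0.97
```

The per-transition `λ̃` values scatter around 300 — the weight the tracker
then uses — and the tracked displacements reproduce the reference table to
sub-pixel accuracy on average (the worst of the 39 point-transitions is just
under a pixel; see `docs/methods.md` for why the worst case is limited by
the integer rounding of the reference table itself).

The same pipeline from the shell:

```
lvtrack simulate --table1 --seed 1 --out frames.tif --truth truth.csv
lvtrack lambda   --frames frames.tif --annotations truth.csv
lvtrack track    --frames frames.tif --points truth.csv --lambda 300 --out tracked.csv
lvtrack evaluate --truth truth.csv --tracked tracked.csv --metric hausdorff
```

`lvtrack baseline --method {lk,ssd,xcorr}` runs the conventional trackers
(windowed Lucas-Kanade, block matching by SSD or normalized
cross-correlation) on the same inputs, and `lvtrack simulate --config
scene.yaml` generates parametric scenes including signal-dropout sectors.

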