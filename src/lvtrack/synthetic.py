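"""Ground-truthed synthetic echocardiography sequences.

Emulates an apical-view B-mode sequence with fully developed speckle: the
echo envelope in each tissue class is Rayleigh-distributed, log-compression
``I = alpha1 * ln(A) + alpha2`` turns the intensity statistics into a
Fisher-Tippett distribution, and a Gaussian low-pass stands in for the
system point-spread function.  Heart motion is nonrigid: a global affine
contraction of the endocardial points plus a small free-form perturbation,
with the wall thickness between the endo- and epicardial contours growing
over the sequence.  Frames are produced by piecewise-affine (Delaunay)
warping of the base speckle image along the node trajectories, so the
ground-truth displacement at every node is exact.

An optional dropout region attenuates the signal inside a fixed image-space
mask on every frame, emulating rib shadowing: the attenuation is static in
image coordinates while the tissue moves beneath it.

A reference fixture (:func:`table1_fixture`) drives the 13 endocardial
points along a published table of per-frame integer coordinates over 4
frames, with the matching published displacement table as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.transform import PiecewiseAffineTransform, warp

from .core import AffineParams
from .evaluation import spline_contour

__all__ = [
    "SpeckleParams",
    "MotionModel",
    "TemplateParams",
    "SyntheticScene",
    "CONTRACTION_AFFINE",
    "TABLE1_POINTS",
    "TABLE1_DISPLACEMENTS",
    "fisher_tippett_pdf",
    "make_lv_scene",
    "outward_normals",
    "offset_contour",
    "contour_masks",
    "rayleigh_envelope",
    "log_compress",
    "sample_speckle",
    "apply_dropout",
    "disc_mask",
    "simulate_motion",
    "warp_frames",
    "make_scene",
    "table1_fixture",
    "contrast_sweep",
]

# ---------------------------------------------------------------------------
# published reference tables (coordinates as (x, y), one row per point)
# ---------------------------------------------------------------------------

#: 13 endocardial tracking points on each of the 4 frames of the reference
#: synthetic sequence.
TABLE1_POINTS = np.array(
    [
        [  # frame 1
            (152, 201), (151, 176), (155, 151), (152, 128), (142, 105),
            (147, 82), (167, 71), (188, 84), (207, 101), (217, 124),
            (224, 147), (229, 172), (229, 196),
        ],
        [  # frame 2
            (153, 196), (152, 171), (156, 147), (153, 125), (144, 103),
            (149, 80), (169, 70), (189, 82), (207, 99), (217, 121),
            (223, 143), (228, 167), (228, 191),
        ],
        [  # frame 3
            (154, 187), (153, 165), (157, 142), (155, 120), (146, 100),
            (152, 78), (171, 69), (190, 80), (207, 96), (216, 116),
            (222, 138), (227, 160), (226, 182),
        ],
        [  # frame 4
            (154, 183), (154, 161), (158, 139), (156, 118), (147, 98),
            (153, 77), (172, 68), (191, 79), (207, 94), (216, 114),
            (221, 135), (226, 156), (225, 178),
        ],
    ],
    dtype=float,
)

#: Published per-transition displacements of the 13 points (frame k -> k+1).
TABLE1_DISPLACEMENTS = np.array(
    [
        [  # transition 1 -> 2
            (1, -5), (1, -5), (1, -4), (1, -3), (2, -2), (2, -2), (2, -1),
            (1, -2), (0, -2), (0, -3), (-1, -4), (-1, -5), (-1, -5),
        ],
        [  # transition 2 -> 3
            (1, -9), (1, -6), (1, -5), (2, -5), (2, -3), (3, -2), (2, -1),
            (1, -2), (0, -3), (-1, -5), (-1, -5), (-1, -7), (-2, -9),
        ],
        [  # transition 3 -> 4
            (0, -4), (1, -4), (1, -3), (1, -2), (1, -2), (1, -1), (1, -1),
            (1, -1), (0, -2), (0, -2), (-1, -3), (-1, -4), (-1, -4),
        ],
    ],
    dtype=float,
)

#: Global contraction used by the reference sequence (cumulative over the
#: whole sequence, interpolated per frame).
CONTRACTION_AFFINE = AffineParams(0.92, -0.03, -0.01, 0.89, 20.0, 6.0)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeckleParams:
    """Speckle and log-compression settings.

    ``sigma_tissue``/``sigma_blood`` are the Rayleigh scales of the echo
    envelope in the myocardium and the cavity/background.  ``alpha1`` and
    ``alpha2`` are the log-compression gain and offset mapping the envelope
    to the nominal 0-255 display range; ``smooth_sigma`` is a final display
    Gaussian low-pass in pixels.  ``psf_sigma`` is the standard deviation
    (pixels) of the Gaussian point-spread function applied to the complex
    scattering field before envelope detection: fully developed speckle is
    the modulus of a PSF-filtered complex white Gaussian field, so each
    pixel's envelope is exactly Rayleigh while the texture carries the
    spatial correlation (speckle cell size ~ PSF width) of real B-mode
    images.  ``psf_sigma = 0`` gives pixel-independent speckle.  Defaults
    reproduce the operating point of the reference sequence (tissue/blood
    contrast and self-calibration statistic in its published range); see
    docs/methods.md.
    """

    sigma_tissue: float = 5.0
    sigma_blood: float = 1.5
    alpha1: float = 26.2
    alpha2: float = -10.623  # = -alpha1 * ln(1.5): display floor at envelope 1.5
    smooth_sigma: float = 1.5
    psf_sigma: float = 0.0
    edge_sigma: float = None  # class-boundary blur; default psf_sigma / 2
    annulus_gain: float = 1.4  # valve-plane / annulus echogenicity vs tissue
    valve_sigma: float = 10.0  # blur of the valve-plane region (broad ramp)
    looks: int = 9  # spatial-compounding looks averaged per frame
    seed: int = 0

    def __post_init__(self):
        if self.sigma_tissue <= 0 or self.sigma_blood <= 0:
            raise ValueError("Rayleigh scales must be positive")
        if self.alpha1 <= 0:
            raise ValueError("log-compression gain alpha1 must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be nonnegative")


@dataclass(frozen=True)
class MotionModel:
    """Nonrigid heart motion: cumulative affine + free-form perturbation.

    ``affine`` is the total deformation over the sequence; frame ``k``
    places the endocardial points at ``(1 - f_k) r* + f_k affine(r*)`` for
    interpolation fraction ``f_k``, plus an i.i.d. uniform perturbation of
    each coordinate within ``+- freeform_pct`` of its value (the local
    free-form deformation).  ``wall_thickness`` gives the per-frame endo-epi
    offset in pixels.
    """

    affine: AffineParams = CONTRACTION_AFFINE
    freeform_pct: float = 0.001
    frame_fractions: tuple = (0.0, 0.3, 0.75, 1.0)
    wall_thickness: tuple = (20.0, 20.0 + 5 / 3, 20.0 + 10 / 3, 25.0)
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.frame_fractions, dtype=float)
        if f[0] != 0.0 or f[-1] != 1.0 or np.any(np.diff(f) < 0):
            raise ValueError("frame_fractions must be nondecreasing from 0 to 1")
        if len(self.wall_thickness) != len(f):
            raise ValueError("wall_thickness must give one value per frame")
        if np.any(np.asarray(self.wall_thickness) <= 0):
            raise ValueError("wall thickness must be positive")


@dataclass(frozen=True)
class TemplateParams:
    """Parametric apical-view LV template: a U-shaped cavity whose endocardial
    border is half an ellipse from annulus to annulus over the apex."""

    center_x: float = 186.0
    annulus_y: float = 198.0
    apex_y: float = 71.0
    semi_width: float = 44.0
    wall_thickness: float = 20.0


@dataclass
class SyntheticScene:
    """A generated sequence with full ground truth."""

    frames: np.ndarray  # (T, H, W)
    endo_trajectories: np.ndarray  # (T, n, 2)
    epi_trajectories: np.ndarray  # (T, n, 2)
    displacements: np.ndarray  # (T - 1, n, 2), endocardial ground truth
    masks: list  # per frame: (H, W) label map, 0 background / 1 blood / 2 tissue
    dropout_mask: np.ndarray = None
    speckle: SpeckleParams = None

    @property
    def tissue_mask(self):
        return self.masks[0] == 2

    @property
    def blood_mask(self):
        return self.masks[0] == 1


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit normals of an open contour polyline, oriented away from the
    centroid of the points (outward for a convex-ish cavity)."""
    pts = np.asarray(points, dtype=float)
    tang = np.gradient(pts, axis=0)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    centroid = pts.mean(axis=0)
    sign = np.sign(np.sum(normals * (pts - centroid), axis=1))
    sign[sign == 0] = 1.0
    return normals * sign[:, None]


def offset_contour(endo_points: np.ndarray, thickness: float) -> np.ndarray:
    """Epicardial points: endocardial points pushed outward along normals."""
    return np.asarray(endo_points, dtype=float) + thickness * outward_normals(endo_points)


def contour_masks(
    shape, endo_points, epi_points, samples_k: int = 400,
    valve_polygon=None, papillary_points=None, papillary_radius: float = 9.0,
) -> np.ndarray:
    """Label map from the two contours: 1 = blood cavity (inside the
    endocardial spline, closed by the annulus chord), 2 = myocardial band
    between the endo- and epicardial splines, 3 = echogenic intracavitary
    structures (valve plane / papillary muscles), 0 = background."""
    H, W = shape
    endo = spline_contour(endo_points, samples_k, closed=False)
    epi = spline_contour(epi_points, samples_k, closed=False)

    labels = np.zeros((H, W), dtype=np.uint8)
    band = np.vstack([epi, endo[::-1]])
    rr, cc = draw_polygon(band[:, 1], band[:, 0], shape=(H, W))
    labels[rr, cc] = 2
    rr, cc = draw_polygon(endo[:, 1], endo[:, 0], shape=(H, W))
    labels[rr, cc] = 1
    if valve_polygon is not None:
        vp = np.asarray(valve_polygon, dtype=float)
        rr, cc = draw_polygon(vp[:, 1], vp[:, 0], shape=(H, W))
        labels[rr, cc] = 3
    if papillary_points is not None:
        for p in np.atleast_2d(papillary_points):
            labels[disc_mask(shape, p, papillary_radius)] = 4
    return labels


def make_lv_scene(shape=(336, 320), n_points: int = 13, template: TemplateParams = None):
    """Initial LV geometry: label map plus endo-/epicardial tracking points.

    The endocardial border carries ``n_points`` points spaced uniformly in
    the ellipse parameter from one annulus over the apex to the other;
    epicardial points sit ``wall_thickness`` pixels outward along the
    border normals.

    Returns ``(labels, endo_points, epi_points)``.
    """
    if template is None:
        template = TemplateParams()
    H, W = shape
    s = np.linspace(0.0, 1.0, n_points)
    x = template.center_x - template.semi_width * np.cos(np.pi * s)
    y = template.annulus_y - (template.annulus_y - template.apex_y) * np.sin(np.pi * s)
    endo = np.column_stack([x, y])
    epi = offset_contour(endo, template.wall_thickness)
    all_pts = np.vstack([endo, epi])
    if (
        all_pts[:, 0].min() < 1
        or all_pts[:, 0].max() > W - 2
        or all_pts[:, 1].min() < 1
        or all_pts[:, 1].max() > H - 2
    ):
        raise ValueError(f"LV template does not fit inside a {H}x{W} frame")
    ext = _extend_polyline(endo, 1)
    labels = contour_masks(
        shape, endo, epi, valve_polygon=[endo[0], ext[0], ext[-1], endo[-1]]
    )
    return labels, endo, epi


# ---------------------------------------------------------------------------
# speckle
# ---------------------------------------------------------------------------


def fisher_tippett_pdf(intensity, sigma: float, alpha1: float, alpha2: float):
    """Density of ``I = alpha1 * ln(A) + alpha2`` for ``A ~ Rayleigh(sigma)``.

    By change of variables, ``f(I) = (2 / alpha1) * exp(z - exp(z))`` with
    ``z = 2 (I - alpha2) / alpha1 - ln(2 sigma^2)`` -- the Fisher-Tippett
    (doubly exponential) law of log-compressed fully developed speckle.
    """
    intensity = np.asarray(intensity, dtype=float)
    z = 2.0 * (intensity - alpha2) / alpha1 - np.log(2.0 * sigma**2)
    return (2.0 / alpha1) * np.exp(z - np.exp(z))


def _sigma_map(labels: np.ndarray, params: SpeckleParams) -> np.ndarray:
    """Per-pixel Rayleigh scale: tissue scale on the myocardium label, blood
    scale in the cavity and background, brighter valve-plane/annulus
    structures.  Class boundaries are blurred by ``edge_sigma`` (default:
    half the PSF width): the imaging PSF mixes backscatter across
    interfaces, so echogenicity transitions are gradual, not knife-sharp."""
    sig = np.full(labels.shape, params.sigma_blood, dtype=float)
    sig[labels == 2] = params.sigma_tissue
    edge = params.edge_sigma
    if edge is None:
        edge = 0.5 * params.psf_sigma
    if edge > 0:
        sig = gaussian_filter(sig, edge)
    if np.any(labels == 3):
        # valve plane / atrial structures: a broad echogenic ramp rather than
        # a sharp interface (the region is a mix of leaflets, annulus and
        # atrial wall swept over the cardiac cycle)
        valve = np.where(labels == 3, params.annulus_gain * params.sigma_tissue, 0.0)
        if params.valve_sigma > 0:
            valve = gaussian_filter(valve, params.valve_sigma)
        sig = np.maximum(sig, valve)
    if np.any(labels == 4):
        # papillary/trabecular bodies: echogenic ridges attached to the inner
        # wall, moderately blurred (smaller than the valve-plane sweep)
        pap = np.where(labels == 4, params.annulus_gain * params.sigma_tissue, 0.0)
        pap = gaussian_filter(pap, 4.0)
        sig = np.maximum(sig, pap)
    return sig


def rayleigh_envelope(labels: np.ndarray, params: SpeckleParams, rng=None) -> np.ndarray:
    """Raw (pre-compression) speckle envelope for a class label map.

    Fully developed speckle: a complex circular-Gaussian scattering field is
    filtered with the Gaussian system PSF (``psf_sigma``) and envelope-
    detected.  The filtered components are renormalized to unit variance, so
    after multiplication by the per-pixel class scale every pixel's envelope
    is *exactly* Rayleigh with its class sigma; ``psf_sigma`` only sets the
    spatial correlation (speckle cell size) of the texture.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    H, W = labels.shape
    re = rng.standard_normal((H, W))
    im = rng.standard_normal((H, W))
    if params.psf_sigma > 0:
        re = gaussian_filter(re, params.psf_sigma)
        im = gaussian_filter(im, params.psf_sigma)
        # restore unit component variance (white noise scaled by ||kernel||_2)
        norm = np.sqrt(np.sum(_gaussian_kernel_sq(params.psf_sigma)))
        re /= norm
        im /= norm
    unit = np.hypot(re, im)
    return unit * _sigma_map(labels, params)


def _gaussian_kernel_sq(sigma: float) -> np.ndarray:
    """Squared taps of the (truncated) separable 2D Gaussian kernel that
    scipy's gaussian_filter applies, for exact variance renormalization."""
    radius = int(4.0 * sigma + 0.5)  # scipy default truncate=4.0
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    return k2**2


def log_compress(envelope: np.ndarray, params: SpeckleParams) -> np.ndarray:
    """Log-compression of the envelope to display intensities."""
    return params.alpha1 * np.log(envelope) + params.alpha2


def sample_speckle(
    labels: np.ndarray,
    params: SpeckleParams,
    dropout_mask: np.ndarray = None,
    dropout_factor: float = 1.0,
    rng=None,
) -> np.ndarray:
    """One speckle frame: Rayleigh envelope, optional dropout attenuation,
    log-compression, display clipping and Gaussian low-pass.

    Intensities are clipped to the nonnegative display range *before* the
    final low-pass: envelope nulls whose log-compressed value falls below 0
    render as black, as on a B-mode display (``alpha2`` sets how much of the
    weak-signal tail clips).  With ``looks > 1`` that display image is the
    average of independent speckle realizations (spatial compounding),
    which reduces texture variance by ``1/looks`` while leaving anatomy
    unchanged."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    frame = np.zeros(labels.shape)
    for _ in range(params.looks):
        env = rayleigh_envelope(labels, params, rng=rng)
        if dropout_mask is not None:
            env = env.copy()
            env[np.asarray(dropout_mask, dtype=bool)] *= dropout_factor
        frame += np.clip(log_compress(env, params), 0.0, None)
    frame /= params.looks
    if params.smooth_sigma > 0:
        frame = gaussian_filter(frame, params.smooth_sigma)
    return np.clip(frame, 0.0, None)


def apply_dropout(frame: np.ndarray, mask: np.ndarray, factor: float, alpha1: float):
    """Attenuate the signal inside a static image-space region.

    Multiplying the envelope by ``factor`` shifts the log-compressed
    intensity by ``alpha1 * ln(factor)``; applied post-compression so the
    shadow stays fixed in image coordinates on warped frames.  ``factor=0``
    blanks the region.
    """
    out = np.asarray(frame, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if factor <= 0:
        out[mask] = 0.0
    else:
        out[mask] += alpha1 * np.log(factor)
    return np.clip(out, 0.0, None)


def disc_mask(shape, center, radius: float) -> np.ndarray:
    """Boolean disc mask; ``center`` is (x, y)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# motion and warping
# ---------------------------------------------------------------------------


def simulate_motion(endo_points, model: MotionModel):
    """Node trajectories of the nonrigid motion model.

    Returns ``(endo_traj, epi_traj)``, each (T, n, 2), with
    ``endo_traj[0] == endo_points`` exactly; epicardial points are re-offset
    at each frame's wall thickness along that frame's border normals.
    """
    endo0 = np.asarray(endo_points, dtype=float)
    fractions = np.asarray(model.frame_fractions, dtype=float)
    T = fractions.size
    rng = np.random.default_rng(model.seed)
    moved = model.affine.apply(endo0)

    endo_traj = np.empty((T, endo0.shape[0], 2))
    epi_traj = np.empty_like(endo_traj)
    for k, f in enumerate(fractions):
        pts = (1.0 - f) * endo0 + f * moved
        if k > 0 and model.freeform_pct > 0:
            pts = pts + rng.uniform(-1.0, 1.0, pts.shape) * model.freeform_pct * np.abs(pts)
        endo_traj[k] = pts
        epi_traj[k] = offset_contour(pts, model.wall_thickness[k])
    return endo_traj, epi_traj


def _frame_anchors(shape) -> np.ndarray:
    """Stationary nodes on the frame boundary (corners and edge midpoints)
    keeping the Delaunay mesh defined over the whole image."""
    H, W = shape
    xs = [0.0, (W - 1) / 2.0, W - 1.0]
    ys = [0.0, (H - 1) / 2.0, H - 1.0]
    pts = [(x, y) for x in xs for y in ys if x in (0.0, W - 1.0) or y in (0.0, H - 1.0)]
    return np.array(pts, dtype=float)


def warp_frames(
    base_frame, node_trajectories, add_anchors: bool = True, order: int = 3
) -> np.ndarray:
    """Warp the base frame along node trajectories by piecewise-affine maps.

    Frame ``k`` is produced by the Delaunay piecewise-affine transform that
    moves the frame-0 nodes to their frame-``k`` positions (backward
    mapping); each frame is warped directly from the base frame so
    interpolation blur does not compound.  Resampling uses cubic spline
    interpolation by default (``order=1`` for bilinear); the geometric maps
    per triangle are affine either way.  Stationary anchor nodes on the
    frame boundary are added unless ``add_anchors=False``.
    """
    base = np.asarray(base_frame, dtype=float)
    traj = np.asarray(node_trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[2] != 2:
        raise ValueError("node_trajectories must be (T, N, 2)")
    T = traj.shape[0]
    anchors = _frame_anchors(base.shape) if add_anchors else np.zeros((0, 2))

    frames = np.empty((T,) + base.shape)
    frames[0] = base
    nodes0 = np.vstack([traj[0], anchors])
    for k in range(1, T):
        nodes_k = np.vstack([traj[k], anchors])
        # warp() treats the transform as the map output -> input coordinates
        try:
            tform = PiecewiseAffineTransform.from_estimate(nodes_k, nodes0)
        except Exception as exc:
            raise ValueError(f"degenerate node mesh at frame {k}: {exc}") from exc
        if not tform:
            raise ValueError(
                f"degenerate Delaunay triangle in the node mesh of frame {k}"
            )
        frames[k] = warp(base, tform, order=order, mode="edge", preserve_range=True)
    return frames


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------


def _extend_polyline(pts: np.ndarray, n_ext: int = 2) -> np.ndarray:
    """Continue an open polyline linearly beyond both ends (``n_ext`` extra
    points per end at the spacing of the terminal segments)."""
    pre = [pts[0] + k * (pts[0] - pts[1]) for k in range(n_ext, 0, -1)]
    post = [pts[-1] + k * (pts[-1] - pts[-2]) for k in range(1, n_ext + 1)]
    return np.vstack([pre, pts, post])


def _assemble_scene(
    endo_traj, thickness, shape, speckle, dropout_mask, dropout_factor, seed, n_ext=2
):
    """Common scene assembly from endocardial node trajectories.

    The myocardial band does not end at the mitral annulus: both contours
    are continued linearly beyond the two end points, and the extension
    nodes follow the per-frame least-squares affine motion of the tracked
    nodes, so texture below the valve plane moves coherently with the base
    instead of being pinned to the static background mesh.
    """
    from .core import affine_coefficients, build_design_matrix

    endo_traj = np.asarray(endo_traj, dtype=float)
    T, n = endo_traj.shape[:2]
    if speckle is None:
        speckle = SpeckleParams(seed=seed)

    phi0 = build_design_matrix(endo_traj[0])
    ext0 = _extend_polyline(endo_traj[0], n_ext)
    ext_endo = np.empty((T, n + 2 * n_ext, 2))
    ext_epi = np.empty_like(ext_endo)
    for k in range(T):
        aff = affine_coefficients(phi0, endo_traj[k])
        ext_k = aff.apply(ext0)
        # carry each end node's off-affine residual into its extension chain
        # so the motion field is continuous across the junction
        ext_k[:n_ext] += endo_traj[k][0] - aff.apply(endo_traj[0][:1])[0]
        ext_k[n_ext + n :] += endo_traj[k][-1] - aff.apply(endo_traj[0][-1:])[0]
        ext_k[n_ext : n_ext + n] = endo_traj[k]  # tracked nodes stay verbatim
        ext_endo[k] = ext_k
        ext_epi[k] = offset_contour(ext_k, thickness[k])

    # intracavitary anatomy moving with the walls: the valve plane spanning
    # the cavity below the annulus chord, and papillary bodies at mid-level
    # just inside the endocardial border
    # papillary/trabecular bodies hugging the inner border at every interior
    # tracking point: echogenic intracavitary relief whose edges carry
    # along-wall motion information symmetrically about each point
    centroids = endo_traj.mean(axis=1)
    pap_idx = list(range(1, n - 1))
    pap = [
        np.vstack([0.8 * endo_traj[k][i] + 0.2 * centroids[k] for i in pap_idx])
        for k in range(T)
    ]
    masks = [
        contour_masks(
            shape, ext_endo[k], ext_epi[k],
            valve_polygon=[
                endo_traj[k][0], ext_endo[k][0],
                ext_endo[k][-1], endo_traj[k][-1],
            ],
            papillary_points=pap[k],
            papillary_radius=10.0,
        )
        for k in range(T)
    ]
    rng = np.random.default_rng(seed)
    base = sample_speckle(masks[0], speckle, rng=rng)
    nodes = np.concatenate([ext_endo, ext_epi], axis=1)
    frames = warp_frames(base, nodes)
    if dropout_mask is not None:
        for k in range(T):
            frames[k] = apply_dropout(frames[k], dropout_mask, dropout_factor, speckle.alpha1)
    return SyntheticScene(
        frames=frames,
        endo_trajectories=endo_traj,
        epi_trajectories=ext_epi[:, n_ext : n_ext + n],
        displacements=np.diff(endo_traj, axis=0),
        masks=masks,
        dropout_mask=dropout_mask,
        speckle=speckle,
    )


def make_scene(
    shape=(336, 320),
    n_points: int = 13,
    template: TemplateParams = None,
    motion: MotionModel = None,
    speckle: SpeckleParams = None,
    dropout_mask=None,
    dropout_factor: float = 1.0,
    seed: int = 0,
) -> SyntheticScene:
    """Generate a full synthetic sequence from the parametric LV template."""
    if motion is None:
        motion = MotionModel(seed=seed)
    _, endo0, _ = make_lv_scene(shape, n_points, template)
    endo_traj, _ = simulate_motion(endo0, motion)
    return _assemble_scene(
        endo_traj, np.asarray(motion.wall_thickness, dtype=float),
        shape, speckle, dropout_mask, dropout_factor, seed,
    )


def table1_fixture(
    seed: int = 0,
    speckle: SpeckleParams = None,
    shape=(336, 320),
    dropout_mask=None,
    dropout_factor: float = 1.0,
) -> SyntheticScene:
    """The reference 4-frame, 13-point sequence.

    Endocardial node trajectories are the published per-frame coordinates
    verbatim; the ground-truth displacements are the published displacement
    table.  Epicardial nodes are offset outward with the wall thickness
    growing linearly from 20 to 25 pixels over the sequence.
    """
    endo_traj = TABLE1_POINTS.copy()
    T = endo_traj.shape[0]
    thickness = np.linspace(20.0, 25.0, T)
    scene = _assemble_scene(
        endo_traj, thickness, shape, speckle, dropout_mask, dropout_factor, seed
    )
    scene.displacements = TABLE1_DISPLACEMENTS.copy()
    return scene


def contrast_sweep(
    tissue_sigmas,
    shape=(192, 256),
    n_points: int = 13,
    template: TemplateParams = None,
    speckle: SpeckleParams = None,
    window=None,
    seed: int = 0,
):
    """Sweep the tissue Rayleigh scale and record (contrast, lambda_tilde).

    For each tissue scale a two-frame scene (half of the default
    contraction) is generated; the contrast ratio is measured on the first
    frame's masks and lambda_tilde on the transition using the ground-truth
    node displacements.  Returns ``(contrasts, lambda_tildes)`` arrays.
    """
    from .calibration import contrast_ratio, lambda_tilde
    from .core import gaussian_window

    if window is None:
        window = gaussian_window(21, 5.0)
    if speckle is None:
        speckle = SpeckleParams(seed=seed)
    if template is None:
        template = TemplateParams(
            center_x=shape[1] * 0.58,
            annulus_y=shape[0] * 0.78,
            apex_y=shape[0] * 0.28,
            semi_width=shape[1] * 0.14,
        )
    # one transition of half the reference contraction
    identity = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    half = AffineParams(
        *(identity + 0.5 * (np.array(CONTRACTION_AFFINE.as_tuple()) - identity))
    )
    motion = MotionModel(
        affine=half,
        frame_fractions=(0.0, 1.0),
        wall_thickness=(20.0, 21.0),
        seed=seed,
    )
    contrasts = []
    lts = []
    for i, sig_t in enumerate(tissue_sigmas):
        sp = SpeckleParams(
            sigma_tissue=float(sig_t),
            sigma_blood=speckle.sigma_blood,
            alpha1=speckle.alpha1,
            alpha2=speckle.alpha2,
            smooth_sigma=speckle.smooth_sigma,
            seed=seed + i,
        )
        scene = make_scene(
            shape=shape,
            n_points=n_points,
            template=template,
            motion=motion,
            speckle=sp,
            seed=seed + i,
        )
        # core-region masks: erode away boundary blur and the halos of the
        # intracavitary structures so the ratio reflects the two tissue classes
        from scipy.ndimage import binary_dilation, binary_erosion

        labels0 = scene.masks[0]
        tissue = binary_erosion(labels0 == 2, iterations=3)
        blood = binary_erosion(
            (labels0 == 1) & ~binary_dilation(labels0 >= 3, iterations=12),
            iterations=3,
        )
        contrasts.append(contrast_ratio(scene.frames[0], tissue, blood))
        lts.append(
            lambda_tilde(
                scene.frames[0],
                scene.frames[1],
                scene.endo_trajectories[0],
                scene.displacements[0],
                window,
            )
        )
    return np.asarray(contrasts), np.asarray(lts)
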