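"""Shape-constrained Lucas-Kanade tracking of a left-ventricle border.

The tracker moves ``n`` contour points from frame to frame by minimizing, for
each frame pair, an energy that couples

* a windowed Lucas-Kanade optical-flow term per point (brightness constancy
  ``u . grad(I) + dI/dt ~ 0`` over a Gaussian-weighted neighborhood), and
* a global shape term penalizing the distance of the displaced configuration
  from the affine shape space ``W`` -- the set of affine transforms of the
  initial point configuration.

The stationarity conditions form one symmetric ``2n x 2n`` linear system per
frame pair which is solved directly; there is no contour evolution loop.

Coordinate convention: points are ``(x, y) = (column, row)``, 0-based, with
``y`` increasing downward.  Positions are kept at subpixel precision; images
are sampled by bilinear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.ndimage import map_coordinates

__all__ = [
    "SingularShapeError",
    "WindowSpec",
    "ContourState",
    "ShapeBasis",
    "AffineParams",
    "PointLocalSystem",
    "GlobalSystem",
    "TrackerConfig",
    "Trajectory",
    "gaussian_window",
    "image_derivatives",
    "local_system",
    "build_design_matrix",
    "projection_matrix",
    "affine_coefficients",
    "solve_step",
    "track_sequence",
]

#: condition-number estimate above which the global solve is regularized
COND_LIMIT = 1e12


class SingularShapeError(ValueError):
    """Raised when the initial points span no 2D affine shape space
    (collinear or duplicated points make ``Phi^T Phi`` singular)."""


# ---------------------------------------------------------------------------
# windows and image derivatives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """Square sampling window with isotropic Gaussian weights.

    The weight scale trades off directly against the regularization
    parameter ``lam``, so the normalization is a fixed package convention:
    by default the weights are *unnormalized* (peak value 1, as a plain
    Gaussian bump; a 21x21, sigma 5 window then has total weight ~ 150).
    All reported ``lam`` values (e.g. the default 300) assume this
    convention; ``gaussian_window(..., normalize="sum")`` gives unit-sum
    weights, under which every lam must be divided by the window's total
    weight to describe the same tracker.
    """

    side: int
    sigma: float
    weights: np.ndarray  # (side, side)
    offsets: np.ndarray = field(repr=False, default=None)  # (side**2, 2) as (dx, dy)

    def __post_init__(self):
        if self.offsets is None:
            h = self.side // 2
            dx, dy = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1))
            object.__setattr__(
                self, "offsets", np.column_stack([dx.ravel(), dy.ravel()]).astype(float)
            )


def gaussian_window(side: int, sigma: float, normalize: str = "peak") -> WindowSpec:
    """Centered 2D Gaussian weights on an odd ``side x side`` grid.

    Parameters
    ----------
    side
        Odd window side length in pixels (default elsewhere: 21).
    sigma
        Gaussian standard deviation in pixels (default elsewhere: 5).
    normalize
        ``"peak"`` (default, center weight 1 -- the package convention that
        all quoted ``lam`` values assume) or ``"sum"`` (unit total weight).
    """
    if side % 2 == 0 or side < 3:
        raise ValueError(f"window side must be odd and >= 3, got {side}")
    if sigma <= 0:
        raise ValueError(f"window sigma must be positive, got {sigma}")
    if normalize not in ("peak", "sum"):
        raise ValueError(f"normalize must be 'peak' or 'sum', got {normalize!r}")
    h = side // 2
    ax = np.arange(-h, h + 1, dtype=float)
    dx, dy = np.meshgrid(ax, ax)
    w = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    if normalize == "sum":
        w = w / w.sum()
    return WindowSpec(side=side, sigma=float(sigma), weights=w)


def _as_float_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D grayscale frame, got shape {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    return frame


def image_derivatives(frame_t: np.ndarray, frame_next: np.ndarray):
    """Spatial gradient and the two-frame temporal difference.

    The spatial gradient is the average of the central-difference gradients
    of the two frames (one-sided at image borders).  Centering the gradient
    between the frames matches the forward temporal difference and keeps the
    brightness-constancy linearization accurate to second order in the
    displacement, which matters for the larger inter-frame motions near
    end-diastole.

    Returns
    -------
    grad : (H, W, 2) array
        ``grad[..., 0] = dI/dx`` and ``grad[..., 1] = dI/dy``.
    temporal : (H, W) array
        ``frame_next - frame_t``.
    """
    frame_t = _as_float_frame(frame_t)
    frame_next = _as_float_frame(frame_next)
    if frame_t.shape != frame_next.shape:
        raise ValueError(
            f"frame shapes differ: {frame_t.shape} vs {frame_next.shape}"
        )
    gy0, gx0 = np.gradient(frame_t)
    gy1, gx1 = np.gradient(frame_next)
    grad = np.stack([0.5 * (gx0 + gx1), 0.5 * (gy0 + gy1)], axis=-1)
    temporal = frame_next - frame_t
    return grad, temporal


# ---------------------------------------------------------------------------
# local (per-point) optical-flow systems
# ---------------------------------------------------------------------------


@dataclass
class PointLocalSystem:
    """Windowed optical-flow terms around one tracking point.

    ``grad_rows`` (the rows of ``A_j``), ``weights`` (diagonal of ``W_j``)
    and ``temporal`` (``b_j``) are restricted to window samples that fall
    inside the image; weights are renormalized over the surviving samples.
    ``alpha, beta, gamma`` are the entries of ``A^T W A + lam*I`` and
    ``xi, eta`` those of ``A^T W b + lam*r``.
    """

    grad_rows: np.ndarray  # (m_valid, 2)
    weights: np.ndarray  # (m_valid,)
    temporal: np.ndarray  # (m_valid,)
    alpha: float
    beta: float
    gamma: float
    xi: float
    eta: float
    out_of_image: bool = False


def _bilinear(field2d: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return map_coordinates(field2d, np.vstack([y, x]), order=1, mode="nearest")


def local_system(
    grad: np.ndarray,
    temporal: np.ndarray,
    point,
    window: WindowSpec,
    lam: float,
    current_point=None,
) -> PointLocalSystem:
    """Assemble the weighted normal-equation terms of one point's window.

    ``point`` is the sampling center (subpixel allowed); ``current_point``
    is the position entering the ``lam * r_j(t)`` term and defaults to
    ``point``.  Window samples outside the image are dropped and the
    remaining weights renormalized to unit sum; a point entirely outside the
    image yields a purely shape-driven system (all data terms zero) with
    ``out_of_image=True``.
    """
    point = np.asarray(point, dtype=float)
    if current_point is None:
        current_point = point
    current_point = np.asarray(current_point, dtype=float)
    H, W = temporal.shape

    pos = point[None, :] + window.offsets
    x, y = pos[:, 0], pos[:, 1]
    valid = (x >= 0) & (x <= W - 1) & (y >= 0) & (y <= H - 1)

    if not valid.any():
        zero = np.zeros(0)
        return PointLocalSystem(
            grad_rows=np.zeros((0, 2)),
            weights=zero,
            temporal=zero,
            alpha=lam,
            beta=0.0,
            gamma=lam,
            xi=lam * current_point[0],
            eta=lam * current_point[1],
            out_of_image=True,
        )

    # clipped windows keep the full window's total weight so the data-term
    # scale (hence the lam trade-off) stays comparable near borders
    w = window.weights.ravel()[valid]
    w = w * (window.weights.sum() / w.sum())
    xv, yv = x[valid], y[valid]
    gx = _bilinear(grad[..., 0], xv, yv)
    gy = _bilinear(grad[..., 1], xv, yv)
    bt = _bilinear(temporal, xv, yv)

    alpha = float(np.sum(w * gx * gx)) + lam
    beta = float(np.sum(w * gx * gy))
    gamma = float(np.sum(w * gy * gy)) + lam
    xi = float(np.sum(w * gx * bt)) + lam * current_point[0]
    eta = float(np.sum(w * gy * bt)) + lam * current_point[1]

    return PointLocalSystem(
        grad_rows=np.column_stack([gx, gy]),
        weights=w,
        temporal=bt,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        xi=xi,
        eta=eta,
    )


# ---------------------------------------------------------------------------
# shape space
# ---------------------------------------------------------------------------


def build_design_matrix(initial_points) -> np.ndarray:
    """Design matrix ``Phi`` of the affine shape space: row i = (x*_i, y*_i, 1)."""
    pts = np.asarray(initial_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to span an affine shape space, got {n}")
    return np.column_stack([pts, np.ones(n)])


def projection_matrix(phi: np.ndarray) -> np.ndarray:
    """Orthogonal projector ``P = Phi (Phi^T Phi)^{-1} Phi^T`` onto col(Phi).

    ``P`` is symmetric, idempotent and has trace 3 (the dimension of the
    affine shape space).  Its entries ``d(i, j)`` couple the tracking points
    in the global solve.
    """
    phi = np.asarray(phi, dtype=float)
    gram = phi.T @ phi
    # rank check: collinear or duplicated points collapse the shape space
    if np.linalg.matrix_rank(phi, tol=1e-9 * max(1.0, np.abs(phi).max())) < 3:
        raise SingularShapeError(
            "initial points are collinear or duplicated; they span no 2D "
            "affine shape space (Phi^T Phi is singular)"
        )
    return phi @ linalg.solve(gram, phi.T, assume_a="pos")


@dataclass
class ShapeBasis:
    """Affine shape space of the initial contour: ``Phi`` and projector ``P``."""

    phi: np.ndarray  # (n, 3)
    proj: np.ndarray  # (n, n)

    @classmethod
    def from_points(cls, initial_points) -> "ShapeBasis":
        phi = build_design_matrix(initial_points)
        return cls(phi=phi, proj=projection_matrix(phi))


@dataclass(frozen=True)
class AffineParams:
    """Affine map ``x' = a1 x + a2 y + a5``, ``y' = a3 x + a4 y + a6``."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        A = np.array([[self.a1, self.a2], [self.a3, self.a4]])
        b = np.array([self.a5, self.a6])
        return pts @ A.T + b

    def as_tuple(self):
        return (self.a1, self.a2, self.a3, self.a4, self.a5, self.a6)


def affine_coefficients(phi: np.ndarray, target_points) -> AffineParams:
    """Least-squares affine map from the initial points (rows of ``Phi``)
    onto ``target_points``.

    Solves ``(Phi^T Phi) C = Phi^T targets`` for the 3x2 coefficient block
    ``C = [[a1, a3], [a2, a4], [a5, a6]]``; ``Phi @ C`` is then the
    projection of the targets onto the affine shape space.
    """
    phi = np.asarray(phi, dtype=float)
    targets = np.asarray(target_points, dtype=float)
    if targets.shape != (phi.shape[0], 2):
        raise ValueError(
            f"targets shape {targets.shape} does not match {phi.shape[0]} points"
        )
    if np.linalg.matrix_rank(phi, tol=1e-9 * max(1.0, np.abs(phi).max())) < 3:
        raise SingularShapeError(
            "initial points are collinear or duplicated; affine fit is underdetermined"
        )
    C = linalg.solve(phi.T @ phi, phi.T @ targets, assume_a="pos")
    return AffineParams(
        a1=C[0, 0], a2=C[1, 0], a3=C[0, 1], a4=C[1, 1], a5=C[2, 0], a6=C[2, 1]
    )


# ---------------------------------------------------------------------------
# global coupled solve
# ---------------------------------------------------------------------------


@dataclass
class ContourState:
    """Initial (reference) and current positions of the n tracking points."""

    initial_points: np.ndarray  # (n, 2)
    current_points: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.initial_points = np.asarray(self.initial_points, dtype=float)
        self.current_points = np.asarray(self.current_points, dtype=float)
        if self.initial_points.shape != self.current_points.shape:
            raise ValueError("initial and current points must have the same shape")
        if self.initial_points.ndim != 2 or self.initial_points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.initial_points.shape[0] < 3:
            raise ValueError("need at least 3 tracking points")

    @property
    def n(self) -> int:
        return self.initial_points.shape[0]


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker settings: regularization weight and sampling window.

    ``lam >= 0`` balances the per-point optical-flow terms against the
    affine shape constraint; ``lam = 0`` decouples the system into plain
    windowed Lucas-Kanade solves.
    """

    lam: float = 300.0
    window: WindowSpec = None
    interpolation: str = "bilinear"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")
        if self.window is None:
            object.__setattr__(self, "window", gaussian_window(21, 5.0))


@dataclass
class GlobalSystem:
    """Assembled 2n x 2n block system of one tracking step (for inspection)."""

    lam_diag: np.ndarray
    b_diag: np.ndarray
    gam_diag: np.ndarray
    xi_vec: np.ndarray
    eta_vec: np.ndarray
    x_vec: np.ndarray
    y_vec: np.ndarray
    matrix: np.ndarray
    rhs: np.ndarray
    solution_u: np.ndarray = None
    solution_v: np.ndarray = None


def assemble_global_system(
    frame_t, frame_next, contour: ContourState, shape: ShapeBasis, config: TrackerConfig
) -> GlobalSystem:
    """Build the coupled block system

    ``[[Lam - lam*P, B], [B, Gam - lam*P]] [U; V] = [-Xi + lam*P X; -Pi + lam*P Y]``

    from the per-point local systems (Lam, B, Gam diagonal; P the affine
    projector of the initial contour).
    """
    grad, temporal = image_derivatives(frame_t, frame_next)
    pts = contour.current_points
    n = contour.n
    lam = config.lam

    alphas = np.empty(n)
    betas = np.empty(n)
    gammas = np.empty(n)
    xis = np.empty(n)
    etas = np.empty(n)
    out_flags = np.zeros(n, dtype=bool)
    for j in range(n):
        ls = local_system(grad, temporal, pts[j], config.window, lam, pts[j])
        alphas[j], betas[j], gammas[j] = ls.alpha, ls.beta, ls.gamma
        xis[j], etas[j] = ls.xi, ls.eta
        out_flags[j] = ls.out_of_image
    if out_flags.any():
        warnings.warn(
            f"{int(out_flags.sum())} tracking point(s) left the image; "
            "their motion is driven by the shape constraint alone",
            RuntimeWarning,
            stacklevel=2,
        )

    P = shape.proj
    X, Y = pts[:, 0], pts[:, 1]
    top_left = np.diag(alphas) - lam * P
    bot_right = np.diag(gammas) - lam * P
    B = np.diag(betas)
    matrix = np.block([[top_left, B], [B, bot_right]])
    rhs = np.concatenate([-xis + lam * (P @ X), -etas + lam * (P @ Y)])
    sys = GlobalSystem(
        lam_diag=alphas,
        b_diag=betas,
        gam_diag=gammas,
        xi_vec=xis,
        eta_vec=etas,
        x_vec=X,
        y_vec=Y,
        matrix=matrix,
        rhs=rhs,
    )
    sys.out_of_image = out_flags
    return sys


def solve_step(
    frame_t, frame_next, contour: ContourState, shape: ShapeBasis, config: TrackerConfig
):
    """One tracking step: solve the coupled system for displacements (U, V).

    Returns ``(displacements, updated_contour)`` where ``displacements`` is
    an (n, 2) array and the updated contour keeps subpixel precision.  An
    ill-conditioned system (condition estimate above ``COND_LIMIT``, e.g.
    textureless windows at ``lam = 0``) triggers a warning and a small
    diagonal Tikhonov bump before the solve.
    """
    sys = assemble_global_system(frame_t, frame_next, contour, shape, config)
    n = contour.n
    M, rhs = sys.matrix, sys.rhs
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        bump = 1e-8 * np.trace(M) / (2 * n)
        if bump <= 0 or not np.isfinite(bump):
            bump = 1e-8
        warnings.warn(
            f"global system condition estimate {cond:.3g} exceeds {COND_LIMIT:.0e}; "
            f"regularizing diagonal by {bump:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        M = M + bump * np.eye(2 * n)
    sol = linalg.solve(M, rhs, assume_a="sym")
    sys.solution_u, sys.solution_v = sol[:n], sol[n:]
    disp = np.column_stack([sol[:n], sol[n:]])
    updated = ContourState(
        initial_points=contour.initial_points,
        current_points=contour.current_points + disp,
    )
    return disp, updated


@dataclass
class Trajectory:
    """Tracked positions over T frames and the per-transition displacements.

    Invariant: ``points[t + 1] == points[t] + displacements[t]`` exactly.
    """

    points: np.ndarray  # (T, n, 2)
    displacements: np.ndarray  # (T - 1, n, 2)
    lam_used: float

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]


def track_sequence(frames, initial_points, config: TrackerConfig) -> Trajectory:
    """Track the contour through an ordered frame stack.

    ``frames`` is a (T, H, W) array or list of equally shaped 2D frames with
    T >= 2; ``initial_points`` are the (n, 2) positions on frame 0.  The
    shape basis is built once from the initial points and reused for every
    frame pair.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    shape0 = frames[0].shape
    for k, f in enumerate(frames):
        if f.shape != shape0:
            raise ValueError(f"frame {k} shape {f.shape} differs from {shape0}")

    contour = ContourState(
        initial_points=np.asarray(initial_points, dtype=float),
        current_points=np.asarray(initial_points, dtype=float),
    )
    shape = ShapeBasis.from_points(contour.initial_points)

    T = len(frames)
    n = contour.n
    points = np.empty((T, n, 2))
    disps = np.empty((T - 1, n, 2))
    points[0] = contour.current_points
    for t in range(T - 1):
        disp, contour = solve_step(frames[t], frames[t + 1], contour, shape, config)
        disps[t] = disp
        points[t + 1] = points[t] + disp
        contour.current_points = points[t + 1]  # enforce exact invariant
    return Trajectory(points=points, displacements=disps, lam_used=config.lam)
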