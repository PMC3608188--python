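"""Self-calibration of the shape-regularization weight ``lambda``.

Given a frame pair and reference point displacements (manual delineations or
simulator ground truth), the statistic ``lambda_tilde`` is the ratio of the
stacked Lucas-Kanade residuals to the stacked shape-space residuals,

    lambda_tilde = sqrt( sum_j || (A_j^T W_j A_j) u_j + A_j^T W_j b_j ||^2 )
                   / sqrt( sum_j || r_j + u_j - sum_i d(i,j)(r_i + u_i) ||^2 ),

i.e. a ratio of Frobenius norms.  The local terms are lambda-free by
construction (the statistic exists to *choose* lambda).  The normalization
is fixed by the consistency requirement: at a stationary point of the
coupled tracking energy the LK residual of every point equals ``-lambda``
times its shape residual, so reference displacements that solve the coupled
system for some lambda give back exactly that lambda.  (A ratio of *squared*
norms would return lambda**2 and could not be fed back as the weight.)

Empirically lambda_tilde depends mainly on the tissue/blood intensity
contrast of the sequence, nearly linearly as ``log10(lambda_tilde) =
slope * ln(I_tissue / I_blood) + intercept``; fitting that law on simulated
sweeps gives a way to pick lambda for a new sequence from its contrast alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    WindowSpec,
    build_design_matrix,
    image_derivatives,
    local_system,
    projection_matrix,
)

__all__ = [
    "LambdaEstimate",
    "ContrastLaw",
    "lambda_tilde",
    "lambda_for_sequence",
    "contrast_ratio",
    "fit_contrast_law",
    "choose_lambda",
    "choose_lambda_from_law",
]


@dataclass
class LambdaEstimate:
    """Per-transition lambda_tilde values, their mean, and optional contrast."""

    per_pair: np.ndarray
    mean: float
    contrast: float = np.nan


@dataclass
class ContrastLaw:
    """Linear law ``log10(lambda_tilde) = slope * ln(contrast) + intercept``."""

    slope: float
    intercept: float


def lambda_tilde(
    frame_t,
    frame_next,
    ref_points_t,
    ref_displacements,
    window: WindowSpec,
    initial_points=None,
) -> float:
    """Evaluate the self-calibration statistic for one frame transition.

    Parameters
    ----------
    ref_points_t, ref_displacements
        (n, 2) reference positions on ``frame_t`` and their reference
        displacements to the next frame.
    initial_points
        Points defining the affine shape space (defaults to
        ``ref_points_t``, i.e. the annotated contour of this frame).

    Raises
    ------
    ZeroDivisionError
        If the displaced reference points lie exactly in the affine shape
        space, where the statistic is undefined.
    """
    pts = np.asarray(ref_points_t, dtype=float)
    disp = np.asarray(ref_displacements, dtype=float)
    if pts.shape != disp.shape or pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points and displacements must both be (n, 2) arrays")
    if initial_points is None:
        initial_points = pts

    grad, temporal = image_derivatives(frame_t, frame_next)
    num = 0.0
    for j in range(pts.shape[0]):
        ls = local_system(grad, temporal, pts[j], window, lam=0.0)
        M = np.array([[ls.alpha, ls.beta], [ls.beta, ls.gamma]])
        c = np.array([ls.xi, ls.eta])
        num += float(np.sum((M @ disp[j] + c) ** 2))

    P = projection_matrix(build_design_matrix(initial_points))
    targets = pts + disp
    resid = targets - P @ targets
    den = float(np.sum(resid**2))
    if den <= 1e-12 * max(1.0, float(np.sum(targets**2))):
        raise ZeroDivisionError(
            "displaced reference points are affine-consistent with the initial "
            "contour; lambda_tilde is undefined for this frame pair"
        )
    return float(np.sqrt(num / den))


def lambda_for_sequence(
    frames, trajectory_points, window: WindowSpec, initial_points=None
) -> LambdaEstimate:
    """lambda_tilde per transition of an annotated sequence, and their mean.

    ``trajectory_points`` is a (T, n, 2) array of reference point positions
    on each frame; displacements are taken as consecutive differences.
    """
    traj = np.asarray(trajectory_points, dtype=float)
    frames = [np.asarray(f, dtype=float) for f in frames]
    if traj.shape[0] != len(frames):
        raise ValueError("one set of reference points per frame is required")
    if initial_points is None:
        initial_points = traj[0]
    vals = np.array(
        [
            lambda_tilde(
                frames[t],
                frames[t + 1],
                traj[t],
                traj[t + 1] - traj[t],
                window,
                initial_points=initial_points,
            )
            for t in range(len(frames) - 1)
        ]
    )
    return LambdaEstimate(per_pair=vals, mean=float(vals.mean()))


def contrast_ratio(image, tissue_mask, blood_mask) -> float:
    """Mean intensity over the tissue mask divided by the mean over blood."""
    image = np.asarray(image, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    if not tissue_mask.any() or not blood_mask.any():
        raise ValueError("tissue and blood masks must both be nonempty")
    if np.any(tissue_mask & blood_mask):
        raise ValueError("tissue and blood masks must be disjoint")
    return float(image[tissue_mask].mean() / image[blood_mask].mean())


def fit_contrast_law(contrasts, lambda_tildes) -> ContrastLaw:
    """OLS fit of ``log10(lambda_tilde)`` on ``ln(contrast)``."""
    contrasts = np.asarray(contrasts, dtype=float)
    lts = np.asarray(lambda_tildes, dtype=float)
    if contrasts.shape != lts.shape or contrasts.ndim != 1:
        raise ValueError("contrasts and lambda_tildes must be equal-length 1D")
    if np.unique(contrasts).size < 2:
        raise ValueError("need at least 2 distinct contrast values")
    if np.any(lts <= 0) or np.any(contrasts <= 0):
        raise ValueError("contrasts and lambda_tildes must be positive")
    slope, intercept = np.polyfit(np.log(contrasts), np.log10(lts), 1)
    return ContrastLaw(slope=float(slope), intercept=float(intercept))


def choose_lambda(lambda_tildes) -> float:
    """Per-sequence lambda: the mean of per-transition lambda_tilde values."""
    lts = np.asarray(lambda_tildes, dtype=float)
    if lts.size == 0:
        raise ValueError("need at least one lambda_tilde value")
    return float(lts.mean())


def choose_lambda_from_law(law: ContrastLaw, contrast: float) -> float:
    """lambda predicted by the contrast law: ``10**(slope*ln(c) + intercept)``."""
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    return float(10.0 ** (law.slope * np.log(contrast) + law.intercept))
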