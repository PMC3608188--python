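"""Contour interpolation and tracking-quality metrics.

* natural cubic spline through the tracking points (chord-length
  parameterization) to turn point sets into dense contours,
* Hausdorff distance between two dense contours,
* forward-backward sequence construction (a palindromic cycle) and the
  forward-backward point tracking error (FBTE): track through one cardiac
  cycle and back through the time-reversed frames; a drift-free tracker
  returns every point to its start.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "spline_contour",
    "hausdorff_distance",
    "forward_backward_sequence",
    "fbte",
    "FBResult",
]

from dataclasses import dataclass


@dataclass
class FBResult:
    """Outcome of a forward-backward tracking run."""

    initial: np.ndarray  # (n, 2)
    returning: np.ndarray  # (n, 2)
    fbte: float
    t_r: int  # frame index of the cycle end


def spline_contour(points, samples_k: int = 500, closed: bool = False) -> np.ndarray:
    """Dense polyline through control points via a natural cubic spline.

    Uses chord-length parameterization; the sample parameters are a uniform
    grid merged with the control-point parameters, so every control point is
    hit exactly (the output may hold slightly more than ``samples_k``
    points).  ``closed=True`` uses a periodic spline through the wrapped
    point list.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of control points")
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicated consecutive control points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    bc = "periodic" if closed else "natural"
    sx = CubicSpline(t, pts[:, 0], bc_type=bc)
    sy = CubicSpline(t, pts[:, 1], bc_type=bc)
    tt = np.unique(np.concatenate([np.linspace(0.0, t[-1], samples_k), t]))
    return np.column_stack([sx(tt), sy(tt)])


def hausdorff_distance(c1, c2) -> float:
    """Symmetric Hausdorff distance between two sampled contours (pixels)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("contours must be nonempty")
    return max(directed_hausdorff(c1, c2)[0], directed_hausdorff(c2, c1)[0])


def forward_backward_sequence(frames) -> np.ndarray:
    """Palindromic sequence: the cycle followed by its time reversal.

    ``T`` input frames yield ``2T - 1`` output frames; frame ``2 t_R - t``
    equals frame ``t`` and the last frame equals the first.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T >= 2, H, W) frame stack")
    return np.concatenate([frames, frames[-2::-1]], axis=0)


def fbte(initial_points, returning_points, rms: bool = False) -> float:
    """Forward-backward point tracking error.

    Mean over points of the squared Euclidean distance between the initial
    and the returning positions (the printed definition); ``rms=True``
    returns its square root, a distance in pixels.
    """
    a = np.asarray(initial_points, dtype=float)
    b = np.asarray(returning_points, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    val = float(np.mean(np.sum((a - b) ** 2, axis=1)))
    return float(np.sqrt(val)) if rms else val
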