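"""Conventional point trackers used for comparison.

Three local methods that estimate each tracking point's motion independently:

* windowed Lucas-Kanade optical flow (weighted 2x2 normal equations),
* block matching minimizing the weighted sum-of-squared differences (SSD),
* block matching maximizing the normalized cross-correlation coefficient
  (raw correlation as printed in the region-based tracking literature,
  without mean subtraction -- invariant to intensity gain, not to offset).

Block matching searches integer displacements exhaustively; displacements
are accumulated on subpixel point state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, WindowSpec, gaussian_window, image_derivatives, local_system

__all__ = ["SearchSpec", "lk_track_step", "block_match", "track_sequence_baseline"]


@dataclass(frozen=True)
class SearchSpec:
    """Exhaustive integer search over ``|u|_inf <= radius`` with a square block."""

    radius: int = 10
    block: WindowSpec = None

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"search radius must be >= 1, got {self.radius}")
        if self.block is None:
            object.__setattr__(self, "block", gaussian_window(21, 5.0))


def lk_track_step(frame_t, frame_next, points, window: WindowSpec):
    """Per-point windowed Lucas-Kanade solve.

    Solves ``(A^T W A) u = -A^T W b`` independently for each point.  A
    (near-)singular structure tensor -- textureless window -- yields
    displacement (0, 0) and a degeneracy flag for that point.

    Returns ``(displacements, degenerate_flags)``.
    """
    grad, temporal = image_derivatives(frame_t, frame_next)
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    disp = np.zeros((n, 2))
    flags = np.zeros(n, dtype=bool)
    for j in range(n):
        ls = local_system(grad, temporal, points[j], window, lam=0.0)
        if ls.out_of_image:
            flags[j] = True
            continue
        M = np.array([[ls.alpha, ls.beta], [ls.beta, ls.gamma]])
        c = np.array([ls.xi, ls.eta])
        det = M[0, 0] * M[1, 1] - M[0, 1] ** 2
        scale = max(M[0, 0], M[1, 1], 1e-300)
        if det <= 1e-12 * scale**2:
            flags[j] = True
            continue
        disp[j] = np.linalg.solve(M, -c)
    return disp, flags


def _candidate_shifts(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    ux, uy = np.meshgrid(r, r)
    return np.column_stack([ux.ravel(), uy.ravel()])  # row-major in (uy, ux)


def block_match(frame_t, frame_next, points, search: SearchSpec, mode: str = "ssd"):
    """Exhaustive integer block matching at each point.

    ``mode='ssd'`` minimizes the Gaussian-weighted sum of squared
    differences; ``mode='xcorr'`` maximizes the unweighted normalized
    cross-correlation.  A candidate is considered only if the whole block
    lies inside both frames.  Ties are broken toward the smallest Euclidean
    displacement, then row-major candidate order.

    Returns ``(displacements, degenerate_flags)`` with integer displacements.
    """
    if mode not in ("ssd", "xcorr"):
        raise ValueError(f"mode must be 'ssd' or 'xcorr', got {mode!r}")
    frame_t = np.asarray(frame_t, dtype=float)
    frame_next = np.asarray(frame_next, dtype=float)
    if frame_t.shape != frame_next.shape:
        raise ValueError("frames must share one shape")
    H, W = frame_t.shape
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    half = search.block.side // 2
    offs = search.block.offsets.astype(int)  # (m, 2) as (dx, dy)
    w = search.block.weights.ravel()
    cands = _candidate_shifts(search.radius)
    cand_norm2 = (cands**2).sum(axis=1)

    disp = np.zeros((n, 2), dtype=int)
    flags = np.zeros(n, dtype=bool)
    for j in range(n):
        cx, cy = np.rint(points[j]).astype(int)
        bx, by = cx + offs[:, 0], cy + offs[:, 1]
        base_in = (bx >= 0) & (bx < W) & (by >= 0) & (by < H)
        if not base_in.all():
            # clip the block to the frame; candidates then also require the
            # shifted clipped block to stay inside
            if not base_in.any():
                flags[j] = True
                continue
        bxv, byv, wv = bx[base_in], by[base_in], w[base_in]
        wv = wv / wv.sum()
        ref = frame_t[byv, bxv]
        ref2 = float(np.sum(ref**2))
        if mode == "xcorr" and ref2 <= 0:
            flags[j] = True
            continue

        best_score = None
        best = None
        best_norm2 = None
        for k, (ux, uy) in enumerate(cands):
            sx, sy = bxv + ux, byv + uy
            if sx.min() < 0 or sx.max() >= W or sy.min() < 0 or sy.max() >= H:
                continue
            tgt = frame_next[sy, sx]
            if mode == "ssd":
                score = float(np.sum(wv * (ref - tgt) ** 2))
            else:
                denom2 = ref2 * float(np.sum(tgt**2))
                if denom2 <= 0:
                    continue  # constant-zero target block: no correlation defined
                score = -float(np.sum(ref * tgt)) / np.sqrt(denom2)  # maximize
            better = (
                best_score is None
                or score < best_score - 1e-15
                or (abs(score - best_score) <= 1e-15 and cand_norm2[k] < best_norm2)
            )
            if better:
                best_score, best, best_norm2 = score, (ux, uy), cand_norm2[k]
        if best is None:
            flags[j] = True
            continue
        disp[j] = best
    return disp, flags


def track_sequence_baseline(
    frames,
    initial_points,
    method: str = "lk",
    window: WindowSpec = None,
    search: SearchSpec = None,
) -> Trajectory:
    """Track a contour with one of the baseline methods over a frame stack.

    ``method`` is one of ``'lk'``, ``'ssd'``, ``'xcorr'``.  Block-matching
    displacements are integers evaluated at integer-rounded centers but are
    accumulated on subpixel point state.
    """
    if method not in ("lk", "ssd", "xcorr"):
        raise ValueError(f"unknown baseline method {method!r}")
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    if window is None:
        window = gaussian_window(21, 5.0)
    if search is None:
        search = SearchSpec(radius=10, block=window)

    pts = np.asarray(initial_points, dtype=float)
    T = len(frames)
    n = pts.shape[0]
    points = np.empty((T, n, 2))
    disps = np.empty((T - 1, n, 2))
    points[0] = pts
    for t in range(T - 1):
        if method == "lk":
            d, _ = lk_track_step(frames[t], frames[t + 1], points[t], window)
        else:
            d, _ = block_match(frames[t], frames[t + 1], points[t], search, mode=method)
        disps[t] = d
        points[t + 1] = points[t] + d
    return Trajectory(points=points, displacements=disps, lam_used=0.0)
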