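"""File formats: image sequences (TIFF/PNG), point trajectories (CSV).

CSV schema for points and trajectories: columns ``frame, point, x, y`` and
optionally ``u, v`` (the displacement to the next frame).  Floats are
serialized with 17 significant digits so round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image_sequence",
    "write_image_sequence",
    "read_points_csv",
    "write_points_csv",
]

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


def read_image_sequence(path) -> np.ndarray:
    """Load a (T, H, W) float frame stack.

    ``path`` is either a multi-page TIFF file or a directory of PNG/TIFF
    frames taken in lexicographic filename order.  All frames must share one
    shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
        frames = []
        shape = None
        for p in files:
            try:
                arr = np.asarray(iio.imread(p))
            except Exception as exc:  # pragma: no cover - backend specific
                raise OSError(f"cannot read frame {p}: {exc}") from exc
            if arr.ndim == 3:  # collapse RGB(A) to grayscale by averaging
                arr = arr[..., :3].mean(axis=-1)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"frame {p.name} has shape {arr.shape}, expected {shape}"
                )
            frames.append(arr.astype(float))
        return np.stack(frames)
    if not path.exists():
        raise OSError(f"no such image sequence: {path}")
    stack = tifffile.imread(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path} is not a grayscale frame stack (shape {stack.shape})")
    return stack.astype(float)


def write_image_sequence(path, frames, dtype=None) -> None:
    """Write a (T, H, W) stack as a multi-page TIFF (dtype preserved unless
    overridden)."""
    frames = np.asarray(frames)
    if dtype is not None:
        frames = frames.astype(dtype)
    tifffile.imwrite(Path(path), frames, photometric="minisblack")


def write_points_csv(path, points, displacements=None) -> None:
    """Serialize (T, n, 2) positions (or a single (n, 2) contour) to CSV."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2:
        pts = pts[None]
    T, n, _ = pts.shape
    frames = np.repeat(np.arange(T), n)
    ids = np.tile(np.arange(n), T)
    data = {
        "frame": frames,
        "point": ids,
        "x": pts[:, :, 0].ravel(),
        "y": pts[:, :, 1].ravel(),
    }
    if displacements is not None:
        disp = np.asarray(displacements, dtype=float)
        full = np.full((T, n, 2), np.nan)
        full[: disp.shape[0]] = disp
        data["u"] = full[:, :, 0].ravel()
        data["v"] = full[:, :, 1].ravel()
    pd.DataFrame(data).to_csv(Path(path), index=False, float_format="%.17g")


def read_points_csv(path):
    """Read a points CSV back into arrays.

    Returns ``(points, displacements)`` with ``points`` of shape (T, n, 2)
    and ``displacements`` of shape (T - 1, n, 2) or ``None`` when the file
    has no u/v columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} is empty or not a CSV") from exc
    required = {"frame", "point", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} is missing column(s): {sorted(missing)}")
    df = df.sort_values(["frame", "point"])
    T = df["frame"].nunique()
    n = df["point"].nunique()
    if len(df) != T * n:
        raise ValueError(f"{path} does not hold a full frame x point grid")
    pts = df[["x", "y"]].to_numpy().reshape(T, n, 2)
    disp = None
    if {"u", "v"} <= set(df.columns) and T > 1:
        disp = df[["u", "v"]].to_numpy().reshape(T, n, 2)[: T - 1]
    return pts, disp
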