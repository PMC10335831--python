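"""Polyline resampling and banded intensity sampling shared by the
kymograph and oocyte-profile code."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConfigurationError

__all__ = ["resample_polyline", "band_sample", "polyline_length"]


def polyline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_polyline(points: np.ndarray, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length steps.

    Parameters
    ----------
    points
        ``(n, 2)`` vertices in (x, y) pixel coordinates.
    step
        Arc-length step in pixels.

    Returns
    -------
    samples, tangents
        ``(m, 2)`` resampled points and unit tangents at each sample.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ConfigurationError(f"polyline must be (n>=2, 2), got {pts.shape}")
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    if not np.any(keep):
        raise ConfigurationError("degenerate polyline (zero length)")
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    s = np.arange(0.0, total + step / 2, step)
    s[-1] = min(s[-1], total)
    x = np.interp(s, arc, pts[:, 0])
    y = np.interp(s, arc, pts[:, 1])
    samples = np.column_stack([x, y])
    grads = np.gradient(samples, axis=0)
    norms = np.linalg.norm(grads, axis=1)
    norms[norms == 0] = 1.0
    tangents = grads / norms[:, None]
    return samples, tangents


def band_sample(
    image: np.ndarray,
    polyline: np.ndarray,
    width: int = 1,
    step: float = 1.0,
    check_bounds: bool = True,
) -> np.ndarray:
    """Mean intensity across ``width`` normal offsets at each arc-length step.

    At every resampled point of the polyline the image is interpolated
    bilinearly at ``width`` evenly spaced offsets along the local normal
    (spacing 1 px, centered on the line); the returned profile is the mean
    over the offsets.  ``width=1`` degenerates to direct line sampling.
    """
    if width < 1:
        raise ConfigurationError(f"width must be >= 1, got {width}")
    img = np.asarray(image, dtype=float)
    samples, tangents = resample_polyline(polyline, step=step)
    h, w = img.shape
    if check_bounds:
        inside = (
            (samples[:, 0] >= 0)
            & (samples[:, 0] <= w - 1)
            & (samples[:, 1] >= 0)
            & (samples[:, 1] <= h - 1)
        )
        if not np.all(inside):
            k = int(np.argmin(inside))
            raise ConfigurationError(
                f"polyline exits the image at sample {k}: {tuple(samples[k])}"
            )
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    # coords shape: (width, m, 2)
    coords = samples[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    if check_bounds and width > 1:
        off_img = (
            (coords[..., 0] < 0)
            | (coords[..., 0] > w - 1)
            | (coords[..., 1] < 0)
            | (coords[..., 1] > h - 1)
        )
        if np.any(off_img):
            warnings.warn(
                "sampling band extends beyond the image; clipped to the border",
                stacklevel=2,
            )
    vals = map_coordinates(
        img,
        [coords[..., 1].ravel(), coords[..., 0].ravel()],
        order=1,
        mode="nearest",
    ).reshape(width, -1)
    return vals.mean(axis=0)
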