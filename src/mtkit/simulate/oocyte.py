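"""Synthetic single-plane oocyte images with a cortical crescent and
inner intensity peaks.

The oocyte is an ellipse; the cortex polyline follows its boundary and
the AP axis runs horizontally through the center, anterior (nurse-cell
border) on the left.  The crescent is rendered as a Gaussian-blurred ridge
along a cortical arc (a boxcar of the configured arc length convolved
with the 2-px spot kernel, so the half-maximum width equals the
configured length); inner accumulations are isotropic Gaussians placed
along the AP axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._geometry import resample_polyline
from ..errors import ConfigurationError

__all__ = ["OocyteSimConfig", "SimulatedOocyte", "simulate_oocyte_image", "OocyteGeometry"]

from ..imaging import OocyteGeometry  # re-exported for convenience

_SPOT_SIGMA_PX = 2.0


@dataclass(frozen=True)
class OocyteSimConfig:
    """Scene parameters.  Intensities are arbitrary camera units.

    ``crescent_center_frac``: position of the crescent center as a
    fraction of cortex arc length; ``None`` places it at the posterior
    pole.  ``inner_peaks``: (ap_fraction, amplitude, width_um) tuples.
    """

    image_shape: tuple[int, int] = (160, 224)  # (H, W)
    pixel_size_um: float = 0.65
    crescent_arc_um: float = 40.0
    crescent_center_frac: float | None = None
    crescent_amplitude: float = 400.0
    inner_peaks: tuple[tuple[float, float, float], ...] = ()
    background: float = 100.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 32 or w < 32:
            raise ConfigurationError(f"image_shape too small: {self.image_shape}")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.crescent_arc_um < 0 or self.crescent_amplitude < 0:
            raise ConfigurationError("crescent arc and amplitude must be >= 0")
        if self.noise_sd < 0 or self.background < 0:
            raise ConfigurationError("background and noise_sd must be >= 0")
        for f, a, wd in self.inner_peaks:
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"inner peak ap_fraction {f} not in [0, 1]")
            if a < 0 or wd <= 0:
                raise ConfigurationError("inner peak amplitude >= 0 and width > 0 required")
        if self.crescent_center_frac is not None and not (
            0.0 <= self.crescent_center_frac <= 1.0
        ):
            raise ConfigurationError("crescent_center_frac must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedOocyte:
    image: np.ndarray  # (H, W) float
    geometry: OocyteGeometry
    truth: dict = field(default_factory=dict)


def _ellipse_cortex(h: int, w: int, n: int = 720) -> np.ndarray:
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a, b = 0.42 * (w - 1), 0.38 * (h - 1)
    # start at the posteriormost point (theta=0, +x) and run counterclockwise,
    # closing the loop
    theta = np.linspace(0.0, 2 * np.pi, n + 1)
    return np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])


def simulate_oocyte_image(cfg: OocyteSimConfig) -> SimulatedOocyte:
    """Render the scene and return image, geometry and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    cortex = _ellipse_cortex(h, w)
    samples, _ = resample_polyline(cortex, step=1.0)
    arc_px = np.arange(samples.shape[0], dtype=float)
    total_um = float(arc_px[-1]) * cfg.pixel_size_um
    if cfg.crescent_arc_um >= total_um:
        raise ConfigurationError(
            f"crescent_arc_um={cfg.crescent_arc_um} exceeds cortex length {total_um:.1f} um"
        )

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a = 0.42 * (w - 1)
    ap_line = np.array([[cx - a, cy], [cx + a, cy]])

    # posterior pole = cortex sample nearest the posterior AP endpoint
    pole_idx = int(np.argmin(np.linalg.norm(samples - ap_line[1][None, :], axis=1)))
    center_frac = (
        cfg.crescent_center_frac
        if cfg.crescent_center_frac is not None
        else pole_idx / (samples.shape[0] - 1)
    )
    center_arc = center_frac * arc_px[-1]
    half_arc_px = 0.5 * cfg.crescent_arc_um / cfg.pixel_size_um

    img = np.full((h, w), cfg.background, dtype=float)

    # crescent: splat a Gaussian kernel at every cortex sample inside the arc
    # (circular arc distance); the sum approximates a boxcar * Gaussian ridge
    # whose half-max length equals crescent_arc_um.
    if cfg.crescent_amplitude > 0 and cfg.crescent_arc_um > 0:
        d = np.abs(arc_px - center_arc)
        d = np.minimum(d, arc_px[-1] - d)  # closed cortex: wraparound distance
        in_arc = d <= half_arc_px
        rad = int(np.ceil(3 * _SPOT_SIGMA_PX))
        # per-sample kernel peak chosen so the summed ridge peaks at
        # crescent_amplitude (unit arc spacing: sum ~ peak * sigma * sqrt(2*pi))
        peak = cfg.crescent_amplitude / (_SPOT_SIGMA_PX * np.sqrt(2 * np.pi))
        for x, y in samples[in_arc]:
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            xs = np.arange(max(x0 - rad, 0), min(x0 + rad + 1, w))
            ys = np.arange(max(y0 - rad, 0), min(y0 + rad + 1, h))
            gx = np.exp(-0.5 * ((xs - x) / _SPOT_SIGMA_PX) ** 2)
            gy = np.exp(-0.5 * ((ys - y) / _SPOT_SIGMA_PX) ** 2)
            img[np.ix_(ys, xs)] += peak * gy[:, None] * gx[None, :]

    yy, xx = np.mgrid[0:h, 0:w]
    for frac, amp, width_um in cfg.inner_peaks:
        px_ = ap_line[0] + frac * (ap_line[1] - ap_line[0])
        sig = width_um / cfg.pixel_size_um
        img += amp * np.exp(-(((xx - px_[0]) ** 2 + (yy - px_[1]) ** 2) / (2 * sig**2)))

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)

    geometry = OocyteGeometry(
        cortex=cortex, ap_line=ap_line, line_width=50, pixel_size=cfg.pixel_size_um
    )
    truth = {
        "crescent_arc_um": cfg.crescent_arc_um if cfg.crescent_amplitude > 0 else 0.0,
        "crescent_center_frac": center_frac,
        "inner_peak_fracs": [p[0] for p in cfg.inner_peaks],
        "cortex_length_um": total_um,
    }
    return SimulatedOocyte(image=img, geometry=geometry, truth=truth)
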