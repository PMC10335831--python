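"""Oocyte image quantification: cortical crescent length, AP-axis
intensity profiles, inner-peak detection and posterior-enrichment calls.

All measurements are anchored on a user-supplied (or simulated) geometry:
a cortex polyline and an anterior-to-posterior axis line, both in pixel
coordinates, with a physical pixel size.  The crescent length is the
longest contiguous cortical arc whose background-subtracted intensity
exceeds half the peak contrast (a scale-free boundary criterion); the AP
profile averages intensities across a wide band (50 px by default) normal
to the axis line, the convention of line-profile tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.ndimage import binary_dilation
from skimage.draw import polygon2mask
from skimage.morphology import disk

from ._geometry import band_sample, resample_polyline
from ._util import percent
from .errors import ConfigurationError, UndefinedResultError

__all__ = [
    "OocyteGeometry",
    "ProfileResult",
    "measure_crescent_length",
    "ap_profile",
    "detect_inner_peaks",
    "call_posterior_enrichment",
    "summarize_fractions",
]


@dataclass(frozen=True)
class OocyteGeometry:
    """Cortex polyline and AP axis anchoring all oocyte measurements.

    ``ap_line``: two endpoints, anterior first.  ``line_width``: width in
    px of the AP sampling band.  ``pixel_size``: um per px.
    """

    cortex: np.ndarray
    ap_line: np.ndarray
    line_width: int = 50
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        cortex = np.asarray(self.cortex, dtype=float)
        ap = np.asarray(self.ap_line, dtype=float)
        if cortex.ndim != 2 or cortex.shape[1] != 2 or cortex.shape[0] < 3:
            raise ConfigurationError("cortex must be an (n>=3, 2) polyline")
        if ap.shape != (2, 2):
            raise ConfigurationError("ap_line must be two (x, y) endpoints")
        if self.line_width < 1:
            raise ConfigurationError("line_width must be >= 1")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        object.__setattr__(self, "cortex", cortex)
        object.__setattr__(self, "ap_line", ap)

    @property
    def is_closed(self) -> bool:
        return bool(np.allclose(self.cortex[0], self.cortex[-1], atol=1.5))


@dataclass(frozen=True)
class ProfileResult:
    """AP intensity profile with detected peaks.

    ``positions``: AP fraction in [0, 1]; ``peaks``: (ap_fraction,
    prominence) sorted by position; ``classification``: none |
    single_anterior | single_central | double_peak.
    """

    positions: np.ndarray
    intensities: np.ndarray
    peaks: tuple[tuple[float, float], ...] = ()
    classification: str = "unclassified"


def _longest_true_run(above: np.ndarray, circular: bool) -> int:
    """Length of the longest contiguous True run, optionally wrapping."""
    if not above.any():
        return 0
    if above.all():
        return above.size
    if circular:
        # rotate so a False sits at position 0, then runs cannot wrap
        k = int(np.argmin(above))
        above = np.roll(above, -k)
    best = cur = 0
    for v in above:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def measure_crescent_length(
    image: np.ndarray,
    geometry: OocyteGeometry,
    threshold_frac: float = 0.5,
    sample_width: int = 3,
) -> float:
    """Length (um) of the longest contiguous cortical arc above threshold.

    The intensity profile along the cortex (1-px arc steps, averaged over
    ``sample_width`` normal offsets) is thresholded at
    ``background + threshold_frac * (peak - background)`` with the
    background taken as the median profile intensity; a closed cortex is
    treated circularly.  Returns 0 with a warning when there is no
    contrast above the background.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ConfigurationError("threshold_frac must be in (0, 1)")
    profile = band_sample(
        np.asarray(image, dtype=float), geometry.cortex, width=sample_width, step=1.0
    )
    background = float(np.median(profile))
    peak = float(profile.max())
    if peak - background <= 1e-9 * max(1.0, abs(background)):
        warnings.warn("no cortical signal above background; crescent length 0", stacklevel=2)
        return 0.0
    thr = background + threshold_frac * (peak - background)
    above = profile >= thr
    n = _longest_true_run(above, circular=geometry.is_closed)
    return float(n) * geometry.pixel_size


def ap_profile(image: np.ndarray, geometry: OocyteGeometry) -> ProfileResult:
    """Mean-intensity profile along the AP axis line.

    At each 1-px arc step the image is sampled bilinearly at
    ``line_width`` evenly spaced normal offsets and averaged; offsets that
    leave the image are clipped to the border with a warning.
    """
    intensities = band_sample(
        np.asarray(image, dtype=float),
        geometry.ap_line,
        width=geometry.line_width,
        step=1.0,
    )
    positions = np.linspace(0.0, 1.0, intensities.size)
    return ProfileResult(positions=positions, intensities=intensities)


def detect_inner_peaks(
    profile: ProfileResult,
    margin_frac: float = 0.1,
    prominence_frac: float = 0.2,
    anterior_max_frac: float = 0.5,
    min_contrast_frac: float = 0.02,
) -> ProfileResult:
    """Find inner accumulation peaks along the AP profile and classify.

    Local maxima with prominence >= ``prominence_frac * (max - min)``,
    excluding ``margin_frac`` of the axis at each end (cortical signal).
    ``min_contrast_frac`` additionally requires a peak to rise by that
    fraction of the median intensity, so a flat, purely noisy profile
    yields no peaks.  One peak anterior of ``anterior_max_frac`` ->
    single_anterior, one peak at/behind it -> single_central; two or more
    -> double_peak (the two most prominent are reported); none -> none.
    """
    y = profile.intensities
    span = float(y.max() - y.min())
    if span == 0:
        return ProfileResult(profile.positions, y, (), "none")
    floor = min_contrast_frac * abs(float(np.median(y)))
    idx, props = find_peaks(y, prominence=max(prominence_frac * span, floor))
    fr = profile.positions[idx]
    keep = (fr >= margin_frac) & (fr <= 1.0 - margin_frac)
    idx, prom, fr = idx[keep], props["prominences"][keep], fr[keep]
    if idx.size == 0:
        return ProfileResult(profile.positions, y, (), "none")
    if idx.size > 2:
        top = np.argsort(-prom)[:2]
        idx, prom, fr = idx[top], prom[top], fr[top]
    order = np.argsort(fr)
    peaks = tuple((float(fr[i]), float(prom[i])) for i in order)
    if len(peaks) == 1:
        cls = "single_anterior" if peaks[0][0] < anterior_max_frac else "single_central"
    else:
        cls = "double_peak"
    return ProfileResult(profile.positions, y, peaks, cls)


def _oocyte_mask(shape: tuple[int, int], cortex: np.ndarray) -> np.ndarray:
    return polygon2mask(shape, cortex[:, ::-1])  # polygon2mask wants (row, col)


def call_posterior_enrichment(
    image: np.ndarray,
    geometry: OocyteGeometry,
    band_frac: float = 0.15,
    ratio_min: float = 1.3,
    inward_px: int = 5,
) -> bool:
    """Deterministic surrogate for blind posterior-enrichment scoring.

    True iff the mean intensity of the posterior cortical band — the
    cortex arc spanning ``band_frac`` of the total arc length, centered on
    the posterior pole, dilated ``inward_px`` px — is at least
    ``ratio_min`` times the mean intensity of the rest of the oocyte.
    """
    img = np.asarray(image, dtype=float)
    samples, _ = resample_polyline(geometry.cortex, step=1.0)
    pole = np.asarray(geometry.ap_line[1], dtype=float)
    pole_idx = int(np.argmin(np.linalg.norm(samples - pole[None, :], axis=1)))
    n = samples.shape[0]
    arc = np.arange(n, dtype=float)
    d = np.abs(arc - pole_idx)
    if geometry.is_closed:
        d = np.minimum(d, n - d)
    band_pts = samples[d <= 0.5 * band_frac * n]
    if band_pts.size == 0:
        raise ConfigurationError("posterior band is empty")
    band = np.zeros(img.shape, dtype=bool)
    ij = np.round(band_pts[:, ::-1]).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, img.shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, img.shape[1] - 1)
    band[ij[:, 0], ij[:, 1]] = True
    band = binary_dilation(band, structure=disk(inward_px))
    oocyte = _oocyte_mask(img.shape, samples)
    band &= oocyte
    rest = oocyte & ~band
    if not band.any() or not rest.any():
        raise ConfigurationError("posterior band or remaining oocyte mask is empty")
    return float(img[band].mean()) >= ratio_min * float(img[rest].mean())


def summarize_fractions(calls_by_genotype: dict) -> pd.DataFrame:
    """Percent of positive calls per genotype (rounded half-up), with n."""
    rows = []
    for genotype, calls in calls_by_genotype.items():
        calls = list(calls)
        if not calls:
            raise ConfigurationError(f"genotype {genotype!r} has no calls")
        n_pos = int(sum(bool(c) for c in calls))
        rows.append(
            {
                "genotype": genotype,
                "n": len(calls),
                "n_positive": n_pos,
                "pct_positive": percent(n_pos, len(calls)),
            }
        )
    return pd.DataFrame(rows)
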