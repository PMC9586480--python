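"""Vein-unloading peak widths along a grid of scan lines.

An image (a projection showing tracer halos around veins) is scanned by n
vertical plus n horizontal equidistant lines (default 50 each).  Along each
line the intensity is LOESS-smoothed, peaks and valleys extracted, and each
peak's left/right base placed at the outermost position where the curve
still exceeds ``neighbouring valley minimum + 2 x SD of the LOESS
residuals``.  The mean of all retained widths summarises one projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._loess import loess_smooth
from .errors import ConfigError, DataError
from .stack import ImageStack

__all__ = [
    "PeakRecord",
    "grid_profiles",
    "detect_peaks_valleys",
    "peak_bases",
    "measure_peak_widths",
    "mean_peak_width",
]

DEFAULT_N_LINES = 50  # per axis
DEFAULT_SPAN = 0.1


@dataclass
class PeakRecord:
    line_id: str
    peak_position: float  # um
    left_base: float  # um
    right_base: float  # um

    @property
    def width(self) -> float:
        return self.right_base - self.left_base

    def __post_init__(self) -> None:
        if not self.left_base <= self.peak_position <= self.right_base:
            raise DataError("peak must lie between its bases")


def grid_profiles(image: np.ndarray, n_lines_per_axis: int = DEFAULT_N_LINES):
    """2n equidistant full-length profiles: n horizontal rows, n vertical cols.

    Lines sit at the centres of n equal bands, so ``n=1`` gives the central
    row and column.  Returns ``[(line_id, profile_values), ...]``.
    """
    if n_lines_per_axis < 1:
        raise ConfigError("need at least one line per axis")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DataError("expected a single 2-D image")
    h, w = img.shape
    rows = np.round((np.arange(n_lines_per_axis) + 0.5) / n_lines_per_axis * h
                    - 0.5).astype(int)
    cols = np.round((np.arange(n_lines_per_axis) + 0.5) / n_lines_per_axis * w
                    - 0.5).astype(int)
    out = [(f"h{r}", img[r, :]) for r in rows]
    out += [(f"v{c}", img[:, c]) for c in cols]
    return out


def detect_peaks_valleys(profile: np.ndarray, span: float = DEFAULT_SPAN,
                         window: int = 3):
    """LOESS-smooth a line profile and extract its local maxima and minima.

    Returns ``(smoothed, peak_indices, valley_indices, sd_resid)`` where
    ``sd_resid`` is the SD of the raw-minus-smoothed residuals.
    """
    from .tracking import find_local_maxima

    profile = np.asarray(profile, dtype=float)
    x = np.arange(profile.size, dtype=float)
    smoothed = loess_smooth(x, profile, span=span)
    sd_resid = float(np.std(profile - smoothed, ddof=1))
    # tolerance guards against float jitter posing as extrema on flat stretches
    atol = 1e-8 * max(1.0, float(np.ptp(smoothed)))
    peaks = find_local_maxima(smoothed, window=window, atol=atol)
    valleys = find_local_maxima(-smoothed, window=window, atol=atol)
    return smoothed, peaks, valleys, sd_resid


def _flanking_valleys(peak: int, valleys: np.ndarray, n: int,
                      curve: np.ndarray) -> tuple[int, int]:
    # profile ends count as valleys
    left = [v for v in valleys if v < peak]
    right = [v for v in valleys if v > peak]
    lv = max(left) if left else 0
    rv = min(right) if right else n - 1
    return lv, rv


def peak_bases(curve: np.ndarray, peak: int, left_valley: int,
               right_valley: int, sd_resid: float,
               valley_rule: str = "lower") -> tuple[float, float] | None:
    """Sub-pixel left/right base positions of one peak, or None if discarded.

    The base level is ``valley minimum + 2 * sd_resid``; with
    ``valley_rule='lower'`` the lower of the two flanking valley values is
    used on both sides (``'per_side'`` uses each side's own valley).  Walking
    outward from the peak, the base is the outermost position (linearly
    interpolated) where the curve still exceeds the level on that side.
    Peaks not rising above their base level are discarded.
    """
    curve = np.asarray(curve, dtype=float)
    if not left_valley <= peak <= right_valley:
        raise DataError("peak must lie between its flanking valleys")
    if valley_rule == "lower":
        level = min(curve[left_valley], curve[right_valley]) + 2 * sd_resid
        level_l = level_r = level
    elif valley_rule == "per_side":
        level_l = curve[left_valley] + 2 * sd_resid
        level_r = curve[right_valley] + 2 * sd_resid
    else:
        raise ConfigError("valley_rule must be 'lower' or 'per_side'")
    if curve[peak] <= max(level_l, level_r):
        return None  # prominence below the noise allowance

    def cross(level: float, indices: np.ndarray) -> float:
        # walk outward; stop at the first sample at or below the level
        prev = peak
        for i in indices:
            if curve[i] <= level:
                frac = (curve[prev] - level) / (curve[prev] - curve[i])
                return prev + frac * (i - prev)
            prev = i
        return float(prev)

    left = cross(level_l, np.arange(peak - 1, left_valley - 1, -1))
    right = cross(level_r, np.arange(peak + 1, right_valley + 1))
    return left, right


def measure_peak_widths(image: np.ndarray | ImageStack,
                        n_lines_per_axis: int = DEFAULT_N_LINES,
                        span: float = DEFAULT_SPAN, window: int = 3,
                        pixel_size: float | None = None,
                        sd_resid: float | None = None,
                        valley_rule: str = "lower") -> pd.DataFrame:
    """All retained peak records across the grid lines of one projection.

    ``sd_resid=None`` estimates the residual SD per line from the LOESS fit;
    a float forces a common value (useful on noiseless fixtures).
    """
    if isinstance(image, ImageStack):
        if pixel_size is None:
            pixel_size = image.pixel_size
        image = image.frames[0]
    if pixel_size is None:
        pixel_size = 1.0
    records = []
    for line_id, profile in grid_profiles(image, n_lines_per_axis):
        curve, peaks, valleys, sd_est = detect_peaks_valleys(profile, span,
                                                             window)
        sd = sd_est if sd_resid is None else float(sd_resid)
        for pk in peaks:
            lv, rv = _flanking_valleys(pk, valleys, curve.size, curve)
            bases = peak_bases(curve, pk, lv, rv, sd, valley_rule)
            if bases is None:
                continue
            rec = PeakRecord(line_id, pk * pixel_size,
                             bases[0] * pixel_size, bases[1] * pixel_size)
            records.append({"line_id": rec.line_id,
                            "peak_um": rec.peak_position,
                            "left_base_um": rec.left_base,
                            "right_base_um": rec.right_base,
                            "width_um": rec.width})
    return pd.DataFrame(records, columns=["line_id", "peak_um",
                                          "left_base_um", "right_base_um",
                                          "width_um"])


def mean_peak_width(image, **kwargs) -> float:
    """Mean width (um) over all retained peaks of one projection; NaN if none."""
    df = measure_peak_widths(image, **kwargs)
    if df.empty:
        warnings.warn("no peaks retained; mean width undefined", stacklevel=2)
        return float("nan")
    return float(df["width_um"].mean())
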