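"""Baseline estimation and traveling peak/front tracking on distance profiles.

The workflow per time point: LOESS-smooth the averaged distance profile,
find local maxima of the smoothed curve, keep those above the upper noise
band, and select the brightest one whose distance does not regress behind
the previously selected peak.  The front is the outermost distance where the
smoothed profile still reaches ``baseline + sd_bar``.

Noise bands follow the two closed formulas
``noise = baseline +/- 1.96 * sd_bar`` and ``front threshold = baseline +
sd_bar``, where ``sd_bar`` is the mean (over pre-response time points) of the
SD across distance of the averaged profile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._loess import loess_smooth
from .errors import ConfigError, DataError
from .scan import ProfileSet

__all__ = [
    "BaselineModel",
    "WaveTrack",
    "smooth_profile",
    "estimate_baseline",
    "find_local_maxima",
    "track_peak",
    "track_front",
    "track_wave",
    "set_time_zero",
]

NOISE_MULTIPLIER = 1.96


@dataclass
class BaselineModel:
    baseline: float
    sd_bar: float
    noise_multiplier: float = NOISE_MULTIPLIER

    @property
    def noise_upper(self) -> float:
        return self.baseline + self.noise_multiplier * self.sd_bar

    @property
    def noise_lower(self) -> float:
        return self.baseline - self.noise_multiplier * self.sd_bar

    @property
    def front_threshold(self) -> float:
        return self.baseline + self.sd_bar

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "baseline": self.baseline, "sd_bar": self.sd_bar,
            "noise_multiplier": self.noise_multiplier,
            "noise_upper": self.noise_upper, "noise_lower": self.noise_lower,
            "front_threshold": self.front_threshold}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BaselineModel":
        d = json.loads(Path(path).read_text())
        return cls(d["baseline"], d["sd_bar"],
                   d.get("noise_multiplier", NOISE_MULTIPLIER))


@dataclass
class WaveTrack:
    """Per-frame wave summary; undefined entries are NaN, never interpolated."""

    t: np.ndarray  # s, relative to the chosen time zero
    peak_distance: np.ndarray  # um
    peak_intensity: np.ndarray  # a.u.
    snr: np.ndarray  # peak_intensity / noise_upper
    front_distance: np.ndarray  # um
    time_zero_rule: str = "stimulus_frame"
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        arrays = (self.t, self.peak_distance, self.peak_intensity,
                  self.snr, self.front_distance)
        if len({np.asarray(a).size for a in arrays}) != 1:
            raise DataError("all track columns must have equal length")
        self.t = np.asarray(self.t, dtype=float)
        self.peak_distance = np.asarray(self.peak_distance, dtype=float)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        self.front_distance = np.asarray(self.front_distance, dtype=float)

    def __len__(self) -> int:
        return self.t.size

    def peak_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, peak_distance) with undefined entries dropped."""
        ok = np.isfinite(self.peak_distance)
        return self.t[ok], self.peak_distance[ok]

    def front_table(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.front_distance)
        return self.t[ok], self.front_distance[ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "peak_um": self.peak_distance,
                             "peak_intensity": self.peak_intensity,
                             "snr": self.snr, "front_um": self.front_distance})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WaveTrack":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["peak_um"].to_numpy(),
                   df["peak_intensity"].to_numpy(), df["snr"].to_numpy(),
                   df["front_um"].to_numpy())


def smooth_profile(distances, intensities, span: float = 0.75) -> np.ndarray:
    """LOESS (tricube, local degree 2) fitted values on the input grid.

    ``span`` is the fraction of points per local fit. ``span=0`` disables
    smoothing and returns the raw profile (useful for noiseless inputs).
    """
    if span == 0:
        return np.asarray(intensities, dtype=float).copy()
    return loess_smooth(np.asarray(distances, float),
                        np.asarray(intensities, float), span=span)


def estimate_baseline(profiles: ProfileSet,
                      pre_frames=None, pre_distances=None,
                      sd_floor: float = 0.0,
                      noise_multiplier: float = NOISE_MULTIPLIER) -> BaselineModel:
    """Estimate the baseline and noise bands from a pre-response region.

    The region is the block of the profile matrix selected by ``pre_frames``
    (time indices) and/or ``pre_distances`` (distance indices) — tissue not
    yet reached by the response.  ``baseline`` is the mean intensity there;
    ``sd_bar`` the mean over selected time points of the SD across distance.
    ``sd_floor`` guards degenerate noiseless input where sd_bar collapses
    to 0 and the front threshold would equal the baseline exactly.
    """
    if pre_frames is None and pre_distances is None:
        raise ConfigError("specify pre_frames and/or pre_distances")
    ti = np.arange(profiles.times.size) if pre_frames is None \
        else np.atleast_1d(np.asarray(pre_frames, dtype=int))
    di = np.arange(profiles.distances.size) if pre_distances is None \
        else np.atleast_1d(np.asarray(pre_distances, dtype=int))
    if ti.size == 0 or di.size == 0:
        raise ConfigError("pre-response region is empty")
    block = profiles.intensity[np.ix_(di, ti)]
    if not np.all(np.isfinite(block)):
        raise DataError("pre-response region contains non-finite intensities")
    baseline = float(block.mean())
    sd_bar = float(block.std(axis=0, ddof=1).mean()) if di.size > 1 else 0.0
    sd_bar = max(sd_bar, sd_floor)
    return BaselineModel(baseline, sd_bar, noise_multiplier)


def find_local_maxima(values: np.ndarray, window: int = 5,
                      distances: np.ndarray | None = None,
                      atol: float = 0.0):
    """Indices of points strictly greater than all neighbours within +/-window.

    Boundary points are never maxima.  ``atol`` requires the point to exceed
    its neighbours by at least that much (guards float jitter on flat
    curves).  Returns ``(indices,)`` or ``(distances[i], values[i])`` pairs
    when ``distances`` is given.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    n = v.size
    out = []
    for i in range(1, n - 1):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neigh = np.r_[v[lo:i], v[i + 1:hi]]
        if neigh.size and np.all(v[i] > neigh + atol):
            out.append(i)
    idx = np.asarray(out, dtype=int)
    if distances is None:
        return idx
    d = np.asarray(distances, dtype=float)
    return [(d[i], v[i]) for i in idx]


def _refine_parabolic(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid vertex of the parabola through (i-1, i, i+1); falls back to i."""
    if i <= 0 or i >= x.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    h = x[i + 1] - x[i] if delta >= 0 else x[i] - x[i - 1]
    return float(x[i] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def track_peak(profiles: ProfileSet, baseline: BaselineModel,
               span: float = 0.75, window: int = 5) -> WaveTrack:
    """Track the traveling intensity peak across frames.

    At each frame, local maxima of the smoothed profile above the upper
    noise band are candidates; among those at or beyond the previously
    selected distance, the brightest wins (ties: the nearer one).  Frames
    with no qualifying maximum stay NaN.
    """
    nt = profiles.times.size
    peak_d = np.full(nt, np.nan)
    peak_i = np.full(nt, np.nan)
    snr = np.full(nt, np.nan)
    prev = -np.inf
    tol = 1e-9
    for k in range(nt):
        smoothed = smooth_profile(profiles.distances, profiles.intensity[:, k],
                                  span)
        idx = find_local_maxima(smoothed, window)
        cand = [i for i in idx if smoothed[i] > baseline.noise_upper
                and profiles.distances[i] >= prev - tol]
        if not cand:
            continue
        best = max(cand, key=lambda i: (smoothed[i], -profiles.distances[i]))
        d, v = _refine_parabolic(profiles.distances, smoothed, best)
        d = max(d, prev if np.isfinite(prev) else d)
        peak_d[k], peak_i[k] = d, v
        snr[k] = v / baseline.noise_upper
        prev = d
    if not np.any(np.isfinite(peak_d)):
        warnings.warn("no frame produced a qualifying peak; empty track",
                      stacklevel=2)
    return WaveTrack(profiles.times.copy(), peak_d, peak_i, snr,
                     np.full(nt, np.nan))


def track_front(profiles: ProfileSet, baseline: BaselineModel,
                span: float = 0.75, min_run: int = 1) -> np.ndarray:
    """Outermost distance per frame where the smoothed profile reaches the
    front threshold, with linear sub-grid interpolation of the crossing.
    NaN where the profile never exceeds the threshold.

    ``min_run > 1`` requires the outermost super-threshold excursion to span
    at least that many consecutive grid steps, which rejects isolated
    smoothed-noise bumps on noisy profiles (1 reproduces the plain rule).
    """
    if min_run < 1:
        raise ConfigError("min_run must be >= 1")
    nt = profiles.times.size
    d = profiles.distances
    thr = baseline.front_threshold
    front = np.full(nt, np.nan)
    for k in range(nt):
        s = smooth_profile(d, profiles.intensity[:, k], span)
        above = s > thr
        if min_run > 1 and above.any():
            run = np.convolve(above.astype(int), np.ones(min_run, dtype=int),
                              mode="valid") == min_run
            if not run.any():
                above = np.zeros_like(above)
            else:  # keep only samples inside a long-enough run
                mask = np.zeros_like(above)
                for j in np.nonzero(run)[0]:
                    mask[j:j + min_run] = True
                above &= mask
        if not above.any():
            continue
        i = int(np.nonzero(above)[0][-1])
        if i == d.size - 1:
            front[k] = d[i]
        else:  # interpolate the downward crossing between i and i+1
            frac = (s[i] - thr) / (s[i] - s[i + 1])
            front[k] = d[i] + frac * (d[i + 1] - d[i])
    return front


def track_wave(profiles: ProfileSet, baseline: BaselineModel,
               span: float = 0.75, window: int = 5,
               min_run: int = 1) -> WaveTrack:
    """Convenience: peak and front tracking with shared settings."""
    track = track_peak(profiles, baseline, span=span, window=window)
    track.front_distance = track_front(profiles, baseline, span=span,
                                       min_run=min_run)
    track.frame_interval = float(np.median(np.diff(profiles.times))) \
        if profiles.times.size > 1 else None
    return track


def set_time_zero(track: WaveTrack, rule: str = "stimulus_frame",
                  stimulus_frame: int | None = None) -> WaveTrack:
    """Re-express track times relative to a zero; entries before it drop.

    ``stimulus_frame``: zero at the given frame index (needle hit).
    ``first_progression``: zero at the first frame where the tracked
    distance advances past its previous defined value.
    """
    if rule == "stimulus_frame":
        if stimulus_frame is None:
            raise ConfigError("stimulus_frame rule needs a frame index")
        if not 0 <= stimulus_frame < len(track):
            raise ConfigError("stimulus_frame outside the track")
        i0 = int(stimulus_frame)
    elif rule == "first_progression":
        series = track.peak_distance if np.any(np.isfinite(track.peak_distance)) \
            else track.front_distance
        defined = np.nonzero(np.isfinite(series))[0]
        i0 = None
        for a, b in zip(defined[:-1], defined[1:]):
            if series[b] > series[a] + 1e-9:
                i0 = int(b)
                break
        if i0 is None:
            raise DataError("track never progresses; cannot set time zero")
    else:
        raise ConfigError(f"unknown time-zero rule {rule!r}")
    t0 = track.t[i0]
    keep = slice(i0, None)
    return WaveTrack(track.t[keep] - t0, track.peak_distance[keep],
                     track.peak_intensity[keep], track.snr[keep],
                     track.front_distance[keep], time_zero_rule=rule,
                     frame_interval=track.frame_interval)
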