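"""Synthetic fluorescence-wave generators with analytic ground truth.

Three image generators and two table generators cover the signal classes the
analysis pipeline consumes:

* a radially propagating local wave from an instantaneous 2-D point release,
  whose threshold-crossing front slows like a diffusion front;
* a distal wave from a line release (a vein), invariant along the vein;
* distance-time tables for a vascular advection front with a shear-enhanced
  (Taylor-dispersion) leading tail;
* single-frame vein "ridge" images for peak-width analysis;
* direct front tables ``r_i = sqrt(6 D t_i)`` for fit-recovery tests.

Every generator draws all randomness from one integer seed and returns a
:class:`GroundTruth` carrying the exact front/peak laws of the noiseless
signal, so trackers and fitters can be scored against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfcinv, lambertw

from .errors import ConfigError, DataError
from .stack import ImageStack

__all__ = [
    "LocalWaveParams",
    "DistalWaveParams",
    "VascularWaveParams",
    "GroundTruth",
    "agonist_concentration",
    "line_source_concentration",
    "response_kernel",
    "gen_local_wave_stack",
    "gen_distal_wave_stack",
    "gen_vascular_tables",
    "gen_cf_vein_image",
    "gen_front_table",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class LocalWaveParams:
    """Parameters of the radial (point-release) wave generator.

    ``source_mass`` is a free parameter (the released amount is not known
    physically); together with ``activation_threshold`` it sets how far the
    front travels.  ``rise_decay`` are the time constants (s) of the
    difference-of-exponentials fluorescence response after local activation.
    """

    D_true: float = 116.0  # um^2/s
    source_mass: float = 1e7  # a.u. (2-D point release)
    activation_threshold: float = 1e-3  # a.u.
    rise_decay: tuple[float, float] = (2.0, 20.0)  # s
    amplitude: float = 1000.0  # peak fluorescence above baseline, a.u.
    baseline: float = 100.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    pixel_size: float = 4.0  # um/px
    frame_interval: float = 2.0  # s
    n_frames: int = 120
    image_size: int = 256  # px (square)
    origin: tuple[float, float] = (128.0, 128.0)  # (x, y) px
    n_baseline_frames: int = 0  # pre-stimulus frames (baseline only)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true <= 0:
            raise ConfigError("D_true must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ConfigError("frame_interval and pixel_size must be positive")
        if self.source_mass <= 0 or self.activation_threshold <= 0:
            raise ConfigError("source_mass and activation_threshold must be positive")
        rise, decay = self.rise_decay
        if not 0 < rise < decay:
            raise ConfigError("need 0 < rise < decay time constants")
        x, y = self.origin
        if not (0 <= x < self.image_size and 0 <= y < self.image_size):
            raise ConfigError("origin must lie inside the image")


@dataclass
class DistalWaveParams:
    """Parameters of the distal (line-release) wave generator.

    The vein is a vertical line at column ``vein_x``; ``source_mass`` is the
    released amount per unit length of the vein.
    """

    D_true: float = 116.0
    source_mass: float = 1e5
    activation_threshold: float = 1e-3
    rise_decay: tuple[float, float] = (2.0, 20.0)
    amplitude: float = 1000.0
    baseline: float = 100.0
    noise_sd: float = 0.0
    pixel_size: float = 4.0
    frame_interval: float = 2.0
    n_frames: int = 120
    image_size: int = 256
    vein_x: float = 20.0  # px
    n_baseline_frames: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true <= 0 or self.source_mass <= 0 or self.activation_threshold <= 0:
            raise ConfigError("D_true, source_mass, activation_threshold must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 <= self.vein_x < self.image_size:
            raise ConfigError("vein_x must lie inside the image")


@dataclass
class VascularWaveParams:
    """Parameters of the vascular bulk-flow / Taylor-dispersion tables."""

    u: float = 500.0  # um/s
    Dm: float = 100.0  # um^2/s (1e-6 cm^2/s)
    radius: float = 10.0  # um
    theta: float = 0.25  # activation threshold, fraction of source concentration
    t_max: float = 10.0  # s
    sample_times: Sequence[float] | None = None
    noise_sd: float = 0.0  # um, on distances
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ConfigError("u must be non-negative")
        if self.Dm <= 0 or self.radius <= 0:
            raise ConfigError("Dm and radius must be positive")
        if not 0 < self.theta < 1:
            raise ConfigError("theta must be in (0, 1)")

    def times(self) -> np.ndarray:
        if self.sample_times is not None:
            t = np.asarray(self.sample_times, dtype=float)
        else:
            t = np.arange(1.0, self.t_max + 0.5)
        if np.any(t <= 0):
            raise ConfigError("sample times must be positive")
        return t


@dataclass
class GroundTruth:
    """Exact laws of the noiseless signal, for parameter-recovery scoring."""

    front_law: Callable[[np.ndarray], np.ndarray]
    peak_law: Callable[[np.ndarray], np.ndarray] | None = None
    params_used: dict = field(default_factory=dict)

    def front(self, t) -> np.ndarray:
        return self.front_law(np.asarray(t, dtype=float))

    def peak(self, t) -> np.ndarray:
        if self.peak_law is None:
            raise DataError("this generator records no peak law")
        return self.peak_law(np.asarray(t, dtype=float))


# --------------------------------------------------------------------------
# concentration kernels and activation times
# --------------------------------------------------------------------------

def agonist_concentration(r, t, params: LocalWaveParams) -> np.ndarray:
    """2-D instantaneous point-source kernel M/(4 pi D t) exp(-r^2 / 4 D t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DataError("t must be positive")
    r = np.asarray(r, dtype=float)
    D, M = params.D_true, params.source_mass
    return M / (4 * np.pi * D * t) * np.exp(-r ** 2 / (4 * D * t))


def line_source_concentration(x, t, params: DistalWaveParams) -> np.ndarray:
    """1-D instantaneous line-source kernel M/sqrt(4 pi D t) exp(-x^2 / 4 D t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DataError("t must be positive")
    x = np.asarray(x, dtype=float)
    D, M = params.D_true, params.source_mass
    return M / np.sqrt(4 * np.pi * D * t) * np.exp(-x ** 2 / (4 * D * t))


def response_kernel(tau, rise: float, decay: float, amplitude: float) -> np.ndarray:
    """Difference-of-exponentials fluorescence response, peak = ``amplitude``.

    Zero for ``tau <= 0``; rises on the ``rise`` scale and relaxes on the
    ``decay`` scale, producing a traveling intensity peak behind the front.
    """
    tau = np.asarray(tau, dtype=float)
    tau_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    norm = math.exp(-tau_peak / decay) - math.exp(-tau_peak / rise)
    g = np.where(tau > 0,
                 np.exp(-np.clip(tau, 0, None) / decay)
                 - np.exp(-np.clip(tau, 0, None) / rise), 0.0)
    return amplitude * g / norm


def _point_activation_times(r_um: np.ndarray, D: float, M: float,
                            theta: float) -> np.ndarray:
    """First time the 2-D kernel exceeds ``theta`` at radius r; inf if never.

    Solving ``(1/t) exp(-alpha/t) = beta`` with ``alpha = r^2/4D`` and
    ``beta = 4 pi D theta / M`` gives ``t = alpha / x`` where
    ``x = -W_{-1}(-alpha beta)`` (earlier of the two crossings).
    """
    alpha = r_um ** 2 / (4 * D)
    beta = 4 * np.pi * D * theta / M
    arg = alpha * beta
    t_a = np.full(r_um.shape, np.inf)
    never = arg > 1 / np.e
    origin = alpha == 0
    ok = ~never & ~origin
    with np.errstate(all="ignore"):
        x = -np.real(lambertw(-arg[ok], k=-1))
    t_a[ok] = alpha[ok] / x
    t_a[origin] = 0.0
    return t_a


def _line_activation_times(x_um: np.ndarray, D: float, M: float,
                           theta: float) -> np.ndarray:
    """First time the 1-D line kernel exceeds ``theta``; inf if never."""
    alpha = x_um ** 2 / (4 * D)
    beta2 = (theta * np.sqrt(4 * np.pi * D) / M) ** 2
    arg = 2 * alpha * beta2
    t_a = np.full(x_um.shape, np.inf)
    never = arg > 1 / np.e
    origin = alpha == 0
    ok = ~never & ~origin
    with np.errstate(all="ignore"):
        xr = -np.real(lambertw(-arg[ok], k=-1))
    t_a[ok] = 2 * alpha[ok] / xr
    t_a[origin] = 0.0
    return t_a


def _point_front_law(D: float, M: float, theta: float) -> Callable:
    """Outermost activated radius (um) vs time for the 2-D point kernel.

    r_f(t) = sqrt(4 D t ln(C/t)) with C = M/(4 pi D theta), growing until
    t* = C/e and then frozen at the maximal activation radius
    sqrt(M / (pi e theta)).
    """
    C = M / (4 * np.pi * D * theta)
    t_star = C / np.e
    r_max = math.sqrt(M / (np.pi * np.e * theta))

    def law(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        grow = (t > 0) & (t < t_star)
        out[grow] = np.sqrt(4 * D * t[grow] * np.log(C / t[grow]))
        out[t >= t_star] = r_max
        return out

    return law


def _line_front_law(D: float, M: float, theta: float) -> Callable:
    """Outermost activated distance (um) vs time for the 1-D line kernel."""
    K = math.log(M / (theta * math.sqrt(4 * np.pi * D)))
    t_star = math.exp(2 * K - 1)
    r_max = math.sqrt(2 * D * t_star)

    def law(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        grow = (t > 0) & (t < t_star)
        out[grow] = np.sqrt(4 * D * t[grow] * (K - 0.5 * np.log(t[grow])))
        out[t >= t_star] = r_max
        return out

    return law


def _peak_from_front(front_law: Callable, rise: float, decay: float) -> Callable:
    # the intensity maximum sits where the response age equals its peak lag
    tau_peak = rise * decay / (decay - rise) * math.log(decay / rise)

    def law(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return front_law(np.clip(t - tau_peak, 0.0, None))

    return law


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _render_stack(t_act: np.ndarray, params) -> np.ndarray:
    """Shared frame renderer: baseline + response(t - t_act) + noise."""
    rng = np.random.default_rng(params.rng_seed)
    rise, decay = params.rise_decay
    n = params.n_frames
    frames = np.empty((n, *t_act.shape))
    for k in range(n):
        t = (k - params.n_baseline_frames) * params.frame_interval
        frames[k] = params.baseline + response_kernel(
            t - t_act, rise, decay, params.amplitude)
        if params.noise_sd > 0:
            frames[k] += rng.normal(0.0, params.noise_sd, size=t_act.shape)
    return frames


def gen_local_wave_stack(params: LocalWaveParams) -> tuple[ImageStack, GroundTruth]:
    """Radial wave from an instantaneous point release at ``params.origin``.

    Each pixel turns on when the diffusing agonist concentration at its
    position first exceeds ``activation_threshold``; its fluorescence then
    follows the difference-of-exponentials response.  The ground-truth front
    law is the analytic threshold-crossing radius of the kernel.
    """
    s = params.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    ox, oy = params.origin
    r_um = np.hypot(xx - ox, yy - oy) * params.pixel_size
    t_act = _point_activation_times(r_um, params.D_true, params.source_mass,
                                    params.activation_threshold)
    frames = _render_stack(t_act, params)
    stack = ImageStack(frames, params.pixel_size, params.frame_interval,
                       meta={"stimulus_frame": params.n_baseline_frames,
                             "kind": "local"})
    front = _point_front_law(params.D_true, params.source_mass,
                             params.activation_threshold)
    rise, decay = params.rise_decay
    gt = GroundTruth(front_law=front,
                     peak_law=_peak_from_front(front, rise, decay),
                     params_used=asdict(params))
    return stack, gt


def gen_distal_wave_stack(params: DistalWaveParams) -> tuple[ImageStack, GroundTruth]:
    """Distal wave spreading perpendicular to a vertical vein line.

    Intensity is constant along any line parallel to the vein; the front law
    is the 1-D threshold-crossing distance of the line-source kernel.
    """
    s = params.image_size
    xx = np.arange(s, dtype=float)
    d_um = np.abs(xx - params.vein_x) * params.pixel_size
    t_row = _line_activation_times(d_um, params.D_true, params.source_mass,
                                   params.activation_threshold)
    t_act = np.broadcast_to(t_row, (s, s)).copy()
    frames = _render_stack(t_act, params)
    stack = ImageStack(frames, params.pixel_size, params.frame_interval,
                       meta={"stimulus_frame": params.n_baseline_frames,
                             "kind": "distal"})
    front = _line_front_law(params.D_true, params.source_mass,
                            params.activation_threshold)
    rise, decay = params.rise_decay
    gt = GroundTruth(front_law=front,
                     peak_law=_peak_from_front(front, rise, decay),
                     params_used=asdict(params))
    return stack, gt


def gen_vascular_tables(params: VascularWaveParams
                        ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Distance-time tables for tracer bulk flow and the dispersion-led wave.

    Tracer front: ``d = u t``.  Calcium front: the threshold crossing of the
    advected-dispersed profile, ``d = u t + 2 sqrt(D_eff t) erfcinv(2 theta)``
    with the Aris-Taylor ``D_eff = Dm (1 + Pe^2/48)``.  Gaussian noise of SD
    ``noise_sd`` (um) is added independently to each distance.
    """
    from .transport import taylor_Deff  # local import avoids a cycle at import time

    t = params.times()
    d_eff = taylor_Deff(params.u, params.Dm, params.radius)
    g = erfcinv(2 * params.theta)
    tracer_true = params.u * t
    calcium_true = params.u * t + 2 * np.sqrt(d_eff * t) * g
    rng = np.random.default_rng(params.rng_seed)
    tracer = tracer_true + rng.normal(0, params.noise_sd, t.size) \
        if params.noise_sd > 0 else tracer_true.copy()
    calcium = calcium_true + rng.normal(0, params.noise_sd, t.size) \
        if params.noise_sd > 0 else calcium_true.copy()
    tracer_df = pd.DataFrame({"t_s": t, "distance_um": tracer})
    calcium_df = pd.DataFrame({"t_s": t, "distance_um": calcium})

    u, geff = params.u, float(g)

    def front(tq: np.ndarray) -> np.ndarray:
        tq = np.asarray(tq, dtype=float)
        return u * tq + 2 * np.sqrt(d_eff * np.clip(tq, 0, None)) * geff

    gt = GroundTruth(front_law=front, peak_law=None,
                     params_used={**asdict(params), "D_eff": float(d_eff)})
    return tracer_df, calcium_df, gt


def gen_cf_vein_image(n_veins: int, ridge_sigmas, baseline: float = 100.0,
                      noise_sd: float = 0.0, seed: int = 0, *,
                      amplitude: float = 1000.0, image_size: int = 256,
                      pixel_size: float = 1.0, base_level_frac: float = 0.2,
                      ) -> tuple[ImageStack, list[float]]:
    """Single-frame image of vertical Gaussian ridges (vein unloading halos).

    ``ridge_sigmas`` is one sigma (um) per vein, or a scalar shared by all.
    The returned true widths are the analytic crossing widths at intensity
    ``baseline + base_level_frac * amplitude`` above background, i.e.
    ``2 sigma sqrt(2 ln(1/base_level_frac))`` — the width the base-crossing
    rule recovers when ``valley + 2 sd_resid`` sits at that level.
    """
    if n_veins < 0:
        raise ConfigError("n_veins must be non-negative")
    sigmas = np.broadcast_to(np.asarray(ridge_sigmas, dtype=float),
                             (n_veins,)) if n_veins else np.empty(0)
    if n_veins and np.any(sigmas <= 0):
        raise ConfigError("ridge sigmas must be positive")
    if not 0 < base_level_frac < 1:
        raise ConfigError("base_level_frac must be in (0, 1)")
    s = image_size
    xx = np.arange(s, dtype=float)
    row = np.full(s, float(baseline))
    centers = [(i + 1) / (n_veins + 1) * s for i in range(n_veins)]
    for c, sig in zip(centers, sigmas):
        row += amplitude * np.exp(-((xx - c) * pixel_size) ** 2 / (2 * sig ** 2))
    img = np.broadcast_to(row, (s, s)).copy()
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0, noise_sd, (s, s))
    widths = [2 * sig * math.sqrt(2 * math.log(1 / base_level_frac))
              for sig in sigmas]
    stack = ImageStack(img[None], pixel_size, 1.0,
                       meta={"kind": "cf_veins", "vein_centers_px": centers})
    return stack, widths


def gen_front_table(D: float, times, noise_sd: float = 0.0,
                    seed: int | None = None, factor: float = 6.0) -> pd.DataFrame:
    """Front-law direct mode: emit ``r_i = sqrt(factor * D * t_i)`` plus noise.

    This is the exact law the diffusion fitter assumes, so fitted and
    generating D agree with no kernel-dimensionality offset.
    """
    if D <= 0:
        raise ConfigError("D must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ConfigError("times must be positive")
    r = np.sqrt(factor * D * t)
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return pd.DataFrame({"t_s": t, "distance_um": r})
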