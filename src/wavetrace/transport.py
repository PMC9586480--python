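"""Physical transport models fitted to distance-time tracks.

Local waves: nonlinear least squares of the free power law ``r(t) = a t^b``
(initialised at b = 0.8) and of the diffusion front ``r(t) = sqrt(6 D t)``
(initialised at D = 60 um^2/s).  Vascular waves: Gaussian-process regression
of the tracer bulk-flow track, an advection-dispersion front prediction with
the Aris-Taylor effective coefficient ``D_eff = Dm (1 + Pe^2 / 48)``, a
threshold-fraction fit for the channel-activation parameter, and the exact
paired sign test for tracer-vs-calcium lags.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erfcinv
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import ConfigError, DataError, FitError

__all__ = [
    "PowerLawFit",
    "DiffusionFit",
    "DispersionModel",
    "GPFit",
    "fit_power_law",
    "fit_diffusion",
    "taylor_Deff",
    "predict_wave_front",
    "fit_theta",
    "gp_fit",
    "gp_predict",
    "lag_sign_test",
]

T_LIMIT_DEFAULT = 10.0  # s; constant-flow assumption holds only early


def _clean_track(t, r, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    ok = np.isfinite(t) & np.isfinite(r)
    t, r = t[ok], r[ok]
    if np.any(t <= 0):
        raise DataError("all times must be positive")
    if t.size < min_points:
        raise FitError(f"need at least {min_points} points, got {t.size}")
    return t, r


@dataclass
class PowerLawFit:
    a: float  # um s^-b
    b: float
    a_se: float
    b_se: float
    residual_sd: float

    def __call__(self, t) -> np.ndarray:
        return self.a * np.asarray(t, dtype=float) ** self.b


@dataclass
class DiffusionFit:
    D: float  # um^2/s
    D_se: float
    residual_sd: float

    def __call__(self, t) -> np.ndarray:
        return np.sqrt(6 * self.D * np.asarray(t, dtype=float))


@dataclass
class DispersionModel:
    """Bulk flow plus Taylor dispersion with a threshold activation front."""

    u: float  # um/s
    Dm: float  # um^2/s
    radius: float  # um
    theta: float  # activation threshold fraction, in (0, 1)
    t_limit: float = T_LIMIT_DEFAULT

    def __post_init__(self) -> None:
        if self.Dm <= 0 or self.radius <= 0:
            raise ConfigError("Dm and radius must be positive")
        if self.u < 0:
            raise ConfigError("u must be non-negative")
        if not 0 < self.theta < 1:
            raise ConfigError("theta must be in (0, 1)")

    @property
    def Pe(self) -> float:
        return self.u * self.radius / self.Dm

    @property
    def D_eff(self) -> float:
        return taylor_Deff(self.u, self.Dm, self.radius)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "u_um_s": self.u, "Dm_um2_s": self.Dm, "radius_um": self.radius,
            "theta": self.theta, "t_limit_s": self.t_limit,
            "Pe": self.Pe, "D_eff_um2_s": self.D_eff}, indent=1))


def fit_power_law(t, r) -> PowerLawFit:
    """Nonlinear least squares of r(t) = a t^b, initialised at b = 0.8."""
    t, r = _clean_track(t, r, 4)
    if np.any(r <= 0):
        raise DataError("distances must be positive for the power-law fit")
    a0 = r[0] / t[0] ** 0.8
    try:
        popt, pcov = curve_fit(lambda tt, a, b: a * tt ** b, t, r,
                               p0=[a0, 0.8], maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"power-law fit did not converge: {exc}") from exc
    resid = r - popt[0] * t ** popt[1]
    dof = max(t.size - 2, 1)
    se = np.sqrt(np.diag(pcov))
    return PowerLawFit(float(popt[0]), float(popt[1]), float(se[0]),
                       float(se[1]), float(np.sqrt(resid @ resid / dof)))


def fit_diffusion(t, r) -> DiffusionFit:
    """Nonlinear least squares of r(t) = sqrt(6 D t), initialised at D = 60."""
    t, r = _clean_track(t, r, 2)
    try:
        popt, pcov = curve_fit(lambda tt, D: np.sqrt(6 * D * tt), t, r,
                               p0=[60.0], bounds=(0.0, np.inf), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"diffusion fit did not converge: {exc}") from exc
    D = float(popt[0])
    if D <= 0:
        raise FitError(f"diffusion fit produced non-positive D = {D}")
    resid = r - np.sqrt(6 * D * t)
    dof = max(t.size - 1, 1)
    return DiffusionFit(D, float(np.sqrt(pcov[0, 0])),
                        float(np.sqrt(resid @ resid / dof)))


def taylor_Deff(u: float, Dm: float, radius: float) -> float:
    """Aris-Taylor effective dispersion Dm (1 + Pe^2/48), Pe = u radius / Dm."""
    if Dm <= 0 or radius <= 0:
        raise ConfigError("Dm and radius must be positive")
    if u < 0:
        raise ConfigError("u must be non-negative")
    pe = u * radius / Dm
    return Dm * (1 + pe ** 2 / 48)


def predict_wave_front(model: DispersionModel, t) -> np.ndarray:
    """Threshold-crossing distance of the advected-dispersed profile.

    The concentration past a moving pulse edge is
    ``c(x, t) = 1/2 erfc((x - u t) / (2 sqrt(D_eff t)))`` in units of the
    source concentration, so the activation front sits at
    ``x(t) = u t + 2 sqrt(D_eff t) erfcinv(2 theta)``; for ``theta < 0.5``
    the wave leads bulk flow.  Times beyond ``model.t_limit`` warn (the
    constant-speed assumption only holds early).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DataError("t must be non-negative")
    if np.any(t > model.t_limit):
        warnings.warn(f"prediction beyond t_limit = {model.t_limit} s; "
                      "constant-flow assumption may not hold", stacklevel=2)
    g = erfcinv(2 * model.theta)
    return model.u * t + 2 * np.sqrt(model.D_eff * t) * g


@dataclass
class GPFit:
    """Squared-exponential GP regression of a distance-time track."""

    lengthscale: float  # s
    signal_variance: float
    noise_variance: float
    t_train: np.ndarray
    d_train: np.ndarray
    _gpr: GaussianProcessRegressor = field(repr=False, default=None)

    def __call__(self, t) -> np.ndarray:
        return gp_predict(self, t)[0]


def gp_fit(t, d, seed: int = 0, n_starts: int = 3) -> GPFit:
    """Fit a squared-exponential GP by marginal-likelihood maximisation.

    Multi-start optimisation (``n_starts`` restarts with a fixed seed) and a
    nugget floored at 1e-8 of the signal variance keep the fit stable on
    near-noiseless tracks.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = np.isfinite(t) & np.isfinite(d)
    t, d = t[ok], d[ok]
    if t.size < 3:
        raise FitError("need at least 3 points for GP regression")
    if np.unique(t).size < 2:
        raise DataError("degenerate track: all times equal")
    ls0 = max(np.ptp(t) / 3, 1e-6)
    # normalize_y standardises the targets, so the kernel lives on unit scale;
    # the white-noise floor is 1e-8 of the (unit) signal variance
    kernel = (ConstantKernel(1.0, (1e-4, 1e4))
              * RBF(ls0, (ls0 * 1e-3, ls0 * 1e3))
              + WhiteKernel(1e-8, (1e-8, 1e1)))
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   n_restarts_optimizer=max(n_starts - 1, 0),
                                   random_state=seed, alpha=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(t[:, None], d)
    k = gpr.kernel_
    y_var = float(np.var(d))  # back to data units
    return GPFit(lengthscale=float(k.k1.k2.length_scale),
                 signal_variance=float(k.k1.k1.constant_value) * y_var,
                 noise_variance=float(k.k2.noise_level) * y_var,
                 t_train=t, d_train=d, _gpr=gpr)


def gp_predict(fit: GPFit, t) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of the GP at times ``t``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    mean, sd = fit._gpr.predict(t[:, None], return_std=True)
    return mean, sd ** 2


def fit_theta(calcium_t, calcium_d, tracer_gp: GPFit, u: float, Dm: float,
              radius: float, t_limit: float = T_LIMIT_DEFAULT) -> DispersionModel:
    """Fit the channel-activation threshold fraction theta.

    Minimises the squared distance between the calcium track and the tracer
    GP mean plus the dispersion lead ``2 sqrt(D_eff t) erfcinv(2 theta)``.
    ``u`` enters only through ``D_eff`` (it is a stated parameter, never
    re-fit).  The least-squares solution is closed form in
    ``g = erfcinv(2 theta)``; ``theta = erfc(g)/2`` always lies in (0, 1).
    """
    from scipy.special import erfc

    t = np.asarray(calcium_t, dtype=float)
    d = np.asarray(calcium_d, dtype=float)
    ok = np.isfinite(t) & np.isfinite(d) & (t > 0)
    t, d = t[ok], d[ok]
    if t.size == 0:
        raise FitError("no usable calcium points")
    if np.any(t > t_limit):
        warnings.warn(f"calcium points beyond t_limit = {t_limit} s are "
                      "excluded from the theta fit", stacklevel=2)
        keep = t <= t_limit
        t, d = t[keep], d[keep]
        if t.size == 0:
            raise FitError("no calcium points within t_limit")
    d_eff = taylor_Deff(u, Dm, radius)
    mu = gp_predict(tracer_gp, t)[0]
    w = 2 * np.sqrt(d_eff * t)
    g = float(np.sum(w * (d - mu)) / np.sum(w ** 2))
    if g < 0:
        warnings.warn("calcium lags the tracer: fitted theta > 0.5 is "
                      "unphysical under the dispersion model", stacklevel=2)
    theta = float(erfc(g) / 2)
    eps = 1e-12
    theta = min(max(theta, eps), 1 - eps)
    return DispersionModel(u=u, Dm=Dm, radius=radius, theta=theta,
                           t_limit=t_limit)


def lag_sign_test(lags) -> dict:
    """Exact two-sided binomial sign test of paired lag signs.

    ``lags`` are per-replicate differences (e.g. calcium front minus tracer
    front); zeros (ties) are excluded from n and reported.  The p-value is
    the doubled one-sided tail under Binomial(n, 1/2), capped at 1.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise DataError("need at least one paired replicate")
    ties = int(np.sum(lags == 0))
    signs = lags[lags != 0] > 0
    n = int(signs.size)
    if n == 0:
        raise DataError("all lags are ties; sign test undefined")
    k = int(signs.sum())
    k_extreme = max(k, n - k)
    tail = sum(math.comb(n, i) for i in range(k_extreme, n + 1)) / 2 ** n
    p = min(1.0, 2 * tail)
    return {"n": n, "n_positive": k, "n_ties": ties, "p_value": p}
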