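"""Cross-replicate kinematic summaries and group comparisons.

Each replicate's distance-time track is condensed to a degree-6 polynomial
through the origin; replicate curves are averaged coefficient-wise and the
analytic first derivative gives the wave velocity.  Vascular tracks get a
through-origin straight-line speed.  Group comparisons: pooled-variance
two-sample t tests per time point, and pairwise Wilcoxon rank-sum tests
(exact for small samples) with optional Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FitError

__all__ = [
    "PolyFit",
    "SpeedFit",
    "fit_poly6_origin",
    "mean_curve",
    "velocity",
    "fit_vascular_speed",
    "compare_tracks_pointwise",
    "compare_speeds",
]

DEGREE = 6


@dataclass
class PolyFit:
    """p(t) = c1 t + c2 t^2 + ... + c6 t^6 (um vs s); no intercept exists."""

    coefficients: np.ndarray  # (6,) c1..c6
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (DEGREE,):
            raise ConfigError(f"expected {DEGREE} coefficients")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        powers = np.stack([t ** k for k in range(1, DEGREE + 1)])
        return np.tensordot(self.coefficients, powers, axes=1)


@dataclass
class SpeedFit:
    """Through-origin straight-line speed of a vascular track."""

    slope: float  # um/s
    replicate_id: str | None = None

    def __call__(self, t) -> np.ndarray:
        return self.slope * np.asarray(t, dtype=float)


def fit_poly6_origin(t, distance, replicate_id: str | None = None) -> PolyFit:
    """Least squares over the six through-origin monomials t..t^6.

    Times are rescaled to [0, 1] internally for conditioning; the returned
    coefficients are on the original time scale.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(distance, dtype=float)
    ok = np.isfinite(t) & np.isfinite(d)
    t, d = t[ok], d[ok]
    if t.size < DEGREE + 1:
        raise FitError(f"need at least {DEGREE + 1} points, got {t.size}")
    scale = np.abs(t).max()
    if scale == 0:
        raise FitError("all times are zero")
    ts = t / scale
    design = np.stack([ts ** k for k in range(1, DEGREE + 1)], axis=1)
    if np.linalg.matrix_rank(design) < DEGREE:
        raise FitError("rank-deficient design (too few distinct times)")
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    coef = coef / scale ** np.arange(1, DEGREE + 1)
    return PolyFit(coef, replicate_id)


def mean_curve(fits: list[PolyFit]) -> PolyFit:
    """Coefficient-wise mean polynomial across replicates."""
    if not fits:
        raise ConfigError("no fits to average")
    coef = np.mean([f.coefficients for f in fits], axis=0)
    return PolyFit(coef, replicate_id="mean")


def velocity(fit: PolyFit, t) -> np.ndarray:
    """Analytic first derivative c1 + 2 c2 t + ... + 6 c6 t^5 (um/s)."""
    t = np.asarray(t, dtype=float)
    k = np.arange(1, DEGREE + 1)
    powers = np.stack([t ** (j - 1) for j in k])
    return np.tensordot(fit.coefficients * k, powers, axes=1)


def fit_vascular_speed(t, distance, replicate_id: str | None = None) -> SpeedFit:
    """Through-origin least-squares slope: sum(t d) / sum(t^2)."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(distance, dtype=float)
    ok = np.isfinite(t) & np.isfinite(d)
    t, d = t[ok], d[ok]
    if t.size < 2:
        raise FitError("need at least 2 points")
    denom = float(np.sum(t ** 2))
    if denom == 0:
        raise FitError("all times are zero")
    return SpeedFit(float(np.sum(t * d) / denom), replicate_id)


def _pooled_t_test(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    if np.ptp(np.r_[a, b]) == 0:  # identical constant groups: no evidence
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_tracks_pointwise(group_a, group_b, welch: bool = False,
                             decimals: int = 6) -> pd.DataFrame:
    """Two-sample t test of tracked distances at each shared time point.

    ``group_a``/``group_b`` are lists of ``(t, distance)`` array pairs, one
    per replicate.  A time point is tested only when both groups contribute
    at least two finite replicates there (matching on time rounded to
    ``decimals``).  Student's pooled-variance test by default; Welch behind
    the flag.
    """
    def collect(group):
        table: dict[float, list[float]] = {}
        for t, d in group:
            t = np.round(np.asarray(t, dtype=float), decimals)
            d = np.asarray(d, dtype=float)
            for ti, di in zip(t, d):
                if np.isfinite(di):
                    table.setdefault(float(ti), []).append(float(di))
        return table

    ta, tb = collect(group_a), collect(group_b)
    rows = []
    for time in sorted(set(ta) & set(tb)):
        a, b = np.asarray(ta[time]), np.asarray(tb[time])
        if a.size < 2 or b.size < 2:
            continue
        stat, p = _pooled_t_test(a, b, welch)
        rows.append({"t_s": time, "n_a": a.size, "n_b": b.size,
                     "mean_a": a.mean(), "mean_b": b.mean(),
                     "t_stat": stat, "p_value": p})
    return pd.DataFrame(rows, columns=["t_s", "n_a", "n_b", "mean_a",
                                       "mean_b", "t_stat", "p_value"])


def _ranksum_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 10) -> float:
    if np.ptp(np.r_[a, b]) == 0:
        return 1.0
    has_ties = np.unique(np.r_[a, b]).size < a.size + b.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_speeds(groups: dict[str, list[SpeedFit]] | list[list[SpeedFit]],
                   correction: str = "bonferroni") -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests between groups of fitted speeds.

    Exact null distribution when both groups have n <= 10 (and no ties),
    normal approximation otherwise.  ``correction='bonferroni'`` multiplies
    each p by the number of pairwise comparisons, capped at 1.
    """
    if correction not in ("none", "bonferroni"):
        raise ConfigError("correction must be 'none' or 'bonferroni'")
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for ga, gb in pairs:
        a = np.asarray([f.slope for f in groups[ga]], dtype=float)
        b = np.asarray([f.slope for f in groups[gb]], dtype=float)
        p = _ranksum_p(a, b)
        p_adj = min(1.0, p * len(pairs)) if correction == "bonferroni" else p
        rows.append({"group_a": ga, "group_b": gb, "n_a": a.size,
                     "n_b": b.size, "p_value": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "p_value", "p_adjusted"])
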