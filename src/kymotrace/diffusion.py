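"""Mean-square-displacement analysis and diffusion-coefficient estimation.

The time-averaged MSD of a uniformly sampled trajectory is

    msd[n] = sum_{i=1..N-n} (X_{i+n} - X_i)^2 / (N - n),   n = 1..N-1

and is fit linearly on a restricted lag window (default 0.25-2 s) to avoid
the noisy long-lag tail and short-lag localization error.  Two slope
conventions are supported: ``paper`` reports D = slope (matching the
published "MSD = D t + b" fit), ``physical`` reports D = slope / 2 (the 1D
Einstein relation MSD = 2 D t).  Every fit records which one was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from kymotrace.io import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "SpeedResult",
    "compute_msd",
    "fit_msd",
    "classify_motion",
    "ensemble_D",
    "mean_speed",
    "regress_condition",
]


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("msd must be non-negative")
        if np.any(np.diff(self.counts) >= 0):
            raise ValueError("pair counts must be strictly decreasing")


@dataclass
class DiffusionFit:
    D_um2_s: float
    intercept_b_um2: float
    alpha: float
    r_squared: float
    alpha_r_squared: float
    fit_window_s: tuple[float, float]
    slope_convention: str
    motion_class: str = "free"
    trajectory_id: int | None = None


@dataclass
class SpeedResult:
    mean_speed_um_s: float
    total_route_um: float
    total_time_s: float


def compute_msd(traj: Trajectory, rtol: float = 1e-6) -> MSDCurve:
    """Time-averaged MSD over all lags n = 1..N-1.

    Requires uniform sampling (within ``rtol`` of the median interval).
    """
    dt = np.diff(traj.times_s)
    dt0 = np.median(dt)
    if np.any(np.abs(dt - dt0) > rtol * dt0 + 1e-12):
        raise ValueError("non-uniform sampling interval")
    x = traj.positions_um
    n_samples = x.size
    lags = np.arange(1, n_samples)
    msd = np.empty(n_samples - 1)
    for n in lags:
        d = x[n:] - x[:-n]
        msd[n - 1] = np.mean(d * d)
    return MSDCurve(lags_s=lags * dt0, msd_um2=msd, counts=n_samples - lags)


def fit_msd(
    msd: MSDCurve,
    window_s: tuple[float, float] = (0.25, 2.0),
    convention: str = "paper",
) -> DiffusionFit:
    """OLS line on the windowed MSD plus log-log power-law exponent.

    D is the slope (``paper``) or slope/2 (``physical``); b the intercept.
    alpha comes from an OLS fit of log(msd) vs log(tau) on the same window.
    """
    if convention not in ("paper", "physical"):
        raise ValueError("convention must be 'paper' or 'physical'")
    lo, hi = window_s
    mask = (msd.lags_s > lo) & (msd.lags_s < hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 lags inside the fit window")
    tau = msd.lags_s[mask]
    y = msd.msd_um2[mask]
    slope, intercept, r, _, _ = stats.linregress(tau, y)
    if np.allclose(y, y[0]):
        r = 1.0 if np.allclose(slope, 0.0) else r
    pos = y > 0
    if pos.sum() >= 3:
        alpha, _, r_a, _, _ = stats.linregress(np.log(tau[pos]), np.log(y[pos]))
        alpha_r2 = float(r_a**2)
    else:
        alpha, alpha_r2 = 0.0, 0.0  # flat (static) MSD: no power law defined
    D = float(slope) if convention == "paper" else float(slope) / 2.0
    return DiffusionFit(
        D_um2_s=D,
        intercept_b_um2=float(intercept),
        alpha=float(alpha),
        r_squared=float(r**2) if np.isfinite(r) else 0.0,
        alpha_r_squared=alpha_r2,
        fit_window_s=(lo, hi),
        slope_convention=convention,
    )


def classify_motion(
    fit: DiffusionFit,
    static_threshold_um2_s: float = 0.01,
    alpha_directed_margin: float = 0.2,
) -> str:
    """static (D at or below threshold), directed (super-diffusive), or free."""
    if fit.D_um2_s <= static_threshold_um2_s:
        return "static"
    if fit.alpha > 1.0 + alpha_directed_margin:
        return "directed"
    return "free"


@dataclass
class EnsembleSummary:
    mean_D_um2_s: float
    ci95_um2_s: tuple[float, float]
    n: int
    static_fraction: float
    hist_counts: np.ndarray
    hist_edges_um2_s: np.ndarray


def ensemble_D(
    fits: list[DiffusionFit],
    exclude_static: bool = False,
    static_threshold_um2_s: float = 0.01,
    bin_width_um2_s: float = 0.01,
) -> EnsembleSummary:
    """Population summary of fitted D values.

    With ``exclude_static`` the slow/static molecules (D at or below the
    threshold — the histogram's first bin) are dropped before the mean/CI,
    giving the "corrected" population D.  Individual fits are never altered.
    """
    if not fits:
        raise ValueError("need at least one fit")
    D = np.array([f.D_um2_s for f in fits])
    static_fraction = float(np.mean(D <= static_threshold_um2_s))
    if exclude_static:
        D = D[D > static_threshold_um2_s]
        if D.size == 0:
            raise ValueError("no fits remain after static exclusion")
    mean = float(np.mean(D))
    if D.size > 1:
        sem = stats.sem(D)
        half = sem * stats.t.ppf(0.975, D.size - 1)
    else:
        half = 0.0
    hi_edge = max(bin_width_um2_s, np.ceil(max(D.max(), 0) / bin_width_um2_s) * bin_width_um2_s)
    edges = np.arange(0.0, hi_edge + bin_width_um2_s / 2, bin_width_um2_s)
    counts, _ = np.histogram(D, bins=edges)
    return EnsembleSummary(
        mean_D_um2_s=mean,
        ci95_um2_s=(mean - half, mean + half),
        n=int(D.size),
        static_fraction=static_fraction,
        hist_counts=counts,
        hist_edges_um2_s=edges,
    )


def mean_speed(traj: Trajectory) -> SpeedResult:
    """Total route (sum of frame-to-frame displacements) over total time.

    Apply Savitzky-Golay smoothing first (tracking.smooth) when suppressing
    thermal fluctuation of the tracked position is desired.
    """
    route = float(np.sum(np.abs(np.diff(traj.positions_um))))
    total = traj.duration_s
    return SpeedResult(
        mean_speed_um_s=route / total if total > 0 else 0.0,
        total_route_um=route,
        total_time_s=total,
    )


def regress_condition(
    series: list[tuple[float, np.ndarray]],
) -> dict:
    """Weighted linear regression of per-condition means vs condition value.

    ``series`` is [(condition, per-molecule values), ...]; means are weighted
    by their sample counts.  Returns slope, stderr, intercept and r^2 (0 when
    the response is constant).
    """
    conditions = np.array([c for c, _ in series], dtype=float)
    if np.unique(conditions).size < 2:
        raise ValueError("need at least 2 distinct condition values")
    means = np.array([float(np.mean(np.asarray(v, dtype=float))) for _, v in series])
    weights = np.array([len(np.asarray(v)) for _, v in series], dtype=float)
    W = np.diag(weights)
    X = np.column_stack([np.ones_like(conditions), conditions])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(weights) * means, rcond=None)
    intercept, slope = beta
    resid = means - (intercept + slope * conditions)
    dof = len(series) - 2
    wmean = np.average(means, weights=weights)
    ss_tot = float(np.sum(weights * (means - wmean) ** 2))
    ss_res = float(np.sum(weights * resid**2))
    r2 = 0.0 if ss_tot <= 0 else 1.0 - ss_res / ss_tot
    if dof > 0 and ss_tot > 0:
        s2 = ss_res / dof
        sxx = float(np.sum(weights * (conditions - np.average(conditions, weights=weights)) ** 2))
        se = float(np.sqrt(s2 / sxx))
    else:
        se = 0.0
    return {
        "slope": float(slope),
        "stderr": se,
        "intercept": float(intercept),
        "r_squared": max(0.0, float(r2)),
    }
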