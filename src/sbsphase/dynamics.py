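"""Steady-state time correlations and reduced-to-physical unit conversion.

The persistence of single-molecule structure is measured by the mean
distance-corrected correlation r' between distance matrices of the same
molecule at increasing lag times: in the coil state it decays to zero (the
contact pattern is fully transient) while in the globule phase-separated
state it plateaus well above zero (globules breathe but persist).  A
stretched exponential ``f(t) = f_inf + (f0 - f_inf) exp[-(t/tau_s)^beta]``
summarizes the decay; the decay time itself is defined on the raw curve as
the lag where 95% of the total variation range has been spanned.

Physical units: the bead diameter sigma (nm) is calibrated by equating the
medians of the model and experimental gyration-radius distributions, the MD
time unit is the Brownian time ``tau = 6 pi eta sigma^3 / (kB T)`` and molar
binder concentration is ``c = P / (V NA)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import AVOGADRO, Conformation, Ensemble, PolymerModel
from .metrics import distance_matrix, _window_centroids

KB = 1.380649e-23  # J/K

__all__ = [
    "Trajectory",
    "PhysicalUnits",
    "time_correlation",
    "stretched_exp_fit",
    "decay_time",
    "calibrate_sigma",
    "md_time_unit",
    "molar_concentration",
    "binder_count",
    "pair_distance_series",
]


@dataclass
class Trajectory:
    """Uniformly spaced steady-state frames of one molecule."""

    frames: list[Conformation]
    dt_frames: float  # MD time (tau units) between stored frames
    model: PolymerModel | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.dt_frames <= 0:
            raise ValueError("dt_frames must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PhysicalUnits:
    """Unit calibration block; viscosity default is the nucleoplasm estimate."""

    sigma_nm: float = 45.0
    eta: float = 0.003  # Pa s  (= 0.03 Poise)
    temperature_K: float = 310.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.eta < 0 or self.temperature_K <= 0:
            raise ValueError("physical units must be positive (eta >= 0)")

    @property
    def tau_seconds(self) -> float:
        return md_time_unit(self)


# ---------------------------------------------------------------------------
# time correlations
# ---------------------------------------------------------------------------


def time_correlation(
    trajectories: Trajectory | list[Trajectory],
    lags=None,
    smooth_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean r' between frame pairs at each lag (averaged over molecules).

    Returns (lags, curve); lag 0 is exactly 1.  Lags not shorter than the
    trajectory are skipped with a warning.
    """
    from .metrics import gaussian_smooth

    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    n_frames = min(len(t) for t in trajs)
    if lags is None:
        lags = np.arange(0, n_frames)
    lags = np.asarray(sorted(set(int(v) for v in lags)))
    good = lags < n_frames
    if not good.all():
        warnings.warn("lags beyond the trajectory length skipped", RuntimeWarning)
        lags = lags[good]
    from .metrics import subtract_diagonal_means

    # r' factorizes: each matrix's per-diagonal means are subtracted
    # independently, so the residual vectors can be precomputed per frame
    resids = []
    for t in trajs:
        model = t.model
        ms = [distance_matrix(f, model) for f in t.frames]
        if smooth_sd:
            ms = [gaussian_smooth(m, smooth_sd) for m in ms]
        W = ms[0].values.shape[0]
        iu = np.triu_indices(W, k=1)
        resids.append(
            np.stack([subtract_diagonal_means(m)[iu] for m in ms])
        )
    curve = np.empty(lags.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, lag in enumerate(lags):
            if lag == 0:
                curve[k] = 1.0
                continue
            vals = []
            for R in resids:
                a = R[: R.shape[0] - lag]
                b = R[lag:]
                am = a - a.mean(axis=1, keepdims=True)
                bm = b - b.mean(axis=1, keepdims=True)
                denom = np.sqrt((am**2).sum(1) * (bm**2).sum(1))
                good = denom > 0
                vals.extend(((am * bm).sum(1)[good] / denom[good]).tolist())
            curve[k] = float(np.nanmean(vals)) if vals else float("nan")
    return lags, curve


def stretched_exp_fit(
    lags: np.ndarray, curve: np.ndarray
) -> dict:
    """Least-squares stretched-exponential fit of a decay curve.

    Model: ``f(t) = f_inf + (f0 - f_inf) exp[-(t/tau_s)^beta]``, beta in
    (0, 2].  Non-convergence (or an unidentifiable constant curve) is
    signaled via ``converged=False``; the raw curve remains usable for
    ``decay_time``.
    """
    t = np.asarray(lags, dtype=float)
    f = np.asarray(curve, dtype=float)
    ok = np.isfinite(f)
    t, f = t[ok], f[ok]
    if t.size < 4 or np.ptp(f) < 1e-12:
        return {
            "f0": float(f[0]) if f.size else float("nan"),
            "f_inf": float(f[-1]) if f.size else float("nan"),
            "tau_s": float("nan"),
            "beta": float("nan"),
            "residual": float("nan"),
            "converged": False,
        }

    def model(tt, f0, finf, tau, beta):
        return finf + (f0 - finf) * np.exp(-((tt / tau) ** beta))

    p0 = (f[0], f[-1], max(t[-1] / 3.0, 1e-6), 1.0)
    try:
        popt, _ = curve_fit(
            model,
            t,
            f,
            p0=p0,
            bounds=([-2.0, -2.0, 1e-9, 1e-3], [2.0, 2.0, np.inf, 2.0]),
            maxfev=20_000,
        )
        resid = float(np.sqrt(np.mean((model(t, *popt) - f) ** 2)))
        return {
            "f0": float(popt[0]),
            "f_inf": float(popt[1]),
            "tau_s": float(popt[2]),
            "beta": float(popt[3]),
            "residual": resid,
            "converged": True,
        }
    except RuntimeError:
        return {
            "f0": float(f[0]),
            "f_inf": float(f[-1]),
            "tau_s": float("nan"),
            "beta": float("nan"),
            "residual": float("nan"),
            "converged": False,
        }


def decay_time(
    lags: np.ndarray, curve: np.ndarray, plateau_fraction: float = 0.1
) -> float:
    """Lag where the curve has spanned 95% of its total variation range.

    The plateau is estimated as the mean over the final ``plateau_fraction``
    of lags; the decay time is the smallest lag with
    ``f0 - f(t) >= 0.95 (f0 - plateau)``.
    """
    t = np.asarray(lags, dtype=float)
    f = np.asarray(curve, dtype=float)
    ok = np.isfinite(f)
    t, f = t[ok], f[ok]
    if t.size < 3:
        raise ValueError("curve too short")
    f0 = f[0]
    k = max(1, int(np.ceil(plateau_fraction * f.size)))
    plateau = f[-k:].mean()
    span = f0 - plateau
    if abs(span) < 1e-15:
        return float(t[0])
    crossed = np.where((f0 - f) >= 0.95 * span)[0]
    return float(t[crossed[0]]) if crossed.size else float(t[-1])


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------


def calibrate_sigma(
    model_rg_sigma: np.ndarray, experimental_rg_nm: np.ndarray
) -> float:
    """Bead diameter (nm) equating the median model and experimental Rg."""
    m = np.asarray(model_rg_sigma, dtype=float)
    e = np.asarray(experimental_rg_nm, dtype=float)
    m, e = m[np.isfinite(m)], e[np.isfinite(e)]
    if m.size == 0 or e.size == 0:
        raise ValueError("empty gyration-radius distribution")
    med = np.median(m)
    if med <= 0:
        raise ValueError("non-positive model Rg median")
    return float(np.median(e) / med)


def md_time_unit(units: PhysicalUnits) -> float:
    """Brownian time tau = 6 pi eta sigma^3 / (kB T) in seconds."""
    sigma_m = units.sigma_nm * 1e-9
    return float(6.0 * math.pi * units.eta * sigma_m**3 / (KB * units.temperature_K))


def molar_concentration(P: int, volume_l: float) -> float:
    """Molar concentration c = P / (V NA) for P binders in V litres."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if P < 0:
        raise ValueError("binder count must be >= 0")
    return float(P / (volume_l * AVOGADRO))


def binder_count(c: float, volume_l: float) -> tuple[int, float]:
    """Inverse of molar_concentration; returns (P, rounding applied)."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    exact = c * volume_l * AVOGADRO
    P = int(round(exact))
    return P, float(P - exact)


# ---------------------------------------------------------------------------
# site-pair distances
# ---------------------------------------------------------------------------


def pair_distance_series(
    source: Trajectory | Ensemble,
    window_pair: tuple[int, int],
    sigma_nm: float = 45.0,
    cap_nm: float = 2000.0,
) -> dict:
    """Per-frame physical distance (nm) of two window centroids.

    Distances above ``cap_nm`` are excluded from the distribution summary as
    outliers (their count is reported); an all-above-cap series yields an
    empty distribution, flagged via ``n_kept = 0``.
    """
    i, j = window_pair
    if isinstance(source, Trajectory):
        confs, model = source.frames, source.model
    else:
        confs, model = source.conformations, source.model
    track = np.empty(len(confs))
    for k, conf in enumerate(confs):
        cent = _window_centroids(conf, model)
        track[k] = np.linalg.norm(cent[i] - cent[j]) * sigma_nm
    kept = track[track <= cap_nm]
    if kept.size == 0:
        warnings.warn("all distances above the cap; empty distribution", RuntimeWarning)
    return {
        "track_nm": track,
        "mean_nm": float(kept.mean()) if kept.size else float("nan"),
        "sd_nm": float(kept.std(ddof=1)) if kept.size > 1 else float("nan"),
        "n_kept": int(kept.size),
        "n_capped": int(track.size - kept.size),
        "cap_nm": cap_nm,
    }
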