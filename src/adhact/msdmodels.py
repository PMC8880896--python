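"""Mean-squared-displacement models and fitting.

Model family
------------
* Fürth (persistent random walk):
  ``MSD(t) = 4 nu^2 gamma^2 (t/gamma - 1 + exp(-t/gamma))`` — ballistic at
  short lags, diffusive at long lags with persistence time ``gamma``.
* Extended Fürth: adds a translational-diffusion term ``D_T t`` accounting
  for short-time membrane fluctuations.
* Anomalous variant: adds ``D_T t^beta`` instead.
* Fractional Klein-Kramers (FKK):
  ``MSD(t) = 4 nu^2 t^2 E_{alpha,3}(-gamma_alpha t^alpha) + noise`` with
  ``E_{alpha,3}`` the two-parameter Mittag-Leffler function; the noise term
  is either a constant ``(2 eta)^2`` or translational diffusion ``D_T t``.
  ``alpha = 1`` with ``eta = 0`` recovers the Fürth form; ``alpha > 1``
  gives long-term subdiffusion (log-log slope ``2 - alpha``), ``alpha < 1``
  superdiffusion.

Fitting happens in log-log space over log-uniformly thinned lags, matching
how such curves are judged across several decades of lag time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln, rgamma

from .tracks import MSDCurve

__all__ = [
    "furth",
    "furth_translational",
    "furth_anomalous",
    "mittag_leffler_2p",
    "fkk_msd",
    "fit_msd",
    "FitResult",
]

_ML_RTOL = 1e-11
_ML_BETA = 3.0  # second Mittag-Leffler parameter used by the FKK MSD


def furth(t, nu: float, gamma: float):
    """Fürth MSD of a 2D persistent random walker."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = np.asarray(t, dtype=float)
    x = t / gamma
    # expm1 keeps the short-lag ballistic limit accurate
    return 4.0 * nu**2 * gamma**2 * (x + np.expm1(-x))


def furth_translational(t, nu: float, gamma: float, d_t: float):
    """Fürth MSD plus translational diffusion ``D_T t``."""
    return furth(t, nu, gamma) + d_t * np.asarray(t, dtype=float)


def furth_anomalous(t, nu: float, gamma: float, d_t: float, beta: float):
    """Fürth MSD plus anomalous diffusion ``D_T t^beta``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return furth(t, nu, gamma) + d_t * np.asarray(t, dtype=float) ** beta


# -- generalized Mittag-Leffler E_{alpha,3} ---------------------------------


def _ml_series_float(alpha: float, z: float) -> tuple[float, float, float]:
    """Taylor series sum, relative-error estimate, and log10 of the largest
    term (the cancellation scale), in float64."""
    total = 0.0
    max_term = 0.0
    term = 0.0
    lz = math.log(abs(z))
    for k in range(0, 400):
        log_term = k * lz - gammaln(alpha * k + _ML_BETA)
        if log_term > 700.0:  # would overflow float64
            return 0.0, math.inf, log_term / math.log(10.0)
        term = math.exp(log_term)
        if z < 0 and k % 2 == 1:
            term = -term
        total += term
        a = abs(term)
        if a > max_term:
            max_term = a
        if a < 1e-17 * max(abs(total), 1e-300) and k > 3:
            break
    log10_max = math.log10(max_term) if max_term > 0 else -math.inf
    if total == 0.0:
        return 0.0, math.inf, log10_max
    est = (2e-15 * max_term + abs(term)) / abs(total)
    return total, est, log10_max


def _ml_asymptotic(alpha: float, z: float) -> tuple[float, float]:
    """Algebraic large-|z| expansion on the negative axis with error estimate.

    ``E_{a,b}(z) ~ -sum_k z^{-k} / Gamma(b - a k)``; the estimate combines the
    optimal-truncation term with the size of the leading exponentially small
    contribution (present on the principal sheet only for alpha >= 1).
    """
    total = 0.0
    prev = math.inf
    trunc = 0.0  # first omitted term (optimal truncation error scale)
    for k in range(1, 80):
        term = -(z ** (-k)) * rgamma(_ML_BETA - alpha * k)
        a = abs(term)
        if a > prev:
            trunc = a
            break
        total += term
        prev = a
    exp_est = 0.0
    if alpha >= 1.0:
        r = abs(z) ** (1.0 / alpha)
        c = math.cos(math.pi / alpha)
        arg = r * c
        exp_est = r ** (1.0 - _ML_BETA) * math.exp(max(arg, -700.0)) / alpha
    if total == 0.0:
        return 0.0, math.inf
    est = (trunc + exp_est) / abs(total) + 2e-16
    return total, est


def _ml_mpmath(alpha: float, z: float, dps: int = 30, max_dps: int = 200) -> float:
    """Arbitrary-precision Taylor series (cancellation-safe fallback)."""
    import mpmath as mp

    for _ in range(4):
        dps = min(dps, max_dps)
        with mp.workdps(dps):
            za = mp.mpf(z)
            al = mp.mpf(alpha)  # gamma argument must be formed in mp precision
            total = mp.mpf(0)
            max_term = mp.mpf(0)
            k = 0
            while True:
                term = za**k / mp.gamma(al * k + _ML_BETA)
                total += term
                if abs(term) > max_term:
                    max_term = abs(term)
                if k > 3 and abs(term) < mp.mpf(10) ** (-dps - 2) * max(abs(total), mp.mpf("1e-300")):
                    break
                k += 1
            if total != 0:
                cancel = mp.log10(max_term / abs(total))
                if cancel + 16 < dps:
                    return float(total)
                dps = int(cancel) + 26
            else:
                dps += 20
    return float(total)


def _ml_scalar(alpha: float, z: float, rtol: float = _ML_RTOL) -> float:
    if z == 0.0:
        return 1.0 / math.gamma(_ML_BETA)
    if z > 0.0:
        raise ValueError("E_{alpha,3} evaluation is supported for z <= 0 only")
    value_s, est_s, log10_max = _ml_series_float(alpha, z)
    if est_s <= rtol:
        return value_s
    value_a, est_a = _ml_asymptotic(alpha, z)
    if est_a <= rtol:
        return value_a
    # decimal digits lost to cancellation: compare the largest series term
    # with the best available estimate of the true magnitude
    mag = abs(value_a) if (math.isfinite(value_a) and value_a != 0.0) else abs(value_s)
    if mag > 0.0 and math.isfinite(log10_max):
        digits = log10_max - math.log10(mag) + 18.0
    else:
        digits = math.inf
    if digits <= 160.0:
        return _ml_mpmath(alpha, z, dps=int(digits) + 12)
    # extreme band (small alpha or alpha near 2 with huge |z|): settle for
    # the better fast-branch estimate; the model-curve error there is far
    # below the sampling noise of any fitted MSD
    return value_a if est_a <= est_s else value_s


def mittag_leffler_2p(alpha: float, z, rtol: float = _ML_RTOL):
    """Generalized Mittag-Leffler function ``E_{alpha,3}(z)`` for real z <= 0.

    Hybrid evaluation: float64 Taylor series where cancellation is benign,
    the algebraic asymptotic expansion for large ``|z|``, and an
    arbitrary-precision series in the intermediate band, targeting a
    relative accuracy of ``rtol`` (about 1e-11 by default; fitting relaxes
    this to skip the expensive band).
    """
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must be in (0, 2), got {alpha}")
    z_arr = np.asarray(z, dtype=float)
    out = np.empty(z_arr.shape, dtype=float)
    for idx, zv in np.ndenumerate(z_arr):
        out[idx] = _ml_scalar(alpha, float(zv), rtol)
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(out.reshape(-1)[0])
    return out


def fkk_msd(t, nu: float, gamma_alpha: float, alpha: float, d_t: float = 0.0,
            eta: float = 0.0, ml_rtol: float = _ML_RTOL):
    """Fractional Klein-Kramers MSD, with translational-diffusion noise
    ``D_T t`` and/or constant noise ``(2 eta)^2``."""
    if gamma_alpha <= 0:
        raise ValueError("gamma_alpha must be positive")
    t = np.asarray(t, dtype=float)
    ml = mittag_leffler_2p(alpha, -gamma_alpha * t**alpha, rtol=ml_rtol)
    return 4.0 * nu**2 * t**2 * np.asarray(ml) + d_t * t + (2.0 * eta) ** 2


# -- fitting ----------------------------------------------------------------

_MODELS = ("furth", "furth_dt", "furth_beta", "fkk", "fkk_eta")


@dataclass
class FitResult:
    """Best-fit parameters of one MSD model on one curve."""

    model: str
    params: dict = field(default_factory=dict)
    residual: float = math.inf  # sum of squared log-space errors
    window: tuple = (0, 0)
    n_points: int = 0
    n_replicates: int = 0
    converged: bool = False

    def predict(self, t):
        return _evaluate(self.model, np.asarray(t, dtype=float), self.params)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "residual": self.residual,
            "window": list(self.window),
            "n_points": self.n_points,
            "n_replicates": self.n_replicates,
            "converged": self.converged,
        }


def _evaluate(model: str, t: np.ndarray, p: dict) -> np.ndarray:
    if model == "furth":
        return furth(t, p["nu"], p["gamma"])
    if model == "furth_dt":
        return furth_translational(t, p["nu"], p["gamma"], p["d_t"])
    if model == "furth_beta":
        return furth_anomalous(t, p["nu"], p["gamma"], p["d_t"], p["beta"])
    if model == "fkk":
        return fkk_msd(t, p["nu"], p["gamma_alpha"], p["alpha"], d_t=p["d_t"],
                       ml_rtol=1e-8)
    if model == "fkk_eta":
        return fkk_msd(t, p["nu"], p["gamma_alpha"], p["alpha"], eta=p["eta"],
                       ml_rtol=1e-8)
    raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")


def _thin_lags(lag: np.ndarray, n_max: int = 80) -> np.ndarray:
    """Log-uniform subset of lag indices (unique, sorted)."""
    if lag.size <= n_max:
        return np.arange(lag.size)
    grid = np.geomspace(lag[0], lag[-1], n_max)
    idx = np.unique(np.searchsorted(lag, grid).clip(0, lag.size - 1))
    return idx


def fit_msd(
    curve: MSDCurve,
    model: str = "furth_dt",
    fit_window: tuple | None = None,
    min_lag: float = 10.0,
    n_max_points: int = 80,
) -> FitResult:
    """Nonlinear least squares on log(MSD) vs log(lag).

    Lags below ``min_lag`` (lattice-discreteness noise) and outside
    ``fit_window`` are excluded; the remaining lags are thinned to at most
    ``n_max_points`` log-uniform points so every decade carries similar
    weight.  Positive parameters are optimised in log space;
    ``alpha``/``beta`` are bounded in (0, 2).  Multi-start: the simpler
    Fürth-family seed plus a grid of fractional orders.  A fit that never
    converges is returned flagged, not raised.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    lag = np.asarray(curve.lag, dtype=float)
    msd = np.asarray(curve.msd, dtype=float)
    lo = min_lag if fit_window is None else max(min_lag, fit_window[0])
    hi = lag.max() if fit_window is None else fit_window[1]
    mask = (lag >= lo) & (lag <= hi) & (msd > 0)
    lag, msd = lag[mask], msd[mask]
    if lag.size < 10:
        raise ValueError("need at least 10 positive MSD points inside the window")
    idx = _thin_lags(lag, n_max_points)
    lag, msd = lag[idx], msd[idx]
    log_msd = np.log(msd)
    window = (float(lag[0]), float(lag[-1]))

    # crude seeds: short-lag ballistic speed, late-lag diffusivity
    t0, m0 = lag[0], msd[0]
    nu0 = max(np.sqrt(m0 / (2.0 * t0**2)), 1e-6)
    d_long = max((msd[-1] - msd[-2]) / (lag[-1] - lag[-2]), 1e-12)
    gamma0 = max(d_long / (4.0 * nu0**2), 2.0 * t0)
    dt0 = max(d_long * 0.05, 1e-9)

    def pack_starts():
        if model == "furth":
            return [("log", ["nu", "gamma"], [nu0, g]) for g in (gamma0, 5 * gamma0, gamma0 / 5)]
        if model == "furth_dt":
            return [
                ("log", ["nu", "gamma", "d_t"], [nu0, g, dt0])
                for g in (gamma0, 5 * gamma0, gamma0 / 5)
            ]
        if model == "furth_beta":
            return [
                ("log+beta", ["nu", "gamma", "d_t", "beta"], [nu0, g, dt0, b])
                for g in (gamma0, 5 * gamma0)
                for b in (0.8, 1.0, 1.3)
            ]
        # FKK family: seed gamma_alpha so the crossover matches gamma0
        starts = []
        for a0 in (0.8, 1.0, 1.2, 1.4):
            ga0 = gamma0 ** (-a0)
            if model == "fkk":
                starts.append(("log+alpha", ["nu", "gamma_alpha", "d_t", "alpha"], [nu0, ga0, dt0, a0]))
            else:
                eta0 = max(np.sqrt(m0) / 2.0, 1e-6)
                starts.append(("log+alpha", ["nu", "gamma_alpha", "eta", "alpha"], [nu0, ga0, eta0, a0]))
        return starts

    def unpack(kind, names, x):
        if kind == "log":
            vals = np.exp(x)
        else:
            vals = np.concatenate([np.exp(x[:-1]), [x[-1]]])
        return dict(zip(names, vals))

    best = FitResult(model=model, window=window, n_points=int(lag.size),
                     n_replicates=curve.n_replicates)
    for kind, names, vals in pack_starts():
        if kind == "log":
            x0 = np.log(vals)
            bounds = (-np.inf, np.inf)
        else:
            x0 = np.concatenate([np.log(vals[:-1]), [vals[-1]]])
            lb = np.full(x0.size, -np.inf)
            ub = np.full(x0.size, np.inf)
            lb[-1], ub[-1] = 0.05, 1.95
            bounds = (lb, ub)

        def resid(x):
            p = unpack(kind, names, x)
            with np.errstate(over="ignore", invalid="ignore"):
                m = _evaluate(model, lag, p)
            m = np.where(np.isfinite(m) & (m > 0), m, 1e-300)
            return np.log(m) - log_msd

        try:
            sol = least_squares(resid, x0, bounds=bounds, xtol=1e-10, ftol=1e-10,
                                gtol=1e-10, max_nfev=400)
        except Exception:
            continue
        res = float(np.sum(sol.fun**2))
        if res < best.residual:
            best.params = {k: float(v) for k, v in unpack(kind, names, sol.x).items()}
            best.residual = res
            best.converged = bool(sol.success)
        if best.residual < 1e-12 * lag.size:  # machine-perfect fit; stop early
            break
    return best
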