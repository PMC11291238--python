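"""Parametric survival fitting for right-censored pseudo-IPD.

Seven candidate families are fitted by maximizing the right-censored
log-likelihood  sum_events log f(t) + sum_censored log S(t)  and compared by
AIC (BIC as tiebreak).  Parameterizations follow the conventions used by
survival-extrapolation practice:

* exponential(rate):            S(t) = exp(-rate t)        [closed-form MLE]
* weibull(scale, shape):        S(t) = exp(-(t/scale)^shape)
* gamma(shape, scale):          standard gamma
* generalized_gamma(mu, sigma, Q): three-parameter log-time family containing
  weibull (Q=1), gamma and lognormal (Q=0) as special cases
* gompertz(eta, b):             S(t) = exp(-eta (e^{b t} - 1))
* loglogistic(scale, shape):    S(t) = 1 / (1 + (t/scale)^shape)  — the scale
  equals the median
* lognormal(mu, sigma):         log-time Gaussian

Optimization runs on transformed parameters (log for positive ones) from
several moment/quantile-based starts, so boundary failures for the Gompertz
and generalized-gamma families are avoided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .curves import SurvivalRecord

FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "generalized_gamma",
    "gompertz",
    "loglogistic",
    "lognormal",
)

_LOGLIK_TOL = 1e-8


@dataclass(frozen=True)
class ParametricFit:
    """A fitted (or externally supplied) parametric survival model.

    ``loglik``/``aic``/``bic``/``n`` are None when the parameters come from a
    published table rather than a fit.
    """

    family: str
    params: dict[str, float]
    loglik: float | None = None
    aic: float | None = None
    bic: float | None = None
    n: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        spec = _FAMILY_SPECS[self.family]
        if set(self.params) != set(spec.param_names):
            raise ValueError(
                f"{self.family} expects parameters {spec.param_names}, got {tuple(self.params)}"
            )
        for name, positive in zip(spec.param_names, spec.positive):
            if positive and not self.params[name] > 0:
                raise ValueError(f"{self.family} parameter {name} must be > 0, got {self.params[name]}")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.params)


@dataclass(frozen=True)
class _FamilySpec:
    param_names: tuple[str, ...]
    positive: tuple[bool, ...]
    logpdf: Callable
    logsf: Callable
    ppf: Callable
    inits: Callable  # records summary -> list of parameter dicts


def _expon_logpdf(t, p):
    return np.log(p["rate"]) - p["rate"] * t


def _expon_logsf(t, p):
    return -p["rate"] * t


def _expon_ppf(u, p):
    return -np.log1p(-u) / p["rate"]


def _weibull_logpdf(t, p):
    return stats.weibull_min.logpdf(t, c=p["shape"], scale=p["scale"])


def _weibull_logsf(t, p):
    return stats.weibull_min.logsf(t, c=p["shape"], scale=p["scale"])


def _weibull_ppf(u, p):
    return stats.weibull_min.ppf(u, c=p["shape"], scale=p["scale"])


def _gamma_logpdf(t, p):
    return stats.gamma.logpdf(t, a=p["shape"], scale=p["scale"])


def _gamma_logsf(t, p):
    return stats.gamma.logsf(t, a=p["shape"], scale=p["scale"])


def _gamma_ppf(u, p):
    return stats.gamma.ppf(u, a=p["shape"], scale=p["scale"])


def _gompertz_logpdf(t, p):
    # S(t) = exp(-eta (e^{b t} - 1)); h(t) = eta b e^{b t}
    return stats.gompertz.logpdf(t, c=p["eta"], scale=1.0 / p["b"])


def _gompertz_logsf(t, p):
    return stats.gompertz.logsf(t, c=p["eta"], scale=1.0 / p["b"])


def _gompertz_ppf(u, p):
    return stats.gompertz.ppf(u, c=p["eta"], scale=1.0 / p["b"])


def _llogis_logpdf(t, p):
    return stats.fisk.logpdf(t, c=p["shape"], scale=p["scale"])


def _llogis_logsf(t, p):
    # S(t) = 1/(1 + (t/scale)^shape); stable at both tails
    with np.errstate(divide="ignore"):
        z = p["shape"] * np.log(np.asarray(t, dtype=float) / p["scale"])
    return -np.logaddexp(0.0, z)


def _llogis_ppf(u, p):
    return stats.fisk.ppf(u, c=p["shape"], scale=p["scale"])


def _lnorm_logpdf(t, p):
    return stats.lognorm.logpdf(t, s=p["sigma"], scale=np.exp(p["mu"]))


def _lnorm_logsf(t, p):
    return stats.lognorm.logsf(t, s=p["sigma"], scale=np.exp(p["mu"]))


def _lnorm_ppf(u, p):
    return stats.lognorm.ppf(u, s=p["sigma"], scale=np.exp(p["mu"]))


_GG_Q_EPS = 1e-5  # below this |Q| the family is evaluated at its lognormal limit


def _gengamma_logpdf(t, p):
    mu, sigma, q = p["mu"], p["sigma"], p["Q"]
    t = np.asarray(t, dtype=float)
    if abs(q) < _GG_Q_EPS:
        return _lnorm_logpdf(t, {"mu": mu, "sigma": sigma})
    w = (np.log(t) - mu) / sigma
    q2 = q ** -2
    return (
        np.log(abs(q))
        - np.log(sigma * t)
        + q2 * np.log(q2)
        + q2 * (q * w - np.exp(q * w))
        - special.gammaln(q2)
    )


def _gengamma_logsf(t, p):
    mu, sigma, q = p["mu"], p["sigma"], p["Q"]
    t = np.asarray(t, dtype=float)
    if abs(q) < _GG_Q_EPS:
        return _lnorm_logsf(t, {"mu": mu, "sigma": sigma})
    w = (np.log(t) - mu) / sigma
    q2 = q ** -2
    u = q2 * np.exp(q * w)
    if q > 0:
        sf = special.gammaincc(q2, u)
    else:
        sf = special.gammainc(q2, u)
    with np.errstate(divide="ignore"):
        return np.log(np.clip(sf, 1e-300, 1.0))


def _gengamma_ppf(u, p):
    mu, sigma, q = p["mu"], p["sigma"], p["Q"]
    u = np.asarray(u, dtype=float)
    if abs(q) < _GG_Q_EPS:
        return _lnorm_ppf(u, {"mu": mu, "sigma": sigma})
    q2 = q ** -2
    # T = exp(mu + (sigma/Q) log(Q^2 G)), G ~ Gamma(Q^-2, 1); T increases with
    # G for Q > 0 and decreases for Q < 0
    g = special.gammaincinv(q2, u if q > 0 else 1.0 - u)
    return np.exp(mu + (sigma / q) * np.log(q ** 2 * g))


def _summaries(times: np.ndarray) -> dict[str, float]:
    logt = np.log(times)
    return {
        "mean": float(np.mean(times)),
        "var": float(np.var(times)) or 1e-6,
        "median": float(np.median(times)),
        "mlog": float(np.mean(logt)),
        "slog": float(np.std(logt)) or 0.1,
    }


def _inits_expon(s):
    return [{"rate": 1.0 / max(s["mean"], 1e-9)}]


def _inits_weibull(s):
    return [
        {"scale": s["mean"], "shape": 1.2},
        {"scale": s["median"] / math.log(2) ** (1 / 0.8), "shape": 0.8},
    ]


def _inits_gamma(s):
    shape0 = min(max(s["mean"] ** 2 / s["var"], 0.2), 50.0)
    return [
        {"shape": shape0, "scale": s["var"] / s["mean"]},
        {"shape": 1.0, "scale": s["mean"]},
    ]


def _inits_gompertz(s):
    return [
        {"eta": 0.5, "b": 1.0 / max(s["mean"], 1e-9)},
        {"eta": 1.5, "b": 0.5 / max(s["mean"], 1e-9)},
    ]


def _inits_llogis(s):
    return [
        {"scale": s["median"], "shape": 1.5},
        {"scale": s["median"], "shape": max(1.8 / s["slog"], 0.5) / 1.8},
    ]


def _inits_lnorm(s):
    return [{"mu": s["mlog"], "sigma": s["slog"]}]


def _inits_gengamma(s):
    return [
        {"mu": s["mlog"], "sigma": s["slog"], "Q": 0.5},
        {"mu": s["mlog"], "sigma": s["slog"], "Q": 1.0},
        {"mu": s["mlog"], "sigma": s["slog"], "Q": -0.5},
    ]


_FAMILY_SPECS: dict[str, _FamilySpec] = {
    "exponential": _FamilySpec(("rate",), (True,), _expon_logpdf, _expon_logsf, _expon_ppf, _inits_expon),
    "weibull": _FamilySpec(
        ("scale", "shape"), (True, True), _weibull_logpdf, _weibull_logsf, _weibull_ppf, _inits_weibull
    ),
    "gamma": _FamilySpec(
        ("shape", "scale"), (True, True), _gamma_logpdf, _gamma_logsf, _gamma_ppf, _inits_gamma
    ),
    "generalized_gamma": _FamilySpec(
        ("mu", "sigma", "Q"),
        (False, True, False),
        _gengamma_logpdf,
        _gengamma_logsf,
        _gengamma_ppf,
        _inits_gengamma,
    ),
    "gompertz": _FamilySpec(
        ("eta", "b"), (True, True), _gompertz_logpdf, _gompertz_logsf, _gompertz_ppf, _inits_gompertz
    ),
    "loglogistic": _FamilySpec(
        ("scale", "shape"), (True, True), _llogis_logpdf, _llogis_logsf, _llogis_ppf, _inits_llogis
    ),
    "lognormal": _FamilySpec(
        ("mu", "sigma"), (False, True), _lnorm_logpdf, _lnorm_logsf, _lnorm_ppf, _inits_lnorm
    ),
}


def censored_loglik(family: str, params: dict[str, float], times: np.ndarray, events: np.ndarray) -> float:
    """Right-censored log-likelihood of ``params`` for the given records."""
    spec = _FAMILY_SPECS[family]
    ll = 0.0
    ev = events.astype(bool)
    if ev.any():
        ll += float(np.sum(spec.logpdf(times[ev], params)))
    if (~ev).any():
        ll += float(np.sum(spec.logsf(times[~ev], params)))
    return ll


def _pack(params: dict[str, float], spec: _FamilySpec) -> np.ndarray:
    return np.array(
        [math.log(params[n]) if pos else params[n] for n, pos in zip(spec.param_names, spec.positive)]
    )


def _unpack(theta: np.ndarray, spec: _FamilySpec) -> dict[str, float]:
    return {
        n: (math.exp(v) if pos else float(v))
        for n, pos, v in zip(spec.param_names, spec.positive, theta)
    }


def fit_family(records: Sequence[SurvivalRecord], family: str) -> ParametricFit:
    """Maximum-likelihood fit of one family to right-censored records."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    n = len(times)
    if n < 10:
        raise ValueError(f"need at least 10 records to fit, got {n}")
    if events.sum() == 0:
        raise ValueError("all records are censored; the likelihood is unbounded")
    if np.any(times <= 0):
        raise ValueError("all survival times must be positive")
    spec = _FAMILY_SPECS[family]

    if family == "exponential":
        # closed form: rate = events / total follow-up time
        rate = float(events.sum() / times.sum())
        params = {"rate": rate}
        ll = censored_loglik(family, params, times, events)
        return _finalize(family, params, ll, n)

    def nll(theta: np.ndarray) -> float:
        p = _unpack(theta, spec)
        ll = censored_loglik(family, p, times, events)
        return -ll if math.isfinite(ll) else 1e12

    best_theta, best_val = None, np.inf
    messages = []
    for init in spec.inits(_summaries(times)):
        theta0 = _pack(init, spec)
        res = optimize.minimize(
            nll,
            theta0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": _LOGLIK_TOL, "xatol": 1e-8},
        )
        messages.append(res.message)
        if math.isfinite(res.fun) and res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None or best_val >= 1e12:
        raise RuntimeError(f"MLE failed to converge for {family}: {messages}")
    params = _unpack(best_theta, spec)
    return _finalize(family, params, -best_val, n)


def _finalize(family: str, params: dict[str, float], loglik: float, n: int) -> ParametricFit:
    k = len(params)
    return ParametricFit(
        family=family,
        params=params,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n=n,
    )


def fit_all(records: Sequence[SurvivalRecord], families: Sequence[str] = FAMILIES) -> list[ParametricFit]:
    """Fit every candidate family; families that fail to converge are skipped."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_family(records, fam))
        except RuntimeError:
            continue
    if not fits:
        raise RuntimeError("no family converged")
    return fits


def select_best(fits: Sequence[ParametricFit]) -> str:
    """Family with minimal AIC; ties broken by BIC, then family name."""
    if not fits:
        raise ValueError("select_best requires at least one fit")
    ranked = sorted(fits, key=lambda f: (f.aic, f.bic, f.family))
    return ranked[0].family


def survival_at(fit: ParametricFit, t: float | np.ndarray) -> float | np.ndarray:
    """S(t) under the fitted family's standard parameterization."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("survival_at requires t >= 0")
    spec = _FAMILY_SPECS[fit.family]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arr == 0.0, 1.0, np.exp(spec.logsf(np.maximum(arr, 1e-300), fit.params)))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def quantile(fit: ParametricFit, u: float | np.ndarray) -> float | np.ndarray:
    """Inverse CDF (event-time quantile) of the fitted family."""
    spec = _FAMILY_SPECS[fit.family]
    return spec.ppf(u, fit.params)


def fits_table(fits: Sequence[ParametricFit]) -> pd.DataFrame:
    """One row per family: parameters, log-likelihood, AIC, BIC."""
    rows = []
    for f in sorted(fits, key=lambda f: (f.aic, f.bic, f.family)):
        rows.append(
            {
                "family": f.family,
                "params": ";".join(f"{k}={v:.6g}" for k, v in f.params.items()),
                "loglik": f.loglik,
                "aic": f.aic,
                "bic": f.bic,
                "n": f.n,
            }
        )
    return pd.DataFrame(rows)


def loglogistic(scale: float, shape: float) -> ParametricFit:
    """Convenience constructor for an externally supplied log-logistic model."""
    return ParametricFit(family="loglogistic", params={"scale": scale, "shape": shape})
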