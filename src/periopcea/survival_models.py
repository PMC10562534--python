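"""Parametric survival families, censored MLE fitting, and AIC/BIC model selection.

Seven families are supported: exponential, Weibull, log-logistic, log-normal,
generalized gamma, gamma, and Gompertz.  Time is measured in months throughout.
The generalized gamma uses the Prentice (mu, sigma, Q) parameterization, in
which Q -> 0 recovers the log-normal and Q = 1 the Weibull; negative Q is
permitted.  The Gompertz shape may be negative, which yields a survival
plateau exp(rate / shape) at infinite time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SurvivalModelSpec",
    "IPDSample",
    "FitResult",
    "survival_at",
    "log_survival",
    "log_density",
    "hazard_at",
    "quantile",
    "fit_parametric",
    "fit_all_families",
    "select_best",
]

#: parameter names, in canonical order, for each family
FAMILIES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "gengamma": ("mu", "sigma", "Q"),
    "gamma": ("shape", "rate"),
    "gompertz": ("shape", "rate"),
}

# parameters that must be strictly positive (all others are unconstrained reals)
_POSITIVE = {"rate", "shape", "scale", "sdlog", "sigma"}
# ... except the Gompertz "shape", which is a real-valued log-hazard slope
_SIGNED_EXCEPTIONS = {("gompertz", "shape"), ("gengamma", "Q"), ("gengamma", "mu"), ("lognormal", "meanlog")}

_QZERO = 1e-7  # |Q| below this treated as the log-normal limit


@dataclass(frozen=True)
class SurvivalModelSpec:
    """A named parametric survival family with its parameter vector (time in months)."""

    family: str
    params: dict[str, float]
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        expected = FAMILIES[self.family]
        missing = [p for p in expected if p not in self.params]
        if missing:
            raise ValueError(f"{self.family}: missing parameter(s) {missing}")
        extra = [p for p in self.params if p not in expected]
        if extra:
            raise ValueError(f"{self.family}: unexpected parameter(s) {extra}")
        for name, value in self.params.items():
            if not math.isfinite(value):
                raise ValueError(f"{self.family}: parameter {name} is not finite")
            if name in _POSITIVE and (self.family, name) not in _SIGNED_EXCEPTIONS and value <= 0:
                raise ValueError(f"{self.family}: parameter {name} must be > 0, got {value}")

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "time_unit": self.time_unit}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalModelSpec":
        return cls(family=d["family"], params={k: float(v) for k, v in d["params"].items()},
                   time_unit=d.get("time_unit", "months"))


@dataclass(frozen=True)
class IPDSample:
    """Right-censored event times in months: ``event`` is 1 if observed, 0 if censored."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be one-dimensional and equal length")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("all times must be positive and finite")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (observed)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "event": self.events})

    @classmethod
    def from_csv(cls, path) -> "IPDSample":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family, with information criteria."""

    spec: SurvivalModelSpec
    loglik: float
    n: int
    converged: bool = True

    @property
    def k(self) -> int:
        return len(FAMILIES[self.spec.family])

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2.0 * self.loglik


# ---------------------------------------------------------------------------
# survival / density evaluation
# ---------------------------------------------------------------------------


def _as_time_array(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def log_survival(spec: SurvivalModelSpec, t) -> np.ndarray:
    """log S(t); vectorized over t (months)."""
    t = _as_time_array(t)
    p = spec.params
    f = spec.family
    with np.errstate(divide="ignore", invalid="ignore"):
        if f == "exponential":
            out = -p["rate"] * t
        elif f == "weibull":
            out = -np.power(t / p["scale"], p["shape"])
        elif f == "loglogistic":
            out = -np.log1p(np.power(t / p["scale"], p["shape"]))
        elif f == "lognormal":
            out = _lognormal_logsf(t, p["meanlog"], p["sdlog"])
        elif f == "gamma":
            out = np.log(special.gammaincc(p["shape"], p["rate"] * t))
        elif f == "gompertz":
            a, b = p["shape"], p["rate"]
            if abs(a) < 1e-12:
                out = -b * t
            else:
                out = -(b / a) * np.expm1(a * t)
        elif f == "gengamma":
            out = _gengamma_logsf(t, p["mu"], p["sigma"], p["Q"])
        else:  # pragma: no cover
            raise AssertionError(f)
    out = np.where(t == 0.0, 0.0, out)
    return out


def survival_at(spec: SurvivalModelSpec, t) -> np.ndarray:
    """S(t) in [0, 1]; S(0) = 1; nonincreasing in t."""
    return np.exp(log_survival(spec, t))


def _lognormal_logsf(t, meanlog, sdlog):
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, 0.0)
    pos = t > 0
    z = (np.log(t, where=pos, out=np.zeros_like(t)) - meanlog) / sdlog
    out = np.where(pos, stats.norm.logsf(z), 0.0)
    return out


def _gengamma_logsf(t, mu, sigma, Q):
    if abs(Q) < _QZERO:
        return _lognormal_logsf(t, mu, sigma)
    t = np.asarray(t, dtype=float)
    pos = t > 0
    w = (np.log(t, where=pos, out=np.zeros_like(t)) - mu) / sigma
    a = Q ** -2
    u = a * np.exp(Q * w)
    if Q > 0:
        s = special.gammaincc(a, u)
    else:
        s = special.gammainc(a, u)
    with np.errstate(divide="ignore"):
        out = np.where(pos, np.log(s), 0.0)
    return out


def log_density(spec: SurvivalModelSpec, t) -> np.ndarray:
    """log f(t) for t > 0; vectorized."""
    t = _as_time_array(t)
    p = spec.params
    f = spec.family
    if f == "exponential":
        return math.log(p["rate"]) - p["rate"] * t
    if f == "weibull":
        k, lam = p["shape"], p["scale"]
        return (math.log(k) - k * math.log(lam) + (k - 1.0) * np.log(t)
                - np.power(t / lam, k))
    if f == "loglogistic":
        k, lam = p["shape"], p["scale"]
        z = np.power(t / lam, k)
        return math.log(k) - math.log(lam) + (k - 1.0) * (np.log(t) - math.log(lam)) - 2.0 * np.log1p(z)
    if f == "lognormal":
        z = (np.log(t) - p["meanlog"]) / p["sdlog"]
        return stats.norm.logpdf(z) - np.log(t * p["sdlog"])
    if f == "gamma":
        a, r = p["shape"], p["rate"]
        return a * math.log(r) + (a - 1.0) * np.log(t) - r * t - special.gammaln(a)
    if f == "gompertz":
        a, b = p["shape"], p["rate"]
        if abs(a) < 1e-12:
            return math.log(b) - b * t
        return math.log(b) + a * t - (b / a) * np.expm1(a * t)
    if f == "gengamma":
        mu, sigma, Q = p["mu"], p["sigma"], p["Q"]
        if abs(Q) < _QZERO:
            z = (np.log(t) - mu) / sigma
            return stats.norm.logpdf(z) - np.log(t * sigma)
        w = (np.log(t) - mu) / sigma
        a = Q ** -2
        return (math.log(abs(Q)) + a * math.log(a) + a * (Q * w - np.exp(Q * w))
                - special.gammaln(a) - np.log(sigma * t))
    raise AssertionError(f)  # pragma: no cover


def hazard_at(spec: SurvivalModelSpec, t) -> np.ndarray:
    """Instantaneous hazard h(t) = f(t) / S(t)."""
    return np.exp(log_density(spec, t) - log_survival(spec, t))


def quantile(spec: SurvivalModelSpec, q) -> np.ndarray:
    """Inverse CDF: time t such that 1 - S(t) = q (months)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("quantile levels must lie in [0, 1)")
    p = spec.params
    f = spec.family
    if f == "exponential":
        return -np.log1p(-q) / p["rate"]
    if f == "weibull":
        return p["scale"] * np.power(-np.log1p(-q), 1.0 / p["shape"])
    if f == "loglogistic":
        return p["scale"] * np.power(q / (1.0 - q), 1.0 / p["shape"])
    if f == "lognormal":
        return np.exp(p["meanlog"] + p["sdlog"] * stats.norm.ppf(q))
    if f == "gamma":
        return stats.gamma.ppf(q, a=p["shape"], scale=1.0 / p["rate"])
    if f == "gompertz":
        a, b = p["shape"], p["rate"]
        H = -np.log1p(-q)  # cumulative hazard
        if abs(a) < 1e-12:
            return H / b
        arg = 1.0 + a * H / b
        if np.any(arg <= 0):
            # survival plateau: these quantiles are never reached
            raise ValueError("requested quantile beyond the Gompertz survival plateau")
        return np.log(arg) / a
    if f == "gengamma":
        mu, sigma, Q = p["mu"], p["sigma"], p["Q"]
        if abs(Q) < _QZERO:
            return np.exp(mu + sigma * stats.norm.ppf(q))
        a = Q ** -2
        g = stats.gamma.ppf(q if Q > 0 else 1.0 - q, a=a)
        return np.exp(mu + (sigma / Q) * np.log(g / a))
    raise AssertionError(f)  # pragma: no cover


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------


def censored_loglik(spec: SurvivalModelSpec, ipd: IPDSample) -> float:
    """Right-censored log-likelihood: sum of log f for events, log S for censored."""
    ll = np.where(ipd.events == 1,
                  log_density(spec, ipd.times),
                  log_survival(spec, ipd.times))
    return float(np.sum(ll))


def _pack(family: str, params: dict[str, float]) -> np.ndarray:
    """Map parameters to an unconstrained vector (log transform for positive ones)."""
    out = []
    for name in FAMILIES[family]:
        v = params[name]
        if name in _POSITIVE and (family, name) not in _SIGNED_EXCEPTIONS:
            out.append(math.log(v))
        else:
            out.append(v)
    return np.array(out)


def _unpack(family: str, x: np.ndarray) -> dict[str, float]:
    params = {}
    for name, v in zip(FAMILIES[family], x):
        if name in _POSITIVE and (family, name) not in _SIGNED_EXCEPTIONS:
            params[name] = math.exp(min(v, 50.0))
        else:
            params[name] = float(v)
    return params


def _initial_points(family: str, ipd: IPDSample) -> list[dict[str, float]]:
    """Five fixed heuristic starting points derived from sample moments."""
    t = ipd.times
    logs = np.log(t)
    m, s = float(np.mean(logs)), float(np.std(logs) + 1e-3)
    mean_t = float(np.mean(t))
    rate0 = max(ipd.n_events, 1) / float(np.sum(t))
    if family == "exponential":
        base = {"rate": rate0}
        variants = [0.5, 1.0, 2.0, 5.0, 0.2]
        return [{"rate": rate0 * v} for v in variants]
    if family == "weibull":
        return [{"shape": sh, "scale": sc} for sh, sc in
                [(1.0, mean_t), (1.0 / s, math.exp(m)), (0.7, mean_t), (1.5, mean_t), (1.0 / s, mean_t)]]
    if family == "loglogistic":
        return [{"shape": sh, "scale": sc} for sh, sc in
                [(1.0, math.exp(m)), (1.0 / s, math.exp(m)), (0.7, mean_t), (2.0, math.exp(m)), (1.2, mean_t)]]
    if family == "lognormal":
        return [{"meanlog": m + dm, "sdlog": s * ds} for dm, ds in
                [(0, 1), (0.5, 1), (-0.5, 1), (0, 2), (1.0, 1.5)]]
    if family == "gamma":
        return [{"shape": sh, "rate": sh / mean_t} for sh in (1.0, 0.5, 2.0, 4.0, 0.8)]
    if family == "gompertz":
        return [{"shape": a, "rate": rate0} for a in (0.01, -0.01, 0.05, -0.05, 0.0005)]
    if family == "gengamma":
        return [{"mu": m + dm, "sigma": s * ds, "Q": q} for dm, ds, q in
                [(0, 1, 0.01), (0, 1, 1.0), (0, 1, -1.0), (0.5, 1.5, 0.5), (0, 1.2, -0.5)]]
    raise AssertionError(family)  # pragma: no cover


def fit_parametric(ipd: IPDSample, family: str, *, tol: float = 1e-8) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    Uses a log transform of positive parameters and a fixed 5-point multi-start
    so the optimum is deterministic.  Raises on degenerate data (no events or
    fewer than 10 records); non-convergence of every start is flagged via
    ``converged=False`` on the best point found, never silently.
    """
    if len(ipd) < 10:
        raise ValueError(f"need at least 10 records to fit, got {len(ipd)}")
    if ipd.n_events == 0:
        raise ValueError("cannot fit a survival model to fully censored data")
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")

    def nll(x: np.ndarray) -> float:
        try:
            spec = SurvivalModelSpec(family, _unpack(family, x))
        except ValueError:
            return 1e12
        val = censored_loglik(spec, ipd)
        if not math.isfinite(val):
            return 1e12
        return -val

    best = None
    any_converged = False
    for start in _initial_points(family, ipd):
        x0 = _pack(family, start)
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": tol, "maxiter": 4000})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        any_converged = any_converged or bool(res.success)
    assert best is not None
    spec = SurvivalModelSpec(family, _unpack(family, best.x))
    return FitResult(spec=spec, loglik=-float(best.fun), n=len(ipd), converged=any_converged)


def fit_all_families(ipd: IPDSample, families: Iterable[str] = tuple(FAMILIES)) -> list[FitResult]:
    """Fit every requested family; non-converged fits are kept but flagged."""
    return [fit_parametric(ipd, fam) for fam in families]


def select_best(fits: Sequence[FitResult]) -> list[FitResult]:
    """Rank fits by AIC ascending; ties broken by BIC, then by fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: (f.aic, f.bic, f.k))
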