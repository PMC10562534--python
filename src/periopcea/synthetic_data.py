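"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates what the real analysis starts from: right-censored event-time
samples drawn from a chosen parametric family (standing in for trial patient
data), their Kaplan-Meier step functions sampled at a digitization grid with
optional jitter emulating digitizer error, and numbers-at-risk at calendar
intervals.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from periopcea.km_reconstruction import DigitizedCurve, km_at, km_estimator
from periopcea.parameters import ParameterTable, packaged_survival_specs, packaged_table
from periopcea.survival_models import IPDSample, SurvivalModelSpec, quantile

__all__ = ["Censoring", "generate_ipd", "digitize", "table1_fixture",
           "survival_spec_fixture", "digitized_curve_fixture"]


@dataclass(frozen=True)
class Censoring:
    """Right-censoring scheme: administrative cutoff and/or random exponential rate."""

    admin_time: float | None = None  # months; None = no administrative cutoff
    random_rate: float = 0.0  # exponential censoring hazard per month

    def __post_init__(self) -> None:
        if self.admin_time is not None and self.admin_time <= 0:
            raise ValueError("administrative censoring time must be positive "
                             "(a cutoff at 0 censors every record at time 0)")
        if self.random_rate < 0:
            raise ValueError("random censoring rate must be >= 0")


def generate_ipd(spec: SurvivalModelSpec, n: int, censoring: Censoring | None = None,
                 seed: int | None = None) -> IPDSample:
    """Draw ``n`` right-censored survival records from a parametric family.

    Event times come from the inverse CDF; the observed time is the minimum of
    the event time and the censoring time(s).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    censoring = censoring or Censoring()
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    try:
        event_t = np.asarray(quantile(spec, u), dtype=float)
    except ValueError:
        # survival plateau (e.g. negative-shape Gompertz): cap at a far horizon
        cap = 1e6
        event_t = np.empty(n)
        for i, ui in enumerate(u):
            try:
                event_t[i] = quantile(spec, ui)
            except ValueError:
                event_t[i] = cap
    censor_t = np.full(n, np.inf)
    if censoring.random_rate > 0:
        censor_t = rng.exponential(1.0 / censoring.random_rate, size=n)
    if censoring.admin_time is not None:
        censor_t = np.minimum(censor_t, censoring.admin_time)
    times = np.minimum(event_t, censor_t)
    events = (event_t <= censor_t).astype(int)
    times = np.maximum(times, 1e-9)  # IPD times must be strictly positive
    return IPDSample(times, events)


def digitize(ipd: IPDSample, n_points: int = 40, risk_interval: float = 6.0,
             jitter_sd: float = 0.0, seed: int | None = None) -> DigitizedCurve:
    """Sample the KM curve of a cohort the way a human digitizer would.

    Points are quantile-spaced (denser where the curve drops): the grid is
    built from evenly spaced survival levels between 1 and the final KM value,
    mapped back to the first times at which the curve reaches them.  Optional
    Gaussian jitter on the survival reads is clipped to preserve monotonicity.
    The risk table counts subjects still under observation at fixed calendar
    intervals.
    """
    if n_points < 5:
        raise ValueError("need at least 5 digitization points")
    if risk_interval <= 0:
        raise ValueError("risk_interval must be positive")
    rng = np.random.default_rng(seed)
    ev_t, ev_s = km_estimator(ipd)
    if ev_t.size == 0:
        raise ValueError("cannot digitize a curve with no events")
    s_final = float(ev_s[-1])
    levels = np.linspace(1.0, s_final, n_points + 1)[1:]  # skip the (0, 1) anchor
    # first time the KM curve is at or below each level
    grid = np.array([ev_t[np.argmax(ev_s <= lv)] for lv in levels])
    grid = np.unique(grid)
    surv = km_at(ipd, grid)
    if jitter_sd > 0:
        surv = surv + rng.normal(0.0, jitter_sd, size=surv.size)
        surv = np.clip(surv, 0.0, 1.0)
        surv = np.minimum.accumulate(surv)

    t_max = float(np.max(ipd.times))
    risk_times = np.arange(0.0, t_max + risk_interval, risk_interval)
    n_risk = np.array([int(np.sum(ipd.times >= rt)) for rt in risk_times])
    keep = n_risk > 0
    risk_times, n_risk = risk_times[keep], n_risk[keep]
    if risk_times.size < 2:
        risk_times = np.array([0.0, t_max])
        n_risk = np.array([len(ipd), max(int(np.sum(ipd.times >= t_max)), 1)])

    return DigitizedCurve(times=np.concatenate([[0.0], grid]),
                          survival=np.concatenate([[1.0], surv]),
                          risk_times=risk_times, n_risk=n_risk,
                          total_events=int(ipd.n_events))


def table1_fixture() -> ParameterTable:
    """The packaged base-case parameter table (all printed values)."""
    return packaged_table()


def survival_spec_fixture() -> dict:
    """The four packaged base-case survival specifications (per arm, OS/EFS)."""
    return packaged_survival_specs()


def digitized_curve_fixture() -> DigitizedCurve:
    """Packaged synthetic digitized-curve set (curve + risk table).

    Synthetic data: a 400-subject cohort drawn from the packaged intervention
    overall-survival model (administrative censoring at 48 months), digitized
    at 40 quantile-spaced points with a 6-month risk table, seed 42.
    """
    from importlib import resources

    data = resources.files("periopcea").joinpath("data")
    with resources.as_file(data.joinpath("synthetic_km_curve.csv")) as curve_path, \
            resources.as_file(data.joinpath("synthetic_km_risk.csv")) as risk_path:
        return DigitizedCurve.from_csv(curve_path, risk_path)
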