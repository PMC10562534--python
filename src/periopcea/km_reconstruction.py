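"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures only show the KM step function and a
numbers-at-risk table.  The reconstruction here inverts them: within each
interval between consecutive risk-table times it allocates integer event and
censoring counts such that the KM estimator of the output matches the
digitized coordinates and the implied numbers at risk match the risk table
(the Guyot algorithm).  Censoring is assumed uniform within intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from periopcea.survival_models import IPDSample

__all__ = ["DigitizedCurve", "reconstruct_ipd", "km_estimator"]


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized (time, survival) coordinates plus the numbers-at-risk table.

    Times are months; a (0, 1) anchor is prepended when absent.  Survival must
    be nonincreasing and the numbers at risk nonincreasing positive integers.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("need matching 1-d time/survival arrays with >= 2 points")
        if t[0] > 0.0:
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(np.diff(s) > 1e-9) or np.any((s < 0) | (s > 1)):
            raise ValueError("survival coordinates must be nonincreasing and in [0, 1]")
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        rt = np.asarray(self.risk_times, dtype=float)
        nr = np.asarray(self.n_risk)
        if rt.shape != nr.shape or rt.ndim != 1 or rt.size < 2:
            raise ValueError("need >= 2 risk-table entries")
        if np.any(np.diff(rt) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(nr <= 0) or np.any(nr != np.round(nr)) or np.any(np.diff(nr) > 0):
            raise ValueError("numbers at risk must be nonincreasing positive integers")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        object.__setattr__(self, "risk_times", rt)
        object.__setattr__(self, "n_risk", nr.astype(int))

    @classmethod
    def from_csv(cls, curve_path, risk_path, total_events: int | None = None) -> "DigitizedCurve":
        import pandas as pd

        curve = pd.read_csv(curve_path)
        risk = pd.read_csv(risk_path)
        return cls(curve["time"].to_numpy(), curve["survival"].to_numpy(),
                   risk["time"].to_numpy(), risk["n_risk"].to_numpy(),
                   total_events=total_events)


def km_estimator(ipd: IPDSample) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate: returns (event times, survival after each event).

    S(0) = 1 and the function steps only at observed event times.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_["KM_estimate"]
    event_times = np.unique(ipd.times[ipd.events == 1])
    return event_times, sf.asof(event_times).to_numpy()


def km_at(ipd: IPDSample, times) -> np.ndarray:
    """KM estimate evaluated at arbitrary times (right-continuous step)."""
    et, s = km_estimator(ipd)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.ones_like(times)
    for i, t in enumerate(times):
        k = np.searchsorted(et, t, side="right")
        out[i] = 1.0 if k == 0 else s[k - 1]
    return out


def _process_interval(t, S, lo, hi, n_enter, ncen, t_start, t_end, km_prev):
    """Allocate events at digitized points lo..hi and ``ncen`` uniform censorings.

    Returns (event counts per point, censor times actually consumed, n at risk
    after the interval, updated KM level).  A censoring is consumed only while
    subjects remain at risk, so records are conserved.
    """
    proposed = (t_start + (np.arange(1, ncen + 1) / (ncen + 1)) * (t_end - t_start)
                if ncen > 0 else np.empty(0))
    d = np.zeros(hi - lo + 1, dtype=int)
    consumed: list[float] = []
    n = n_enter
    km = km_prev
    for j, k in enumerate(range(lo, hi + 1)):
        if n > 0 and km > 0:
            dk = int(round(n * (1.0 - S[k] / km)))
            dk = min(max(dk, 0), n)
        else:
            dk = 0
        if dk > 0:
            km *= 1.0 - dk / n
        d[j] = dk
        n -= dk
        # censorings falling in (t_k, t_{k+1}]
        upper_t = t[k + 1] if k + 1 < len(t) else np.inf
        here = proposed[(proposed > t[k]) & (proposed <= upper_t)]
        take = min(len(here), n)
        consumed.extend(here[:take].tolist())
        n -= take
    return d, np.asarray(consumed), n, km


def _initial_censoring_guess(t, S, lo, hi, lo_next, n, km, target):
    """First guess: at-risk decline not explained by the expected event count."""
    s_end = S[lo_next] if lo_next < len(S) else S[hi]
    expected_events = round(n * (1.0 - s_end / km)) if km > 0 else 0
    return max(n - expected_events - target, 0)


def reconstruct_ipd(curve: DigitizedCurve) -> IPDSample:
    """Invert a digitized KM curve and risk table into pseudo patient records.

    Raises :class:`ValueError` naming the offending interval when no
    nonnegative integer allocation can reproduce the risk table.
    """
    t, S = curve.times, curve.survival
    rt, nr = curve.risk_times, curve.n_risk
    K = len(t)
    I = len(rt)

    # digitized indices belonging to each risk interval [rt_i, rt_{i+1})
    lowers, uppers = [], []
    for i in range(I):
        lo = int(np.searchsorted(t, rt[i], side="left"))
        hi_t = rt[i + 1] if i + 1 < I else np.inf
        hi = int(np.searchsorted(t, hi_t, side="left")) - 1
        lowers.append(lo)
        uppers.append(hi)

    event_times: list[float] = []
    censor_times: list[float] = []
    n = int(nr[0])
    km = 1.0
    tol = max(5, round(0.05 * int(nr[0])))  # rounding drift vs true inconsistency
    for i in range(I):
        lo, hi = lowers[i], uppers[i]
        if hi < lo:  # no digitized points in this interval
            if i + 1 < I:
                extra = n - int(nr[i + 1])
                if extra < -tol:
                    raise ValueError(f"risk table inconsistent in interval {i} "
                                     f"({rt[i]:g}-{rt[i + 1]:g} months)")
                extra = max(extra, 0)
                t_end = rt[i + 1]
                censor_times.extend(rt[i] + (np.arange(1, extra + 1) / (extra + 1)) * (t_end - rt[i]))
                n -= extra
            continue
        t_end = rt[i + 1] if i + 1 < I else t[hi]
        if i + 1 < I:
            target = int(nr[i + 1])
            ncen = _initial_censoring_guess(t, S, lo, hi, lowers[i + 1], n, km, target)
            best = None
            for _ in range(60):
                d, cen, n_after, km_after = _process_interval(t, S, lo, hi, n, ncen, rt[i], t_end, km)
                diff = n_after - target
                if best is None or abs(diff) < abs(best[0]):
                    best = (diff, d, cen, n_after, km_after, ncen)
                if diff == 0:
                    break
                ncen += diff
                if ncen < 0:
                    ncen = 0
                    d, cen, n_after, km_after = _process_interval(t, S, lo, hi, n, ncen, rt[i], t_end, km)
                    if abs(n_after - target) < abs(best[0]):
                        best = (n_after - target, d, cen, n_after, km_after, ncen)
                    break
            diff, d, cen, n_after, km_after, ncen = best
            # integer rounding of event counts makes small residual mismatches
            # unavoidable on noisy coordinates; only a gross shortfall means the
            # table cannot be satisfied by any nonnegative allocation
            if abs(diff) > tol:
                raise ValueError(f"risk table inconsistent in interval {i} "
                                 f"({rt[i]:g}-{rt[i + 1]:g} months): "
                                 f"reached {n_after} at risk, table says {target}")
        else:
            d, cen, n_after, km_after = _process_interval(t, S, lo, hi, n, 0, rt[i], t_end, km)
        for j, k in enumerate(range(lo, hi + 1)):
            event_times.extend([t[k]] * int(d[j]))
        censor_times.extend(cen.tolist())
        n, km = n_after, km_after

    # survivors are administratively censored at the end of observation (the
    # later of the last digitized time and the last risk-table time)
    if n > 0:
        censor_times.extend([float(max(t[-1], rt[-1]))] * n)

    if curve.total_events is not None:
        event_times = _reconcile_total_events(event_times, censor_times, curve.total_events)

    times = np.array(event_times + censor_times)
    events = np.array([1] * len(event_times) + [0] * len(censor_times))
    if times.size == 0:
        raise ValueError("reconstruction produced no records")
    keep = times > 0
    return IPDSample(times[keep], events[keep])


def _reconcile_total_events(event_times: list, censor_times: list, total: int) -> list:
    """Proportional adjustment so the overall event count matches a known total.

    Only trims surplus events (converting the latest ones to censorings is not
    attempted; they are dropped proportionally across event times).  A deficit
    cannot be manufactured and is left as-is.
    """
    surplus = len(event_times) - total
    if surplus <= 0:
        return event_times
    rng = np.linspace(0, len(event_times) - 1, surplus).round().astype(int)
    keep = np.ones(len(event_times), dtype=bool)
    keep[rng] = False
    trimmed = [et for et, k in zip(sorted(event_times), keep) if k]
    censor_times.extend(et for et, k in zip(sorted(event_times), keep) if not k)
    return trimmed
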