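"""Deterministic (tornado) and probabilistic sensitivity analysis, and the CEAC.

The one-way analysis re-runs the full model at each parameter's lower and
upper limit holding everything else at base; parameters are ranked by the
absolute ICER spread.  The PSA draws every non-fixed parameter independently
from a moment-matched distribution (gamma for costs, beta for proportions and
utilities, normal for anthropometrics, uniform for the discount rate; mean =
base value, sd = 10% of base unless the class dictates otherwise) and re-runs
the model per draw.  Survival-curve parameters are not varied here; they move
only in scenario analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from periopcea.parameters import ParameterTable, fractional_ranges
from periopcea.pipeline import ModelSettings, run_base_case

__all__ = ["TornadoEntry", "one_way", "assign_psa_distribution", "run_psa", "ceac"]


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    name: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    nmb_at_low: float
    nmb_at_high: float
    error: str | None = None  # set when a bound failed to run (entry kept, flagged)

    @property
    def spread(self) -> float:
        if self.error is not None:
            return 0.0
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(table: ParameterTable, settings: ModelSettings | None = None,
            runner=None, bounds: str = "method") -> list[TornadoEntry]:
    """Tornado analysis over every non-fixed parameter, sorted by ICER spread.

    ``bounds="method"`` recomputes exact fractional limits (+/-25% or +/-10%)
    from the base values; ``bounds="table"`` uses the ranges as loaded.
    """
    if bounds not in ("method", "table"):
        raise ValueError("bounds must be 'method' or 'table'")
    settings = settings or ModelSettings()
    if runner is None:
        runner = lambda tbl: run_base_case(tbl, settings)
    src = fractional_ranges(table) if bounds == "method" else table
    entries = []
    for name, p in src.parameters.items():
        if p.psa_class == "fixed" or not p.has_range:
            continue
        res = {}
        err = None
        for side, value in (("low", p.low), ("high", p.high)):
            try:
                res[side] = runner(table.with_value(name, value))
            except Exception as exc:  # noqa: BLE001 -- flagged, not dropped
                err = f"{side}: {exc}"
        if err is not None:
            entries.append(TornadoEntry(name, p.low, p.high,
                                        math.nan, math.nan, math.nan, math.nan, error=err))
            continue
        entries.append(TornadoEntry(
            name, p.low, p.high,
            icer_at_low=res["low"].icer, icer_at_high=res["high"].icer,
            nmb_at_low=res["low"].nmb, nmb_at_high=res["high"].nmb))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.name, "low": e.low, "high": e.high,
        "icer_low": e.icer_at_low, "icer_high": e.icer_at_high,
        "spread": e.spread, "error": e.error} for e in entries])


def assign_psa_distribution(p):
    """Moment-matched frozen distribution for one parameter; None for fixed.

    gamma: mean = base, sd = 0.1 base  =>  shape 100, scale base/100
    beta:  mean m, sd 0.1 m            =>  alpha = m nu, beta = (1-m) nu,
                                           nu = m(1-m)/sd^2 - 1
    normal(base, 0.1 base); uniform on [low, high] (discount rate).
    """
    base = p.base_value
    if p.psa_class == "fixed":
        return None
    if p.psa_class == "gamma":
        if base <= 0:
            raise ValueError(f"{p.name}: gamma PSA class needs a positive base value")
        return stats.gamma(a=100.0, scale=base / 100.0)
    if p.psa_class == "beta":
        m, sd = base, 0.1 * base
        if sd * sd >= m * (1.0 - m):
            raise ValueError(f"{p.name}: beta moments infeasible (sd^2 >= m(1-m))")
        nu = m * (1.0 - m) / (sd * sd) - 1.0
        return stats.beta(a=m * nu, b=(1.0 - m) * nu)
    if p.psa_class == "normal":
        return stats.norm(loc=base, scale=0.1 * base)
    if p.psa_class == "uniform":
        if not p.has_range:
            raise ValueError(f"{p.name}: uniform PSA class needs explicit bounds")
        return stats.uniform(loc=p.low, scale=p.high - p.low)
    raise ValueError(f"{p.name}: unknown psa_class {p.psa_class!r}")  # pragma: no cover


def run_psa(table: ParameterTable, n: int = 1000, seed: int = 0,
            settings: ModelSettings | None = None, runner=None):
    """Probabilistic sensitivity analysis: ``n`` independent joint draws.

    Returns ``(samples, summary)``: a DataFrame with one row per repetition
    (drawn parameter vector plus delta cost/QALY, ICER, NMB and per-arm
    totals) and a summary dict with ranges and the probability of
    cost-effectiveness at the willingness-to-pay threshold.
    """
    settings = settings or ModelSettings()
    if runner is None:
        runner = lambda tbl: run_base_case(tbl, settings)
    rng = np.random.default_rng(seed)
    dists = {name: assign_psa_distribution(p) for name, p in table.parameters.items()}
    varied = [name for name, d in dists.items() if d is not None]

    rows = []
    for _ in range(n):
        tbl = table
        draw = {}
        for name in varied:
            v = float(dists[name].rvs(random_state=rng))
            if table[name].units in ("probability", "utility", "disutility"):
                v = min(max(v, 0.0), 1.0)
            draw[name] = v
            tbl = tbl.with_value(name, v)
        res = runner(tbl)
        rows.append({**draw,
                     "cost_intervention": res.intervention.total_cost,
                     "qaly_intervention": res.intervention.total_qaly,
                     "cost_comparator": res.comparator.total_cost,
                     "qaly_comparator": res.comparator.total_qaly,
                     "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
                     "icer": res.icer, "nmb": res.nmb})
    samples = pd.DataFrame(rows)
    summary = {
        "n": n,
        "seed": seed,
        "wtp": settings.wtp,
        "prob_cost_effective": float((samples["nmb"] > 0).mean()),
        "icer_range": [float(samples["icer"].min()), float(samples["icer"].max())],
        "cost_intervention_range": [float(samples["cost_intervention"].min()),
                                    float(samples["cost_intervention"].max())],
        "cost_comparator_range": [float(samples["cost_comparator"].min()),
                                  float(samples["cost_comparator"].max())],
        "qaly_intervention_range": [float(samples["qaly_intervention"].min()),
                                    float(samples["qaly_intervention"].max())],
        "qaly_comparator_range": [float(samples["qaly_comparator"].min()),
                                  float(samples["qaly_comparator"].max())],
        "all_icers_positive": bool((samples["icer"] > 0).all()),
    }
    return samples, summary


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(NMB > 0) at each threshold."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dc = samples["delta_cost"].to_numpy()
    de = samples["delta_qaly"].to_numpy()
    prob = [(lam * de - dc > 0).mean() for lam in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})
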