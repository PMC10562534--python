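"""Five-state Markov cohort engine with 21-day cycles and survival-derived transitions.

Public states are NEOADJ (neoadjuvant treatment), POST_SURG_RT (post
surgery/radiotherapy residency, also used for post-treatment follow-up),
ADJUVANT, PD (progressive disease) and DEATH (absorbing).  Internally the
ADJUVANT and PD states are expanded into tunnel sub-states so that the number
of adjuvant cycles received (max 13) and the time since progression (chemo in
the first 6 PD cycles) can be tracked without leaving the Markov framework;
the public trace collapses them back to five columns.

Transition probabilities are time-varying: per-cycle death probability is
derived from the arm's overall-survival curve (optionally floored by
age-indexed background mortality), and progression from the event-free
survival curve.  The death hazard is applied uniformly to every alive state,
which makes cohort-level survival reproduce the fitted OS curve exactly when
the background floor and the surgical 30-day mortality are switched off.

Cycle indexing is 1-based: the matrix for cycle c moves the cohort from the
state occupied at the start of cycle c to the state at its end, so the
surgery window "cycles 5-6" means the move can happen at the end of cycle 5
or 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from periopcea.survival_models import SurvivalModelSpec, survival_at

__all__ = [
    "STATES",
    "DAYS_PER_MONTH",
    "EngineConfig",
    "CohortTrace",
    "conditional_transition_prob",
    "background_mortality_annual",
    "build_transition_matrix",
    "run_cohort",
]

#: the five public states, in fixed matrix order
STATES = ("NEOADJ", "POST_SURG_RT", "ADJUVANT", "PD", "DEATH")

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


def background_mortality_annual(age: float) -> float:
    """Annual all-cause death probability at a given age.

    Gompertz approximation to the US period life table (anchored at ~1.3% per
    year at age 65, doubling roughly every 7.5 years), capped below 1.
    """
    return min(0.0131 * math.exp(0.093 * (age - 65.0)), 0.999)


@dataclass(frozen=True)
class EngineConfig:
    """Structural configuration of the cohort model (both arms)."""

    os_specs: dict  # arm -> SurvivalModelSpec
    efs_specs: dict  # arm -> SurvivalModelSpec
    horizon_cycles: int = 174  # 10 years of 21-day cycles
    cycle_days: float = 21.0
    window_neo_to_surg: tuple[int, int] = (5, 6)
    window_surg_to_adj: tuple[int, int] = (6, 10)
    proportion_surgery_or_rt: dict = field(
        default_factory=lambda: {"pembrolizumab": 0.821, "placebo": 0.794}
    )
    proportion_adjuvant_uptake: float = 0.892
    fraction_radiotherapy: float = 0.1  # of those undergoing local therapy
    p_surgery_mortality_30d: float = 0.023
    adjuvant_max_cycles: int = 13
    pd_chemo_cycles: int = 6
    start_age: float = 65.0
    use_background_mortality: bool = True
    background_mortality: Callable[[float], float] = background_mortality_annual

    def __post_init__(self) -> None:
        if self.horizon_cycles < 10:
            raise ValueError("horizon must be at least 10 cycles")
        for w in (self.window_neo_to_surg, self.window_surg_to_adj):
            if not (1 <= w[0] <= w[1] <= self.horizon_cycles):
                raise ValueError(f"window {w} outside horizon")
        for p in (*self.proportion_surgery_or_rt.values(),
                  self.proportion_adjuvant_uptake, self.fraction_radiotherapy,
                  self.p_surgery_mortality_30d):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    # ---- expanded state indexing -------------------------------------
    @property
    def n_expanded(self) -> int:
        return 2 + self.adjuvant_max_cycles + self.pd_chemo_cycles + 2

    @property
    def idx(self) -> dict:
        """Indices of the expanded state space."""
        n_adj, n_pd = self.adjuvant_max_cycles, self.pd_chemo_cycles
        return {
            "NEOADJ": 0,
            "POST": 1,
            "ADJ": list(range(2, 2 + n_adj)),
            "PD": list(range(2 + n_adj, 2 + n_adj + n_pd)),
            "PD_LATE": 2 + n_adj + n_pd,
            "DEATH": 2 + n_adj + n_pd + 1,
        }


def conditional_transition_prob(spec: SurvivalModelSpec, t: float, dt: float) -> float:
    """Per-cycle transition probability 1 - S(t + dt)/S(t); returns 1 when S(t) = 0."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return 0.0
    s0 = float(survival_at(spec, t))
    if s0 <= 0.0:
        return 1.0
    s1 = float(survival_at(spec, t + dt))
    return min(max(1.0 - s1 / s0, 0.0), 1.0)


def _window_move_prob(cycle: int, window: tuple[int, int], total: float) -> float:
    """Conditional per-cycle move probability spreading ``total`` evenly over the window.

    With k window cycles, the unconditional share moved each window cycle is
    total/k for a cohort present from the window start (ignoring competing
    death/progression, which remove mass symmetrically).
    """
    w1, w2 = window
    if not (w1 <= cycle <= w2) or total <= 0.0:
        return 0.0
    k = w2 - w1 + 1
    j = cycle - w1  # window cycles already passed
    remaining = 1.0 - total * j / k
    if remaining <= 0.0:
        return 1.0
    return min((total / k) / remaining, 1.0)


def _cycle_probs(cfg: EngineConfig, arm: str, cycle: int) -> tuple[float, float]:
    """(death, progression) probabilities for cycle ``cycle`` (1-based)."""
    dt = cfg.cycle_months
    t0 = (cycle - 1) * dt
    p_os = conditional_transition_prob(cfg.os_specs[arm], t0, dt)
    if cfg.use_background_mortality:
        age = cfg.start_age + (cycle - 1) * cfg.cycle_years
        q_annual = cfg.background_mortality(age)
        p_bg = 1.0 - (1.0 - q_annual) ** cfg.cycle_years
        p_death = max(p_os, p_bg)
    else:
        p_death = p_os
    p_efs = conditional_transition_prob(cfg.efs_specs[arm], t0, dt)
    p_prog = max(0.0, p_efs - p_death)
    if p_death + p_prog > 1.0:
        p_prog = 1.0 - p_death
    return p_death, p_prog


def build_transition_matrix(cycle: int, cfg: EngineConfig, arm: str) -> np.ndarray:
    """Transition matrix over the expanded state space for one cycle (rows sum to 1)."""
    if not 1 <= cycle <= cfg.horizon_cycles:
        raise ValueError(f"cycle {cycle} outside horizon")
    if arm not in cfg.os_specs:
        raise ValueError(f"unknown arm {arm!r}")
    idx = cfg.idx
    n = cfg.n_expanded
    M = np.zeros((n, n))
    p_death, p_prog = _cycle_probs(cfg, arm, cycle)
    alive = 1.0 - p_death - p_prog
    i_neo, i_post = idx["NEOADJ"], idx["POST"]
    i_adj, i_pd = idx["ADJ"], idx["PD"]
    i_pdl, i_dead = idx["PD_LATE"], idx["DEATH"]
    pd_first = i_pd[0]

    # NEOADJ: death, progression, surgery/RT window, or stay
    q_surg = _window_move_prob(cycle, cfg.window_neo_to_surg, cfg.proportion_surgery_or_rt[arm])
    f_surg = 1.0 - cfg.fraction_radiotherapy
    gamma = cfg.p_surgery_mortality_30d
    M[i_neo, i_dead] = p_death + alive * q_surg * f_surg * gamma
    M[i_neo, pd_first] = p_prog
    M[i_neo, i_post] = alive * q_surg * (1.0 - f_surg * gamma)
    M[i_neo, i_neo] = alive * (1.0 - q_surg)

    # POST: death, progression, adjuvant window (pembrolizumab arm only), or stay
    q_adj = 0.0
    if arm == "pembrolizumab":
        q_adj = _window_move_prob(cycle, cfg.window_surg_to_adj, cfg.proportion_adjuvant_uptake)
    M[i_post, i_dead] = p_death
    M[i_post, pd_first] = p_prog
    M[i_post, i_adj[0]] = alive * q_adj
    M[i_post, i_post] = alive * (1.0 - q_adj)

    # ADJ_j: progress through the adjuvant tunnel, back to POST after the last cycle
    for j, i in enumerate(i_adj):
        nxt = i_adj[j + 1] if j + 1 < len(i_adj) else i_post
        M[i, i_dead] = p_death
        M[i, pd_first] = p_prog
        M[i, nxt] = alive

    # PD tunnel: chemo cycles then late PD; death only (no further progression)
    alive_pd = 1.0 - p_death
    for j, i in enumerate(i_pd):
        nxt = i_pd[j + 1] if j + 1 < len(i_pd) else i_pdl
        M[i, i_dead] = p_death
        M[i, nxt] = alive_pd
    M[i_pdl, i_dead] = p_death
    M[i_pdl, i_pdl] = alive_pd

    M[i_dead, i_dead] = 1.0

    rowsums = M.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-12):
        raise RuntimeError(f"transition matrix rows do not sum to 1 at cycle {cycle}")
    return M


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy trace for one arm plus per-cycle transition-event counts.

    ``occupancy[c]`` is the distribution over the five public states at the
    start of cycle c+1 (row 0 is the initial state); ``expanded`` keeps the
    tunnel sub-states.  Entrant arrays are indexed by the cycle in which the
    flow happened (index 0 unused).
    """

    cfg: EngineConfig
    arm: str
    occupancy: np.ndarray        # (horizon+1, 5)
    expanded: np.ndarray         # (horizon+1, n_expanded)
    surgery_rt_entrants: np.ndarray  # entered POST from NEOADJ during cycle c
    pd_entrants: np.ndarray          # entered PD during cycle c
    death_entrants: np.ndarray       # died during cycle c

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, STATES.index("DEATH")]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["entrants_surgery_rt"] = np.append(self.surgery_rt_entrants, np.nan)[: len(df)]
        df["entrants_pd"] = self.pd_entrants[: len(df)]
        df["entrants_death"] = self.death_entrants[: len(df)]
        return df


def _collapse(cfg: EngineConfig, x: np.ndarray) -> np.ndarray:
    idx = cfg.idx
    return np.array([
        x[idx["NEOADJ"]],
        x[idx["POST"]],
        x[idx["ADJ"]].sum(),
        x[idx["PD"]].sum() + x[idx["PD_LATE"]],
        x[idx["DEATH"]],
    ])


def run_cohort(cfg: EngineConfig, arm: str) -> CohortTrace:
    """Propagate a unit cohort starting in NEOADJ through the full horizon."""
    if arm not in cfg.os_specs or arm not in cfg.efs_specs:
        raise ValueError(f"no survival specs for arm {arm!r}")
    idx = cfg.idx
    n, H = cfg.n_expanded, cfg.horizon_cycles
    expanded = np.zeros((H + 1, n))
    expanded[0, idx["NEOADJ"]] = 1.0
    surgery_rt = np.zeros(H + 1)
    pd_in = np.zeros(H + 1)
    deaths = np.zeros(H + 1)
    i_neo, i_dead = idx["NEOADJ"], idx["DEATH"]
    pd_first = idx["PD"][0]

    for c in range(1, H + 1):
        M = build_transition_matrix(c, cfg, arm)
        x = expanded[c - 1]
        y = x @ M
        expanded[c] = y
        surgery_rt[c] = x[i_neo] * M[i_neo, idx["POST"]]
        pd_in[c] = float(x @ M[:, pd_first]) - x[pd_first] * M[pd_first, pd_first]
        deaths[c] = y[i_dead] - x[i_dead]

    occupancy = np.stack([_collapse(cfg, expanded[c]) for c in range(H + 1)])
    return CohortTrace(cfg=cfg, arm=arm, occupancy=occupancy, expanded=expanded,
                       surgery_rt_entrants=surgery_rt, pd_entrants=pd_in,
                       death_entrants=deaths)
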