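import numpy as np
import pytest

from periopcea.markov_engine import (
    STATES,
    EngineConfig,
    build_transition_matrix,
    conditional_transition_prob,
    run_cohort,
)
from periopcea.pipeline import build_engine_config
from periopcea.survival_models import SurvivalModelSpec, survival_at

DT = 21.0 / 30.4375  # cycle length in months


def test_conditional_probability_is_memoryless_for_exponential():
    spec = SurvivalModelSpec("exponential", {"rate": 0.05})
    probs = {conditional_transition_prob(spec, t, DT) for t in (0.0, 6.0, 60.0, 300.0)}
    assert len({round(p, 14) for p in probs}) == 1
    assert probs.pop() == pytest.approx(1.0 - np.exp(-0.05 * DT))


def test_conditional_probability_boundaries():
    spec = SurvivalModelSpec("weibull", {"shape": 1.232, "scale": 70.275})
    assert conditional_transition_prob(spec, 12.0, 0.0) == 0.0
    direct = 1.0 - float(survival_at(spec, 12.0 + DT)) / float(survival_at(spec, 12.0))
    assert conditional_transition_prob(spec, 12.0, DT) == pytest.approx(direct, abs=1e-12)


def test_exhausted_cohort_transitions_with_certainty():
    # Weibull survival underflows to 0 far beyond the scale
    spec = SurvivalModelSpec("weibull", {"shape": 3.0, "scale": 1.0})
    assert conditional_transition_prob(spec, 1e6, DT) == 1.0


def test_every_row_of_every_matrix_sums_to_one(engine_config):
    for arm in ("pembrolizumab", "placebo"):
        for cycle in range(1, engine_config.horizon_cycles + 1):
            M = build_transition_matrix(cycle, engine_config, arm)
            assert np.max(np.abs(M.sum(axis=1) - 1.0)) < 1e-10
            assert np.all(M >= 0.0)


def test_surgery_window_gates_the_transition(engine_config):
    i_neo, i_post = engine_config.idx["NEOADJ"], engine_config.idx["POST"]
    for cycle, open_ in ((4, False), (5, True), (6, True), (7, False), (50, False)):
        M = build_transition_matrix(cycle, engine_config, "placebo")
        assert (M[i_neo, i_post] > 0.0) == open_
    # adjuvant window is open only for the intervention arm, cycles 6-10
    i_adj1 = engine_config.idx["ADJ"][0]
    for cycle, open_ in ((5, False), (6, True), (10, True), (11, False)):
        M = build_transition_matrix(cycle, engine_config, "pembrolizumab")
        assert (M[i_post, i_adj1] > 0.0) == open_
        assert build_transition_matrix(cycle, engine_config, "placebo")[i_post, i_adj1] == 0.0


def _no_mortality_config(table, settings, **engine_overrides):
    from dataclasses import replace

    cfg = build_engine_config(table.with_value("p_surgery_mortality_30d", 0.0), settings)
    return replace(cfg, use_background_mortality=False, **engine_overrides)


def test_cohort_survival_reproduces_the_os_curve(table, settings):
    cfg = _no_mortality_config(table, settings)
    for arm in ("pembrolizumab", "placebo"):
        trace = run_cohort(cfg, arm)
        cycles = np.arange(cfg.horizon_cycles + 1)
        expected = survival_at(cfg.os_specs[arm], cycles * cfg.cycle_months)
        assert np.max(np.abs(trace.alive - expected)) < 1e-6


def test_death_occupancy_is_monotone(engine_config):
    for arm in ("pembrolizumab", "placebo"):
        dead = run_cohort(engine_config, arm).occupancy[:, STATES.index("DEATH")]
        assert np.all(np.diff(dead) >= -1e-12)
        assert dead[0] == 0.0


def test_no_event_limit_moves_only_window_mass(table, settings):
    inert = SurvivalModelSpec("exponential", {"rate": 1e-12})
    cfg = _no_mortality_config(table, settings,
                               os_specs={"pembrolizumab": inert, "placebo": inert},
                               efs_specs={"pembrolizumab": inert, "placebo": inert})
    trace = run_cohort(cfg, "placebo")
    assert trace.alive == pytest.approx(np.ones(cfg.horizon_cycles + 1), abs=1e-9)
    assert trace.occupancy[:, STATES.index("PD")] == pytest.approx(0.0, abs=1e-9)
    # after the surgery window the NEOADJ -> POST split equals the configured proportion
    final_post = trace.occupancy[-1, STATES.index("POST_SURG_RT")]
    assert final_post == pytest.approx(cfg.proportion_surgery_or_rt["placebo"], abs=1e-9)


def test_pd_empty_when_efs_equals_os(table, settings):
    cfg = build_engine_config(table, settings)
    from dataclasses import replace

    cfg = replace(cfg, efs_specs=dict(cfg.os_specs))
    for arm in ("pembrolizumab", "placebo"):
        pd_occ = run_cohort(cfg, arm).occupancy[:, STATES.index("PD")]
        assert pd_occ == pytest.approx(0.0, abs=1e-12)


def test_pd_occupancy_ordered_under_stochastic_dominance(table, settings):
    # same OS in both arms, intervention EFS stochastically dominates:
    # the dominated arm carries at least as much progressive disease at every cycle
    os_spec = SurvivalModelSpec("weibull", {"shape": 1.232, "scale": 70.275})
    efs_hi = SurvivalModelSpec("weibull", {"shape": 1.2, "scale": 60.0})
    efs_lo = SurvivalModelSpec("weibull", {"shape": 1.2, "scale": 40.0})
    cfg = _no_mortality_config(table, settings,
                               os_specs={"pembrolizumab": os_spec, "placebo": os_spec},
                               efs_specs={"pembrolizumab": efs_hi, "placebo": efs_lo})
    pd_pem = run_cohort(cfg, "pembrolizumab").occupancy[:, STATES.index("PD")]
    pd_pla = run_cohort(cfg, "placebo").occupancy[:, STATES.index("PD")]
    assert np.all(pd_pem <= pd_pla + 1e-9)


def test_trace_rows_are_distributions(engine_config):
    for arm in ("pembrolizumab", "placebo"):
        trace = run_cohort(engine_config, arm)
        assert np.max(np.abs(trace.occupancy.sum(axis=1) - 1.0)) < 1e-10
        assert np.max(np.abs(trace.expanded.sum(axis=1) - 1.0)) < 1e-10
        assert np.all(trace.occupancy >= -1e-15)


def test_entrant_accounting_consistent_with_trace(engine_config):
    trace = run_cohort(engine_config, "pembrolizumab")
    dead = trace.occupancy[:, STATES.index("DEATH")]
    assert np.cumsum(trace.death_entrants[1:]) == pytest.approx(dead[1:], abs=1e-12)
    # surgery/RT flows happen only in the window cycles and sum below the proportion
    w1, w2 = engine_config.window_neo_to_surg
    nonzero = np.nonzero(trace.surgery_rt_entrants)[0]
    assert set(nonzero) <= set(range(w1, w2 + 1))
    total = trace.surgery_rt_entrants.sum()
    assert 0.0 < total <= engine_config.proportion_surgery_or_rt["pembrolizumab"]
    assert np.all(trace.pd_entrants >= 0.0)


def test_microsimulation_agrees_with_cohort_trace(engine_config):
    rng = np.random.default_rng(123)
    N = 1_000_000
    cfg = engine_config
    state = np.zeros(N, dtype=np.int16)
    trace = run_cohort(cfg, "pembrolizumab")
    for c in range(1, cfg.horizon_cycles + 1):
        M = build_transition_matrix(c, cfg, "pembrolizumab")
        cum = np.cumsum(M, axis=1)
        u = rng.random(N)
        new = np.empty_like(state)
        for s in np.unique(state):
            mask = state == s
            new[mask] = np.searchsorted(cum[s], u[mask], side="right")
        state = new
        if c % 43 == 0 or c == cfg.horizon_cycles:
            freq = np.bincount(state, minlength=cfg.n_expanded) / N
            expected = trace.expanded[c]
            se = np.sqrt(np.maximum(expected * (1.0 - expected), 1e-12) / N)
            z = np.abs(freq - expected) / np.maximum(se, 1e-9)
            assert z.max() < 3.0, f"cycle {c}: max z = {z.max():.2f}"


def test_config_validation():
    spec = SurvivalModelSpec("exponential", {"rate": 0.05})
    specs = {"pembrolizumab": spec, "placebo": spec}
    with pytest.raises(ValueError, match="horizon"):
        EngineConfig(os_specs=specs, efs_specs=specs, horizon_cycles=5)
    with pytest.raises(ValueError, match="probability"):
        EngineConfig(os_specs=specs, efs_specs=specs, p_surgery_mortality_30d=1.5)
    cfg = EngineConfig(os_specs=specs, efs_specs=specs)
    with pytest.raises(ValueError, match="arm"):
        run_cohort(cfg, "nonexistent")
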