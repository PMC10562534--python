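import math

import numpy as np
import pytest
from scipy import integrate

from periopcea.survival_models import (
    FAMILIES,
    FitResult,
    IPDSample,
    SurvivalModelSpec,
    fit_all_families,
    fit_parametric,
    hazard_at,
    quantile,
    select_best,
    survival_at,
    censored_loglik,
)
from periopcea.synthetic_data import Censoring, generate_ipd

SPECS = {
    "exponential": SurvivalModelSpec("exponential", {"rate": 0.05}),
    "weibull": SurvivalModelSpec("weibull", {"shape": 1.232, "scale": 70.275}),
    "loglogistic": SurvivalModelSpec("loglogistic", {"shape": 1.5, "scale": 40.0}),
    "lognormal": SurvivalModelSpec("lognormal", {"meanlog": 5.023, "sdlog": 2.074}),
    "gengamma": SurvivalModelSpec("gengamma", {"mu": 2.866, "sigma": 1.951, "Q": -1.399}),
    "gamma": SurvivalModelSpec("gamma", {"shape": 2.0, "rate": 0.04}),
    "gompertz": SurvivalModelSpec("gompertz", {"shape": -0.02, "rate": 0.015}),
}


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
def test_survival_function_is_a_proper_survival_curve(spec):
    grid = np.linspace(0.0, 240.0, 400)
    s = survival_at(spec, grid)
    assert s[0] == 1.0
    assert np.all((s >= 0.0) & (s <= 1.0))
    assert np.all(np.diff(s) <= 1e-12)


def test_weibull_survival_at_scale_is_exp_minus_one():
    s = survival_at(SPECS["weibull"], 70.275)
    assert s == pytest.approx(math.exp(-1.0), abs=1e-12)


@pytest.mark.parametrize("t", [1.0, 12.0, 60.0])
def test_gengamma_small_q_recovers_lognormal(t):
    gg = SurvivalModelSpec("gengamma", {"mu": 4.0, "sigma": 1.5, "Q": 1e-8})
    ln = SurvivalModelSpec("lognormal", {"meanlog": 4.0, "sdlog": 1.5})
    assert survival_at(gg, t) == pytest.approx(float(survival_at(ln, t)), abs=1e-4)


def test_gengamma_q_one_recovers_weibull():
    gg = SurvivalModelSpec("gengamma", {"mu": math.log(70.275), "sigma": 1 / 1.232, "Q": 1.0})
    grid = np.array([3.0, 24.0, 96.0])
    assert survival_at(gg, grid) == pytest.approx(survival_at(SPECS["weibull"], grid), abs=1e-10)


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
def test_hazard_integrates_to_cumulative_hazard(spec):
    # oracle: numeric quadrature of h(t) = f/S over [0, T] equals -ln S(T)
    T = 24.0
    H, err = integrate.quad(lambda u: float(hazard_at(spec, u)), 1e-9, T, limit=200)
    assert H == pytest.approx(-math.log(float(survival_at(spec, T))), abs=1e-6)


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
def test_quantile_inverts_survival(spec):
    # keep below the negative-shape Gompertz plateau S(inf) = exp(rate/shape)
    q = np.array([0.05, 0.3, 0.5])
    t = quantile(spec, q)
    assert survival_at(spec, t) == pytest.approx(1.0 - q, abs=1e-9)


def test_gompertz_plateau_quantile_unreachable():
    with pytest.raises(ValueError, match="plateau"):
        quantile(SPECS["gompertz"], 0.9)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SurvivalModelSpec("weibull", {"shape": 1.0, "scale": -2.0})
    with pytest.raises(ValueError):
        SurvivalModelSpec("weibull", {"shape": 1.0})
    with pytest.raises(ValueError):
        SurvivalModelSpec("nonsense", {"rate": 1.0})


def test_exponential_mle_matches_closed_form():
    ipd = generate_ipd(SPECS["exponential"], 5000, seed=3)
    fit = fit_parametric(ipd, "exponential")
    closed_form = ipd.n_events / ipd.times.sum()
    assert fit.spec["rate"] == pytest.approx(closed_form, rel=1e-4)
    assert fit.spec["rate"] == pytest.approx(0.05, rel=0.03)
    assert fit.aic == pytest.approx(2.0 * 1 - 2.0 * fit.loglik, abs=1e-9)
    assert fit.bic == pytest.approx(math.log(fit.n) - 2.0 * fit.loglik, abs=1e-9)


def test_weibull_recovery_under_censoring():
    rng = np.random.default_rng(5)
    event_t = np.asarray(quantile(SPECS["weibull"], rng.uniform(size=2000)))
    censor_t = rng.uniform(0.0, 200.0, size=2000)  # ~30% censoring
    times = np.minimum(event_t, censor_t)
    ipd = IPDSample(np.maximum(times, 1e-9), (event_t <= censor_t).astype(int))
    assert 0.2 < 1 - ipd.n_events / len(ipd) < 0.4
    fit = fit_parametric(ipd, "weibull")
    assert fit.spec["shape"] == pytest.approx(1.232, rel=0.10)
    assert fit.spec["scale"] == pytest.approx(70.275, rel=0.10)


def test_fit_rejects_degenerate_data():
    with pytest.raises(ValueError, match="censored"):
        fit_parametric(IPDSample(np.arange(1.0, 21.0), np.zeros(20, dtype=int)), "weibull")
    with pytest.raises(ValueError, match="at least 10"):
        fit_parametric(IPDSample(np.arange(1.0, 6.0), np.ones(5, dtype=int)), "weibull")


def test_fitted_optimum_beats_perturbed_neighbours():
    ipd = generate_ipd(SPECS["weibull"], 800, Censoring(admin_time=120.0), seed=9)
    fit = fit_parametric(ipd, "weibull")
    rng = np.random.default_rng(0)
    for _ in range(100):
        perturbed = SurvivalModelSpec("weibull", {
            k: v * float(rng.lognormal(0.0, 0.05)) for k, v in fit.spec.params.items()})
        assert censored_loglik(perturbed, ipd) <= fit.loglik + 1e-9


def test_select_best_orders_by_aic_then_bic_then_k():
    def fr(family, loglik, n=100):
        return FitResult(SurvivalModelSpec(family, dict(zip(FAMILIES[family],
                                                            [1.0] * len(FAMILIES[family])))),
                         loglik=loglik, n=n)

    a, b = fr("exponential", -49.0), fr("weibull", -55.0)  # aic 100 vs 114
    assert select_best([b, a])[0] is a
    # aic tie between 2-parameter families at equal loglik: bic also ties, k breaks vs gengamma
    c = fr("gengamma", -54.0)  # aic 114 ties b; bic larger (k=3)
    ranked = select_best([c, b])
    assert ranked[0] is b
    with pytest.raises(ValueError):
        select_best([])


def test_family_selection_recovers_identifiable_weibull():
    truth = SurvivalModelSpec("weibull", {"shape": 2.2, "scale": 40.0})
    hits = 0
    for seed in range(10):
        ipd = generate_ipd(truth, 1000, Censoring(admin_time=90.0, random_rate=0.002),
                           seed=100 + seed)
        ranked = select_best(fit_all_families(ipd))
        hits += "weibull" in [f.spec.family for f in ranked[:2]]
    assert hits >= 9
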