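"""Cohort model: transition schedules, trace recursion, cost/health accrual."""

import math

import numpy as np
import pytest

from nsclc_cea.markov_engine import (
    AdverseEvent,
    HealthInputs,
    MarkovTrace,
    ModelConfig,
    Strategy,
    TransitionSchedule,
    accrue_costs,
    accrue_health,
    build_transition_schedule,
    evaluate_strategy,
    on_treatment_fraction,
    run_trace,
)
from nsclc_cea.survival_models import SurvivalFit
from nsclc_cea.synthetic_data import default_params, strategies_from_params
from oracles import markov_microsim_oracle


def _exp_fit(rate):
    return SurvivalFit("exponential", (rate,), 0.0, 10, 10)


CFG = ModelConfig()


# --- transition schedule -----------------------------------------------------


def test_schedule_zero_death_rate():
    sched = build_transition_schedule(_exp_fit(0.05), _exp_fit(0.0), CFG)
    assert np.all(sched.p_death == 0.0)


def test_schedule_identical_curves_no_progression():
    sched = build_transition_schedule(_exp_fit(0.03), _exp_fit(0.03), CFG)
    assert np.allclose(sched.p_progress, 0.0, atol=1e-14)


def test_schedule_exponential_closed_form():
    sched = build_transition_schedule(_exp_fit(0.05), _exp_fit(0.02), CFG)
    assert sched.p_death[7] == pytest.approx(1 - math.exp(-0.06), abs=1e-12)
    assert sched.p_progress[7] == pytest.approx(math.exp(-0.06) - math.exp(-0.15), abs=1e-12)


def test_schedule_warns_when_pfs_above_os():
    with pytest.warns(UserWarning, match="floored"):
        sched = build_transition_schedule(_exp_fit(0.01), _exp_fit(0.05), CFG)
    assert np.all(sched.p_progress == 0.0)


# --- trace recursion ---------------------------------------------------------


def test_trace_no_transitions_stays_put():
    sched = TransitionSchedule(np.zeros(100), np.zeros(100))
    trace = run_trace(sched, ModelConfig(max_cycles=100))
    assert trace.n_cycles == 101
    assert np.allclose(trace.occupancy, np.tile([1.0, 0.0, 0.0], (101, 1)))


def test_trace_immediate_death():
    p = np.zeros(10)
    p[0] = 1.0
    trace = run_trace(TransitionSchedule(p, np.zeros(10)), ModelConfig(max_cycles=10))
    assert np.allclose(trace.occupancy[1], [0.0, 0.0, 1.0])
    assert trace.incident_deaths[1] == 1.0
    assert trace.n_cycles == 2  # absorbed; trace stops


def test_trace_rejects_invalid_probabilities():
    with pytest.raises(ValueError):
        run_trace(TransitionSchedule(np.array([1.2]), np.array([0.0])), CFG)
    with pytest.raises(ValueError, match="exceeds 1"):
        run_trace(TransitionSchedule(np.array([0.7]), np.array([0.7])), CFG)


def test_trace_occupancy_rows_sum_to_one_and_death_monotone():
    sched = build_transition_schedule(_exp_fit(0.06), _exp_fit(0.02), CFG)
    trace = run_trace(sched, CFG)
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-15)


def test_trace_survival_telescopes():
    sched = build_transition_schedule(_exp_fit(0.05), _exp_fit(0.02), CFG)
    trace = run_trace(sched, CFG)
    expected = np.cumprod(1.0 - trace.p_death)
    assert np.allclose(trace.alive[1:], expected, atol=1e-10)


def test_trace_matches_microsimulation_oracle():
    """Cohort recursion vs a 100,000-subject individual-level Monte Carlo."""
    cfg = ModelConfig(max_cycles=80, stop_threshold=0.0)
    sched = build_transition_schedule(
        SurvivalFit("weibull", (45.0, 1.4), 0.0, 10, 10),
        SurvivalFit("weibull", (95.0, 1.2), 0.0, 10, 10),
        cfg,
    )
    trace = run_trace(sched, cfg)
    rng = np.random.default_rng(2024)
    occ_sim = markov_microsim_oracle(sched.p_death, sched.p_progress, 100_000, trace.n_cycles - 1, rng)
    assert np.abs(trace.occupancy - occ_sim).max() <= 0.005


# --- on-treatment fraction ---------------------------------------------------


def test_on_treatment_fraction_rules():
    pfs = np.array([1.0, 0.8, 0.5, 0.3])
    assert np.allclose(on_treatment_fraction(pfs, 1.0), pfs)
    capped = on_treatment_fraction(pfs, 0.8, max_treatment_cycles=2)
    assert np.allclose(capped, [0.8, 0.64, 0.0, 0.0])
    assert capped[2] == 0.0
    with pytest.warns(UserWarning, match="clamped"):
        clamped = on_treatment_fraction(pfs, 1.3)
    assert np.allclose(clamped, pfs)
    with pytest.raises(ValueError):
        on_treatment_fraction(pfs, 0.0)


# --- accrual -----------------------------------------------------------------


def _toy_trace(n_cycles=10, pfs=0.5, pd_=0.3, inc_prog=0.05):
    occ = np.tile([pfs, pd_, 1 - pfs - pd_], (n_cycles, 1))
    return MarkovTrace(
        occupancy=occ,
        incident_deaths=np.full(n_cycles, 0.01),
        incident_progressions=np.full(n_cycles, inc_prog),
        p_death=np.zeros(n_cycles - 1),
    )


def _toy_strategy(**kw):
    defaults = dict(
        name="toy",
        induction_cost_per_cycle=1000.0,
        maintenance_cost_per_cycle=600.0,
        induction_cycles=4,
        tot_ratio=0.8,
        adverse_events=(AdverseEvent("ae", 0.2, 150.0, 0.1),),
        subsequent_fraction=0.6,
        subsequent_cost_per_cycle=400.0,
        max_subsequent_cycles=6,
    )
    defaults.update(kw)
    return Strategy(**defaults)


def test_costs_full_death_cycle_zero_hand_sum():
    """Single lived cycle: drug + one-off AE + follow-up + palliative care."""
    p = np.zeros(3)
    p[0] = 1.0
    cfg = ModelConfig(discount_rate=0.0, max_cycles=3)
    trace = run_trace(TransitionSchedule(p, np.zeros(3)), cfg)
    params = default_params()
    strat = strategies_from_params(params)["camrelizumab"]
    costs = accrue_costs(trace, strat, cfg)
    expected = (
        strat.tot_ratio * (452.08 + 17.65 + 1103.30)  # cycle-0 drug
        + 0.38 * 175.37 + 0.19 * 101.02 + 0.17 * 603.79  # AE one-off
        + 85.71  # follow-up while alive
        + 2464.50  # palliative per incident death
    )
    assert costs.total == pytest.approx(expected, abs=1e-8)


def test_costs_zero_strategy_is_free():
    trace = _toy_trace()
    strat = _toy_strategy(
        induction_cost_per_cycle=0.0, maintenance_cost_per_cycle=0.0,
        adverse_events=(), subsequent_cost_per_cycle=0.0,
    )
    cfg = ModelConfig(followup_cost_per_cycle=0.0, supportive_cost_per_cycle=0.0, palliative_cost_per_event=0.0)
    assert accrue_costs(trace, strat, cfg).total == 0.0


def test_costs_constant_trace_hand_oracle():
    """Spreadsheet-style independent accumulation, component by component."""
    trace = _toy_trace()
    strat = _toy_strategy()
    cfg = ModelConfig(discount_rate=0.05)
    costs = accrue_costs(trace, strat, cfg)

    wpy = cfg.weeks_per_year
    hand = {k: 0.0 for k in ("drug", "followup", "subsequent_therapy", "supportive_care", "palliative_care")}
    for k in range(10):
        d = (1.05) ** (-k * 3.0 / wpy)
        hand["drug"] += d * 0.8 * 0.5 * (1000.0 if k < 4 else 600.0)
        hand["followup"] += d * cfg.followup_cost_per_cycle * 0.8
        # no deaths in p_death -> progression cohorts persist; cap 6 cycles
        eligible = 0.05 * min(k + 1, 6)
        hand["subsequent_therapy"] += d * 0.6 * 400.0 * eligible
        hand["supportive_care"] += d * cfg.supportive_cost_per_cycle * (1 - 0.6) * 0.3
        hand["palliative_care"] += d * cfg.palliative_cost_per_event * 0.01
    hand["adverse_events"] = 0.2 * 150.0
    for name, value in hand.items():
        assert costs.components[name] == pytest.approx(value, abs=1e-8), name
    assert costs.total == pytest.approx(sum(hand.values()), abs=1e-8)


def test_health_qaly_equals_ly_with_unit_utilities():
    trace = _toy_trace()
    cfg = ModelConfig(discount_rate=0.0)
    out = accrue_health(trace, HealthInputs(1.0, 1.0), (), cfg)
    assert out.qaly == pytest.approx(out.ly, abs=1e-12)


def test_health_constant_trace_hand_oracle():
    trace = _toy_trace()
    cfg = ModelConfig(discount_rate=0.05)
    aes = (AdverseEvent("ae", 0.2, 150.0, 0.1),)
    out = accrue_health(trace, HealthInputs(0.81, 0.58), aes, cfg)
    wpy, cyc = cfg.weeks_per_year, 3.0 / cfg.weeks_per_year
    ly = qaly = 0.0
    for k in range(10):
        d = 1.05 ** (-k * 3.0 / wpy)
        ly += 0.8 * cyc * d
        qaly += (0.5 * 0.81 + 0.3 * 0.58) * cyc * d
    qaly -= 0.2 * 0.1 * cyc
    assert out.ly == pytest.approx(ly, abs=1e-8)
    assert out.qaly == pytest.approx(qaly, abs=1e-8)


def test_health_rejects_bad_utilities():
    with pytest.raises(ValueError):
        HealthInputs(1.2, 0.5)


# --- strategy evaluation -----------------------------------------------------


def test_evaluate_zero_inputs_yields_only_lys(true_fits):
    strat = _toy_strategy(
        induction_cost_per_cycle=0.0, maintenance_cost_per_cycle=0.0,
        adverse_events=(), subsequent_cost_per_cycle=0.0,
    )
    cfg = ModelConfig(followup_cost_per_cycle=0.0, supportive_cost_per_cycle=0.0, palliative_cost_per_event=0.0)
    f = true_fits["camrelizumab"]
    out = evaluate_strategy(strat, f["pfs"], f["os"], HealthInputs(0.0, 0.0), cfg)
    assert out.cost == 0.0
    assert out.qaly == 0.0
    assert out.ly > 0.5


def test_evaluate_fixture_directional_ordering(camel_fixture, true_fits):
    """Chemotherapy is cheaper; the camrelizumab arm gains QALYs."""
    outs = {
        name: evaluate_strategy(
            camel_fixture.strategies[name], f["pfs"], f["os"], camel_fixture.health, camel_fixture.config
        )
        for name, f in true_fits.items()
    }
    assert outs["chemotherapy"].cost < outs["camrelizumab"].cost
    assert outs["chemotherapy"].qaly < outs["camrelizumab"].qaly
    for o in outs.values():
        assert o.qaly <= o.ly
        assert o.cost <= o.cost_undiscounted
        assert sum(o.cost_components.values()) == pytest.approx(o.cost, abs=1e-8)
        assert min(o.cost_components.values()) >= 0.0


def test_discounting_monotone_and_identity(camel_fixture, true_fits):
    f = true_fits["camrelizumab"]
    strat = camel_fixture.strategies["camrelizumab"]

    def run(rate):
        cfg = ModelConfig(
            discount_rate=rate,
            followup_cost_per_cycle=camel_fixture.config.followup_cost_per_cycle,
            supportive_cost_per_cycle=camel_fixture.config.supportive_cost_per_cycle,
            palliative_cost_per_event=camel_fixture.config.palliative_cost_per_event,
        )
        return evaluate_strategy(strat, f["pfs"], f["os"], camel_fixture.health, cfg)

    r0, r5, r10 = run(0.0), run(0.05), run(0.10)
    assert r0.cost == pytest.approx(r0.cost_undiscounted, abs=1e-9)
    assert r0.ly == pytest.approx(r0.ly_undiscounted, abs=1e-12)
    assert r10.cost < r5.cost < r0.cost
    assert r10.ly < r5.ly < r0.ly
    assert r10.qaly < r5.qaly < r0.qaly


def test_discount_factors_definition():
    cfg = ModelConfig(discount_rate=0.05)
    d = cfg.discount_factors(5)
    assert d[0] == 1.0
    assert d[3] == pytest.approx(1.05 ** (-3 * 3.0 / cfg.weeks_per_year), abs=1e-14)


def test_half_cycle_correction_reduces_accrual(camel_fixture, true_fits):
    f = true_fits["camrelizumab"]
    sched = build_transition_schedule(f["pfs"], f["os"], camel_fixture.config)
    trace = run_trace(sched, camel_fixture.config)
    cfg_hcc = ModelConfig(half_cycle_correction=True)
    plain = accrue_health(trace, camel_fixture.health, (), camel_fixture.config)
    hcc = accrue_health(trace, camel_fixture.health, (), cfg_hcc)
    assert hcc.ly < plain.ly  # occupancy declines, so midpoints sit lower
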