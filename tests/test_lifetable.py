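"""Life-table difference equations: conservation, oracles, cost weighting."""

import math

import numpy as np
import pandas as pd
import pytest

from ssbstroke import (
    CostInputs,
    TaxScenario,
    ValidationError,
    aggregate_results,
    discount_series,
    disease_step,
    run_cohort,
    weighted_cost,
)


def make_epi(groups, sexes=("male", "female"), **rates):
    idx = pd.MultiIndex.from_product(
        [list(groups), list(sexes)], names=["age_group", "sex"]
    )
    defaults = dict(
        population=10_000.0,
        acm_rate=0.02,
        incidence=0.01,
        prevalence=0.03,
        case_fatality=0.2,
        d28=1.0 / 3.0,
        pyld_rate=0.05,
        cost_per_case_year=75.4,
    )
    defaults.update(rates)
    return pd.DataFrame({k: v for k, v in defaults.items()}, index=idx)


# ---------------------------------------------------------------- costs

@pytest.mark.parametrize(
    "cost, share, ratio, expected",
    [
        (100.0, 0.18, 0.70, 75.4),   # 0.18*100 + 0.82*70
        (250.0, 0.18, 1.0, 250.0),   # equal sector costs
        (123.0, 1.0, 0.70, 123.0),   # all private
    ],
)
def test_weighted_cost(cost, share, ratio, expected):
    assert weighted_cost(CostInputs(cost, share, ratio)) == pytest.approx(
        expected, abs=1e-9
    )


def test_cost_inputs_validation():
    with pytest.raises(ValidationError):
        CostInputs(100.0, private_share=1.2)
    with pytest.raises(ValidationError):
        CostInputs(100.0, public_ratio=0.0)


# ---------------------------------------------------------------- discounting

def test_discount_series():
    assert (discount_series([5.0, 5.0], 0.0) == [5.0, 5.0]).all()
    out = discount_series([0.0, 100.0], 0.03)
    assert out[1] == pytest.approx(100.0 / 1.03, abs=1e-9)  # 97.0874
    vals = np.full(10, 7.0)
    assert discount_series(vals, 0.05).sum() < vals.sum()


# ---------------------------------------------------------------- disease step

def test_disease_step_hand_arithmetic():
    S, C, *flows = disease_step(
        1000.0, 0.0, incidence=0.01, case_fatality=0.2, d28=1.0 / 3.0, m_other=0.0
    )
    new_cases, acute, case_d, other = flows
    expected_cases = 1000.0 * (1 - math.exp(-0.01))        # 9.95017
    assert new_cases == pytest.approx(expected_cases, abs=1e-9)
    assert acute == pytest.approx(expected_cases / 3.0, abs=1e-9)       # 3.3167
    assert C == pytest.approx(expected_cases * 2.0 / 3.0, abs=1e-9)     # 6.6334
    assert case_d == 0.0 and other == 0.0
    assert S + C + acute == pytest.approx(1000.0, abs=1e-9)


def test_zero_incidence_only_decays_prevalent_pool():
    S, C, new_cases, acute, case_d, other = disease_step(
        500.0, 100.0, incidence=0.0, case_fatality=0.2, d28=0.5, m_other=0.1
    )
    assert new_cases == 0.0 and acute == 0.0
    assert case_d == pytest.approx(100.0 * (1 - math.exp(-0.2)), abs=1e-9)
    assert S + C + case_d + other == pytest.approx(600.0, abs=1e-9)


def test_full_pif_equals_zero_incidence():
    a = disease_step(800.0, 50.0, 0.05, 0.2, 0.3, 0.02, pif=1.0)
    b = disease_step(800.0, 50.0, 0.0, 0.2, 0.3, 0.02)
    assert a == b


def test_conservation_randomized_hundred_runs():
    """Persons in = persons out + deaths, exactly, across 100 randomized
    multi-year cohort runs."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        S, C = rng.uniform(100, 1e6), rng.uniform(0, 1e5)
        for _year in range(10):
            total_in = S + C
            S, C, _, acute, case_d, other = disease_step(
                S,
                C,
                incidence=rng.uniform(0, 0.5),
                case_fatality=rng.uniform(0, 1.5),
                d28=rng.uniform(0, 1),
                m_other=rng.uniform(0, 1.5),
                pif=rng.uniform(0, 1),
            )
            total_out = S + C + acute + case_d + other
            assert math.isclose(total_in, total_out, rel_tol=1e-12)
            assert S >= 0 and C >= 0


# ---------------------------------------------------------------- cohorts

def test_cohort_conservation_across_years():
    epi = make_epi([f"{lo}-{lo+4}" for lo in range(60, 80, 5)])
    res = run_cohort(epi, None, TaxScenario())
    alive = res["alive_start"]
    deaths = res["total_deaths"]
    for t in range(alive.shape[2] - 1):
        active = alive[:, :, t + 1] > 0
        lhs = alive[:, :, t + 1][active]
        rhs = (alive[:, :, t] - deaths[:, :, t])[active]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


def test_spreadsheet_oracle_one_cohort_five_years():
    """A single cohort with constant rates matches an independently
    hand-unrolled difference-equation computation cell for cell."""
    i, f, d28, m, dw = 0.02, 0.25, 0.3, 0.05, 0.28
    pyld, cost, prev0, pop = 0.06, 120.0, 0.04, 1000.0
    epi = make_epi(
        ["50-54"], sexes=["female"],
        population=pop, acm_rate=m, incidence=i, prevalence=prev0,
        case_fatality=f, d28=d28, pyld_rate=pyld, cost_per_case_year=cost,
    )
    scen = TaxScenario(horizon_years=5)
    res = run_cohort(epi, None, scen, sim_years=5)

    # independent unroll, plain scalar arithmetic
    pyld_bg = pyld - prev0 * dw
    S, C = pop * (1 - prev0), pop * prev0
    for t in range(5):
        nc = S * (1 - math.exp(-i))
        ac = nc * d28
        enter = nc - ac
        cd = C * (1 - math.exp(-f))
        s_mid, c_mid_pool = S - nc, C - cd + enter
        pm = 1 - math.exp(-m)
        oS, oC = s_mid * pm, c_mid_pool * pm
        S2, C2 = s_mid - oS, c_mid_pool - oC
        c_mid = (C + C2) / 2
        ly = (S + C + S2 + C2) / 2
        haly = ly * (1 - pyld_bg) - c_mid * dw

        assert res["incident_cases"][0, 0, t] == pytest.approx(nc, abs=1e-9)
        assert res["stroke_deaths"][0, 0, t] == pytest.approx(ac + cd, abs=1e-9)
        assert res["other_deaths"][0, 0, t] == pytest.approx(oS + oC, abs=1e-9)
        assert res["prevalent_mid"][0, 0, t] == pytest.approx(c_mid, abs=1e-9)
        assert res["life_years"][0, 0, t] == pytest.approx(ly, abs=1e-9)
        assert res["halys"][0, 0, t] == pytest.approx(haly, abs=1e-9)
        assert res["costs"][0, 0, t] == pytest.approx(c_mid * cost, abs=1e-9)
        S, C = S2, C2


def test_null_pif_table_gives_identical_arms():
    epi = make_epi([f"{lo}-{lo+4}" for lo in range(40, 60, 5)])
    pifs = pd.DataFrame(0.0, index=epi.index, columns=range(20))
    scen = TaxScenario()
    ref = run_cohort(epi, None, scen, arm="reference")
    intervention = run_cohort(epi, pifs, scen, arm="intervention")
    for key in ref.arrays:
        np.testing.assert_array_equal(ref[key], intervention[key])
    agg = aggregate_results(ref, intervention, scen)
    for k, v in agg["summary"].items():
        if k.endswith(("averted", "gained", "zar", "final_year")):
            assert v == 0.0


def test_acute_fatality_one_prevents_prevalent_accumulation():
    """With d28 = 1 every incident case dies acutely: prevalence differences
    between arms vanish while mortality differences persist."""
    groups = [f"{lo}-{lo+4}" for lo in range(50, 70, 5)]
    epi = make_epi(groups, d28=1.0, prevalence=0.0)
    pifs = pd.DataFrame(0.2, index=epi.index, columns=range(20))
    scen = TaxScenario()
    ref = run_cohort(epi, None, scen)
    intervention = run_cohort(epi, pifs, scen, arm="intervention")
    np.testing.assert_allclose(
        ref["prevalent_mid"], intervention["prevalent_mid"], atol=1e-12
    )
    assert ref["stroke_deaths"][:, :, 0].sum() > intervention["stroke_deaths"][:, :, 0].sum()


def test_prevalence_reduction_lags_incidence_reduction(bundle):
    """Year-1: the prevalent pool dilutes the incident change, so the
    percentage prevalence reduction is below the incidence reduction."""
    from ssbstroke import run_model

    res = run_model(bundle, TaxScenario())
    for sex in bundle.sexes:
        inc1 = res.pct_reduction[(sex, "incidence")].iloc[0]
        prev1 = res.pct_reduction[(sex, "prevalence")].iloc[0]
        assert 0 < prev1 < inc1


def test_deaths_averted_nonnegative_each_year(bundle):
    from ssbstroke import run_model

    res = run_model(bundle, TaxScenario())
    for sex in bundle.sexes:
        ref = res.per_year[("reference", sex, "stroke_deaths")]
        intv = res.per_year[("intervention", sex, "stroke_deaths")]
        assert (ref - intv >= 0).all()


def test_discounting_changes_only_halys_and_costs(small_bundle):
    from ssbstroke import run_model

    r0 = run_model(small_bundle, TaxScenario(discount_rate=0.0)).summary
    r3 = run_model(small_bundle, TaxScenario(discount_rate=0.03)).summary
    for k in ("incident_cases_averted", "stroke_deaths_averted",
              "prevalent_cases_averted_final_year"):
        assert r3[k] == r0[k]
    assert r3["halys_gained"] < r0["halys_gained"]
    assert r3["costs_saved_zar"] < r0["costs_saved_zar"]


def test_rate_probability_conversion_is_exponential():
    # p = 1 - exp(-rate): a rate of 0.2/yr is not a 20 % annual probability
    _, C, new_cases, *_ = disease_step(1000.0, 0.0, 0.2, 0.0, 0.0, 0.0)
    assert new_cases == pytest.approx(1000.0 * (1 - math.exp(-0.2)), abs=1e-9)
    assert new_cases < 200.0
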