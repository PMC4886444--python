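"""Potential impact fraction: RR curve, integration, PIF identities."""

import numpy as np
import pandas as pd
import pytest

from ssbstroke import BMIDistribution, compute_pif, mean_rr, rr_at
from ssbstroke.bmi_model import SDMeanRelation, fit_lognormal
from ssbstroke.pif import RRSpec, mean_rr_batch, pif_table


@pytest.mark.parametrize(
    "bmi, expected",
    [(21.0, 1.0), (26.0, 1.35), (31.0, 1.35**2), (18.0, 1.0)],
)
def test_rr_curve_values(bmi, expected):
    assert rr_at(bmi, 1.35, tmreb=21.0) == pytest.approx(expected, abs=1e-12)


def test_flat_rr_gives_unit_mean_rr():
    d = BMIDistribution(29.0, 6.0)
    # up to the ~1e-7 truncation of the density beyond BMI 80
    assert mean_rr(d, 1.0) == pytest.approx(1.0, abs=1e-6)
    assert compute_pif(d, BMIDistribution(25.0, 5.0), 1.0) == pytest.approx(0.0, abs=1e-6)


def test_point_mass_at_threshold_has_unit_mean_rr():
    d = BMIDistribution(21.0, 0.01)
    assert mean_rr(d, 1.35) == pytest.approx(1.0, abs=1e-3)


def test_identical_distributions_give_exactly_zero_pif():
    d = BMIDistribution(27.5, 5.5)
    assert compute_pif(d, BMIDistribution(27.5, 5.5), 1.35) == 0.0


def test_degenerate_point_mass_pif_closed_form():
    """Near-point masses at tmreb+10 vs tmreb+5 with RR 1.35 per 5 units:
    PIF -> (1.35^2 - 1.35) / 1.35^2 = 0.259259..."""
    ref = BMIDistribution(31.0, 0.01)
    intervention = BMIDistribution(26.0, 0.01)
    expected = (1.35**2 - 1.35) / 1.35**2
    assert compute_pif(ref, intervention, 1.35) == pytest.approx(expected, abs=1e-6)


def test_quadrature_matches_monte_carlo_oracle():
    """Adaptive quadrature agrees with brute-force sampling within 3 MC
    standard errors for a realistic distribution."""
    n = 10_000_000
    mu, sigma = fit_lognormal(27.0, 5.0)
    rng = np.random.default_rng(2024)
    x = rng.lognormal(mu, sigma, n)
    rr = rr_at(x, 1.35)
    mc, se = rr.mean(), rr.std(ddof=1) / np.sqrt(n)
    quad = mean_rr(BMIDistribution(27.0, 5.0), 1.35)
    assert abs(quad - mc) < 3 * se


def test_downward_shift_with_positive_rr_gives_positive_pif():
    ref = BMIDistribution(28.0, 5.0)
    for shift in (0.1, 0.5, 1.5):
        p = compute_pif(ref, BMIDistribution(28.0 - shift, 5.0), 1.2)
        assert p > 0


def test_batch_quadrature_matches_adaptive():
    rng = np.random.default_rng(5)
    for _ in range(20):
        m, s = rng.uniform(22, 34), rng.uniform(3, 7)
        r = rng.uniform(1.02, 1.7)
        adaptive = mean_rr(BMIDistribution(m, s), r)
        mu, sigma = fit_lognormal(m, s)
        batch = float(mean_rr_batch(mu, sigma, r))
        assert batch == pytest.approx(adaptive, rel=1e-8)


def _spec_for(index, rr=1.35):
    t = pd.DataFrame({"rr_per_unit": rr, "log_sd": 0.05}, index=index)
    return RRSpec(t)


def _bmi_frame():
    idx = pd.MultiIndex.from_tuples(
        [("40-44", "male"), ("40-44", "female")], names=["age_group", "sex"]
    )
    return pd.DataFrame({"mean": [27.0, 29.0], "sd": [5.0, 6.0]}, index=idx)


def test_pif_table_matches_scalar_compute_pif():
    bmi = _bmi_frame()
    db = pd.Series([-0.3, -0.4], index=bmi.index)
    spec = _spec_for(bmi.index)
    table = pif_table(bmi, db, spec, rel=SDMeanRelation(0.25), n_years=3)
    assert table.shape == (2, 3)
    # trend 0: all years identical
    assert (table[0] == table[2]).all()
    for stratum in bmi.index:
        ref = BMIDistribution(*bmi.loc[stratum])
        m_i = bmi.loc[stratum, "mean"] + db[stratum]
        s_i = bmi.loc[stratum, "sd"] + 0.25 * db[stratum]
        scalar = compute_pif(ref, BMIDistribution(m_i, s_i), 1.35)
        assert table.loc[stratum, 0] == pytest.approx(scalar, abs=1e-9)


def test_pif_table_zero_shift_is_exactly_zero():
    bmi = _bmi_frame()
    db = pd.Series([0.0, 0.0], index=bmi.index)
    table = pif_table(bmi, db, _spec_for(bmi.index), n_years=2)
    assert (table.to_numpy() == 0.0).all()


def test_pif_monotone_in_tax_rate(bundle):
    """Through demand -> BMI, a larger price rise shifts BMI further down
    and yields a strictly larger PIF in every stratum."""
    from ssbstroke import consumption_change, net_energy_change
    from ssbstroke.bmi_model import equilibrium_weight_change, weight_to_bmi_change

    last = None
    for dpp in (0.1, 0.2, 0.3):
        dq = consumption_change(bundle.consumption, bundle.elasticities, dpp)
        de = net_energy_change(dq, bundle.energy_density)
        db = pd.Series(
            weight_to_bmi_change(
                equilibrium_weight_change(de.to_numpy()),
                bundle.heights.reindex(de.index).to_numpy(),
            ),
            index=de.index,
        )
        p = pif_table(bundle.bmi.reindex(db.index), db, bundle.rr,
                      rel=bundle.sd_mean_relation, n_years=1)[0]
        assert (p > 0).all()
        if last is not None:
            assert (p > last).all()
        last = p


def test_pif_invariant_to_incidence_scale(small_bundle):
    """The PIF is a proportional change in risk: rescaling baseline
    incidence leaves the relative year-1 incidence reduction unchanged."""
    import dataclasses

    from ssbstroke import TaxScenario, run_model

    r1 = run_model(small_bundle, TaxScenario(horizon_years=5))
    scaled = small_bundle.copy()
    scaled.epi = scaled.epi.assign(incidence=scaled.epi["incidence"] * 0.5)
    r2 = run_model(scaled, TaxScenario(horizon_years=5))
    pd.testing.assert_frame_equal(r1.pifs, r2.pifs)  # PIF acts on rates, not counts
    # and to first order the relative incidence reduction tracks the PIF
    for sex in small_bundle.sexes:
        a = r1.pct_reduction[(sex, "incidence")].iloc[0]
        b = r2.pct_reduction[(sex, "incidence")].iloc[0]
        assert b == pytest.approx(a, rel=0.05)
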