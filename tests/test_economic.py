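"""Cost-consequence model: funnel, savings mechanisms, break-even solvers."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digasim import (
    EconomicParams,
    FundYearRecord,
    FunnelParams,
    TherapyClass,
    TriangularSpec,
    apply_funnel,
    breakeven_adherence,
    breakeven_price,
    complementary_savings,
    demand_reduction,
    evaluate_fund,
    one_way_curve,
    partial_benefit_value,
    substitution_savings,
)
from digasim.economic import ConfigurationError, EconomicModelError, aggregate_net

PHYS, EAP = TherapyClass.PHYSIOTHERAPY, TherapyClass.EAP


def degenerate_econ(c_diga=450.0, r_sub_phys=0.10, r_sub_eap=0.03,
                    e_gain=0.20, r_comp_phys=0.35, r_comp_eap=0.25):
    """All parameters fixed (degenerate triangular specs)."""
    fix = lambda v: TriangularSpec(v, v, v)
    return EconomicParams(
        c_diga=fix(c_diga),
        r_sub={PHYS: fix(r_sub_phys), EAP: fix(r_sub_eap)},
        e_gain=fix(e_gain),
        r_comp={PHYS: fix(r_comp_phys), EAP: fix(r_comp_eap)},
    )


def single_class_record(n_cases, spend_per_case, cls=PHYS, fund_id="T"):
    other = EAP if cls is PHYS else PHYS
    return FundYearRecord(
        fund_id=fund_id, sector_label="toy", year=2024, insured_count=10_000,
        expenditure={cls: spend_per_case * n_cases, other: None},
        case_count={cls: float(n_cases), other: None},
    )


# ---------------------------------------------------------------------------
# Funnel
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n, eligibility, engaged, expected",
    [
        (1000, 0.70, 0.15, (700.0, 105.0, 595.0)),
        (0, 0.70, 0.15, (0.0, 0.0, 0.0)),
        (1000, 1.0, 1.0, (1000.0, 1000.0, 0.0)),
    ],
)
def test_funnel_cohort_arithmetic(n, eligibility, engaged, expected):
    cohorts = apply_funnel(
        n, FunnelParams(eligibility_rate=eligibility, engaged_share=engaged)
    )
    assert (cohorts.n_prescribed, cohorts.n_engaged, cohorts.n_short_term) == expected
    assert cohorts.n_engaged + cohorts.n_short_term == cohorts.n_prescribed


def test_funnel_rejects_out_of_range_shares():
    with pytest.raises(EconomicModelError):
        FunnelParams(eligibility_rate=1.5)
    with pytest.raises(EconomicModelError):
        FunnelParams(engaged_share=-0.1)


# ---------------------------------------------------------------------------
# Savings mechanisms (Models 1 and 2)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "args, expected",
    [
        ((1000, 1500.0, 0.10, 450.0), 105_000.0),
        ((1000, 1500.0, 0.0, 450.0), 0.0),
        ((1000, 450.0, 0.10, 450.0), 0.0),  # price equals avoided cost
    ],
)
def test_substitution_savings(args, expected):
    assert substitution_savings(*args) == pytest.approx(expected)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((1000, 1500.0, 0.10, 0.35, 0.20, 450.0), -47_250.0),
        ((1000, 1500.0, 0.10, 0.35, 0.20, 300.0), 0.0),  # per-case neutrality
        ((1000, 1500.0, 0.10, 0.0, 0.20, 450.0), 0.0),
    ],
)
def test_complementary_savings(args, expected):
    assert complementary_savings(*args) == pytest.approx(expected)


def test_partial_benefit_value():
    funnel = FunnelParams(session_cost=25.0)
    assert partial_benefit_value(595, funnel) == pytest.approx(44_625.0)
    assert partial_benefit_value(0, funnel) == 0.0
    assert partial_benefit_value(
        595, FunnelParams(partial_benefit_sessions=0, session_cost=25.0)) == 0.0


def test_partial_benefit_requires_session_cost():
    with pytest.raises(ConfigurationError):
        partial_benefit_value(10, FunnelParams())


# ---------------------------------------------------------------------------
# Fund evaluation
# ---------------------------------------------------------------------------


def test_evaluate_fund_matches_hand_oracle(toy_record, econ, funnel):
    """Spreadsheet-style oracle for the toy fund, computed independently:

    physio: 700 prescribed, 105 engaged, 595 short-term;
      sub 105*0.10*1500, comp 105*0.9*0.35*0.2*1500, partial 595*3*25,
      cost 700*450
    eap: 350 prescribed, 52.5 engaged, 297.5 short-term;
      sub 52.5*0.03*4000, comp 52.5*0.97*0.25*0.2*4000, partial 297.5*3*25,
      cost 350*450
    """
    b = evaluate_fund(toy_record, econ.at_mode(), funnel)
    assert b.substitution_savings == pytest.approx(15_750.0 + 6_300.0)
    assert b.complementary_savings == pytest.approx(9_922.5 + 10_185.0)
    assert b.partial_benefit_value == pytest.approx(44_625.0 + 22_312.5)
    assert b.diga_cost_total == pytest.approx(315_000.0 + 157_500.0)
    assert b.net == pytest.approx(-363_405.0)
    phys = b.per_class[PHYS]
    assert phys.net == pytest.approx(15_750.0 + 9_922.5 + 44_625.0 - 315_000.0)


def test_all_rates_zero_leaves_only_diga_cost(toy_record):
    econ = degenerate_econ(r_sub_phys=0.0, r_sub_eap=0.0,
                           r_comp_phys=0.0, r_comp_eap=0.0)
    funnel = FunnelParams(partial_benefit_sessions=0)
    b = evaluate_fund(toy_record, econ.at_mode(), funnel)
    assert b.net == pytest.approx(-b.diga_cost_total)
    assert b.diga_cost_total == pytest.approx(0.70 * 1500 * 450)


def test_zero_eligibility_gives_all_zero_breakdown(toy_record, econ):
    funnel = FunnelParams(eligibility_rate=0.0, session_cost=25.0)
    b = evaluate_fund(toy_record, econ.at_mode(), funnel)
    assert (b.substitution_savings, b.complementary_savings,
            b.partial_benefit_value, b.diga_cost_total, b.net) == (0,) * 5


def test_missing_stratum_is_skipped_and_flagged(econ, funnel):
    rec = single_class_record(100, 1500.0, cls=PHYS)
    b = evaluate_fund(rec, econ.at_mode(), funnel)
    assert b.skipped == [EAP]
    assert b.net != 0.0


def test_degenerate_funnel_reduces_to_plain_two_mechanism_model(toy_record, econ):
    """With eligibility 1, full engagement and no partial benefit, the funnel
    model collapses to the two gross mechanisms minus a universal per-case
    prescription charge."""
    funnel = FunnelParams(eligibility_rate=1.0, engaged_share=1.0,
                          partial_benefit_sessions=0)
    p = econ.at_mode()
    b = evaluate_fund(toy_record, p, funnel)
    expected = 0.0
    for cls, n, spc in ((PHYS, 1000.0, 1500.0), (EAP, 500.0, 4000.0)):
        expected += (
            substitution_savings(n, spc, p.r_sub[cls], c_diga=0.0)
            + complementary_savings(n, spc, p.r_sub[cls], p.r_comp[cls],
                                    p.e_gain, c_diga=0.0)
            - n * p.c_diga
        )
    assert b.net == pytest.approx(expected)


def test_session_cost_defaults_to_physio_spend_per_sessions(toy_record, econ):
    funnel = FunnelParams()  # derived: 1500 / 6 = 250 per session
    b = evaluate_fund(toy_record, econ.at_mode(), funnel)
    assert b.partial_benefit_value == pytest.approx((595.0 + 297.5) * 3 * 250.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    c1=st.floats(250, 600), c2=st.floats(250, 600),
    e1=st.floats(0.1, 0.3), e2=st.floats(0.1, 0.3),
)
def test_net_is_monotone_in_price_and_efficiency(c1, c2, e1, e2):
    """Net savings are affine: decreasing in the DiGA price, increasing in
    the efficiency gain."""
    record = single_class_record(1000, 1500.0)
    funnel = FunnelParams(session_cost=25.0)

    def net(c_diga, e_gain):
        econ = degenerate_econ(c_diga=c_diga, e_gain=e_gain)
        return evaluate_fund(record, econ.at_mode(), funnel).net

    lo_c, hi_c = sorted((c1, c2))
    if lo_c < hi_c:
        assert net(hi_c, 0.2) < net(lo_c, 0.2)
    lo_e, hi_e = sorted((e1, e2))
    if lo_e < hi_e:
        assert net(450.0, lo_e) < net(450.0, hi_e)


def test_mechanism_partition_never_exceeds_engaged_cohort(toy_record, econ, funnel):
    """Substituted and complementary cases are disjoint partitions of the
    engaged cohort."""
    p = econ.at_mode()
    for cls, n in ((PHYS, 1000.0), (EAP, 500.0)):
        engaged = apply_funnel(n, funnel).n_engaged
        subbed = engaged * p.r_sub[cls]
        comped = engaged * (1 - p.r_sub[cls]) * p.r_comp[cls]
        assert subbed + comped <= engaged + 1e-12


# ---------------------------------------------------------------------------
# Demand reduction
# ---------------------------------------------------------------------------


def test_demand_reduction_policies():
    econ = EconomicParams().at_mode()
    funnel = FunnelParams()
    assert demand_reduction(econ, funnel, mode="funnel") == pytest.approx(
        0.70 * 0.15 * 0.03
    )
    assert demand_reduction(econ, funnel, mode="fixed") == 0.15
    assert demand_reduction(econ, funnel, mode="fixed", scaling=0.0) == 0.0
    assert demand_reduction(econ, funnel, mode="fixed", scaling=1.5) == pytest.approx(
        0.225
    )
    with pytest.raises(EconomicModelError):
        demand_reduction(econ, funnel, mode="bogus")


# ---------------------------------------------------------------------------
# Break-even thresholds and one-way curves
# ---------------------------------------------------------------------------


def test_breakeven_price_matches_closed_form_on_substitution_only_toy():
    """Substitution only, full engagement, no partial benefit: the universal
    prescription charge breaks even at c* = r_sub * spend_per_case."""
    rec = single_class_record(1000, 1500.0)
    econ = degenerate_econ(r_sub_phys=0.5, r_comp_phys=0.0, r_comp_eap=0.0)
    funnel = FunnelParams(eligibility_rate=1.0, engaged_share=1.0,
                          partial_benefit_sessions=0)
    res = breakeven_price([rec], econ, funnel)
    assert res.feasible
    assert res.value == pytest.approx(0.5 * 1500.0, abs=0.01)
    assert abs(res.net_at_value) < 1.0


def test_breakeven_price_plugged_back_is_cost_neutral():
    """On a dataset where the model is viable at the cheapest price, the
    solved price is cost-neutral within one euro."""
    # High-value toy spend levels make the base case profitable.
    rec = single_class_record(1000, 4000.0)
    econ = EconomicParams()
    funnel = FunnelParams(session_cost=100.0)
    res = breakeven_price([rec], econ, funnel)
    assert res.feasible and res.value > econ.c_diga.low
    assert abs(res.net_at_value) < 1.0


def test_breakeven_price_reports_infeasible_when_loss_making_at_min_price():
    rec = single_class_record(1000, 100.0)
    res = breakeven_price([rec], EconomicParams(),
                          FunnelParams(partial_benefit_sessions=0))
    assert not res.feasible and res.status == "infeasible"


def test_breakeven_adherence_infeasible_when_engaged_savings_cannot_cover_cost():
    """Engaged-only savings per case below the universal prescription charge:
    the root lies above 100% and must be flagged infeasible."""
    rec = single_class_record(1000, 1500.0)
    # per engaged case: 0.10*1500 = 150 of savings vs charge 450 -> root at 3.0
    econ = degenerate_econ(r_sub_phys=0.10, r_comp_phys=0.0, r_comp_eap=0.0)
    funnel = FunnelParams(eligibility_rate=1.0, partial_benefit_sessions=0)
    res = breakeven_adherence([rec], econ, funnel)
    assert res.status == "infeasible" and not res.feasible
    assert res.value == pytest.approx(3.0, abs=1e-6)


def test_breakeven_adherence_feasible_root_matches_hand_algebra():
    """Large spend per case: net(s) = 1000*(150*s*spc_rate...) crosses zero
    inside (0, 1); for r_sub=0.10, spc=9000 and charge 450 the root is 0.5."""
    rec = single_class_record(1000, 9000.0)
    econ = degenerate_econ(r_sub_phys=0.10, r_comp_phys=0.0, r_comp_eap=0.0)
    funnel = FunnelParams(eligibility_rate=1.0, partial_benefit_sessions=0)
    res = breakeven_adherence([rec], econ, funnel)
    assert res.feasible and res.status == "ok"
    assert res.value == pytest.approx(0.5, abs=1e-6)
    assert abs(res.net_at_value) < 1.0


def test_breakeven_adherence_no_root_reported_as_unbounded():
    rec = single_class_record(1000, 100.0)
    econ = degenerate_econ(r_sub_phys=0.0, r_comp_phys=0.0, r_comp_eap=0.0)
    res = breakeven_adherence([rec], econ,
                              FunnelParams(partial_benefit_sessions=0))
    assert res.status == "no_root" and res.value is None


def test_one_way_curve_consistency(toy_record, econ, funnel):
    base = aggregate_net([toy_record], econ.at_mode(), funnel)
    ((v, net),) = one_way_curve("c_diga", [450.0], [toy_record], econ, funnel)
    assert (v, net) == (450.0, pytest.approx(base))

    grid = [250.0, 350.0, 450.0, 550.0, 617.8]
    nets = [n for _, n in one_way_curve("c_diga", grid, [toy_record], econ, funnel)]
    assert all(a > b for a, b in zip(nets, nets[1:]))  # strictly decreasing

    with pytest.raises(EconomicModelError):
        one_way_curve("r_sub", [0.1], [toy_record], econ, funnel)


def test_one_way_curve_sign_change_brackets_breakeven_price():
    rec = single_class_record(1000, 4000.0)
    econ, funnel = EconomicParams(), FunnelParams(session_cost=100.0)
    res = breakeven_price([rec], econ, funnel)
    lo, hi = res.value - 50.0, res.value + 50.0
    (_, net_lo), (_, net_hi) = one_way_curve(
        "c_diga", [lo, hi], [rec], econ, funnel
    )
    assert net_lo > 0 > net_hi
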