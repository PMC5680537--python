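"""Analytic population screening performance: DR, FPR, OAPR and comparators."""

import math

import pytest

from cfscreen import (
    PopulationParams,
    ScreeningPolicy,
    carrier_testing_performance,
    compare_with_carrier_testing,
    detection_rate,
    false_positive_rate,
    format_odds,
    fpr_strata,
    invasive_test_reduction,
    oapr,
    oapr_advantage_ratio,
    resource_requirements,
    screening_performance,
    table1,
    two_mutation_cutoff,
)


@pytest.mark.parametrize(
    "c1, ff, expected",
    [(51.0, 10.0, 46.0), (51.0, 4.0, 49.0), (51.0, 3.0, 49.5), (51.0, 20.0, 41.0),
     (50.0, 10.0, 45.0), (52.0, 2.0, 51.0), (51.0, 1e-9, pytest.approx(51.0))],
)
def test_two_mutation_cutoff_rule(c1, ff, expected):
    assert two_mutation_cutoff(c1, ff) == expected


def test_two_mutation_cutoff_range_check():
    with pytest.raises(ValueError):
        two_mutation_cutoff(5.0, 20.0)  # c2 would be -5


@pytest.mark.parametrize(
    "c1, ff, expected_pct",
    [(51.0, 10.0, 70), (51.0, 2.0, 35), (51.0, 3.0, 67), (50.0, 10.0, 70),
     (50.0, 2.0, 70), (52.0, 4.0, 35), (52.0, 3.0, 3)],
)
def test_detection_rate_rounds_to_printed_values(c1, ff, expected_pct, pop):
    dr = detection_rate(ScreeningPolicy(c1=c1, n=32000), ff, pop)
    assert round(dr) == expected_pct


def test_detection_rate_capped_by_panel_coverage(pop):
    cap = 100.0 * pop.panel_coverage**2
    for c1 in (50.0, 51.0, 52.0):
        for ff in (2.0, 3.0, 10.0, 20.0):
            assert detection_rate(ScreeningPolicy(c1=c1), ff, pop) <= cap + 1e-12


def test_detection_rate_monotone(pop):
    for ff in (2.0, 3.0, 4.0, 10.0):
        assert detection_rate(ScreeningPolicy(c1=52.0), ff, pop) <= detection_rate(
            ScreeningPolicy(c1=51.0), ff, pop
        ) + 1e-12
    for lo, hi in [(2.0, 3.0), (3.0, 4.0), (4.0, 10.0), (10.0, 20.0)]:
        assert detection_rate(ScreeningPolicy(c1=51.0), lo, pop) <= detection_rate(
            ScreeningPolicy(c1=51.0), hi, pop
        ) + 1e-12


def test_fpr_headline_values(pop):
    fpr_51 = false_positive_rate(ScreeningPolicy(c1=51.0), 10.0, pop)
    assert round(fpr_51, 3) == 0.002
    fpr_50 = false_positive_rate(ScreeningPolicy(c1=50.0), 10.0, pop)
    assert round(fpr_50, 1) == 0.8


def test_fpr_cpm_term_dominates_at_51(pop):
    """Without the OXX CPM stratum the FPR at (51, ff=10) drops below 0.001%."""
    no_cpm = PopulationParams(cpm_oxx_prev=0.0)
    assert false_positive_rate(ScreeningPolicy(c1=51.0), 10.0, no_cpm) < 0.001
    assert false_positive_rate(ScreeningPolicy(c1=51.0), 10.0, pop) > 0.001


def test_fpr_subdominant_strata_negligible(pop, policy):
    """All strata beyond the maternal-carrier (+CPM) pair contribute < 1e-4 %
    at the operating points, as the stratum enumeration assumes."""
    for ff in (3.0, 10.0, 20.0):
        df = fpr_strata(policy, ff, pop).set_index("stratum")
        minor = df.drop(["carrier_maternal", "carrier_maternal_cpm_oxx"])
        assert minor["contribution_pct"].sum() < 1e-4


def test_fpr_conservative_cpm_mode_rounds_identically(pop, policy):
    tail = false_positive_rate(policy, 10.0, pop, cpm_mode="tail")
    cons = false_positive_rate(policy, 10.0, pop, cpm_mode="conservative")
    assert cons >= tail
    assert round(tail, 3) == round(cons, 3) == 0.002


def test_fpr_vanishes_for_infinite_counts_without_cpm():
    pop = PopulationParams(cpm_oxx_prev=0.0)
    fpr = false_positive_rate(ScreeningPolicy(c1=51.0, n=10**9), 10.0, pop)
    assert fpr < 1e-12


def test_oapr_definition_and_formatting(pop):
    assert oapr(70.0, 0.002, pop) == pytest.approx(35000 / 2499)
    assert format_odds(oapr(70.0, 0.002, pop)) == "14:1"
    assert format_odds(oapr(70.0, 0.8, pop)) == "1:29"
    assert oapr(70.0, 70.0 / 2499, pop) == pytest.approx(1.0)
    assert math.isinf(oapr(70.0, 0.0, pop))
    assert format_odds(2000.0) == ">1000:1"


def test_two_mutation_pathway_equivalence(pop):
    """c2 = c1 - ff/2 keeps both branches' DR equal: exactly where the tails
    saturate, and at printed (nearest-percent) rounding everywhere."""
    for ff in (10.0, 20.0):
        p = ScreeningPolicy(c1=51.0)
        assert detection_rate(p, ff, pop, "two_mutation") == detection_rate(p, ff, pop)
    for ff in (2.0, 3.0, 4.0, 10.0, 20.0):
        p = ScreeningPolicy(c1=51.0)
        one = detection_rate(p, ff, pop)
        two = detection_rate(p, ff, pop, "two_mutation")
        assert round(one) == round(two)
        assert abs(one - two) < 0.01  # sd differs slightly between branch means


def test_carrier_testing_comparator(pop):
    est = carrier_testing_performance(pop)
    assert est.fpr == pytest.approx(0.12)
    assert round(est.dr) == 70
    assert est.oapr_odds == pytest.approx(1 / 3)
    assert est.oapr == "1:3"
    empty = PopulationParams(carrier_freq=0.0, panel_coverage=1.0)
    assert carrier_testing_performance(empty).fpr == 0.0


def test_oapr_advantage_and_invasive_reduction(pop, policy):
    rep = compare_with_carrier_testing(policy, 10.0, pop)
    assert round(rep["oapr_fold"]) == 42
    assert round(rep["invasive_reduction_pct"]) == 98
    same = carrier_testing_performance(pop)
    assert oapr_advantage_ratio(same, same) == pytest.approx(1.0)
    assert invasive_test_reduction(0.12, 0.12) == pytest.approx(0.0)
    assert invasive_test_reduction(0.0, 0.12) == pytest.approx(100.0)


def test_resource_requirements():
    res = resource_requirements(23, 32000)
    assert res["total_fragments"] == 736_000
    assert res["plasma_ml"] == pytest.approx(13.3, abs=0.05)
    assert resource_requirements(1, 2400)["plasma_ml"] == pytest.approx(1.0)


def test_table1_grid_matches_printed_rounding(pop):
    df = table1(pop).set_index(["ff", "c1"])
    printed_dr = {
        (20, 50): 70, (20, 51): 70, (20, 52): 70,
        (10, 50): 70, (10, 51): 70, (10, 52): 70,
        (4, 50): 70, (4, 51): 70, (4, 52): 35,
        (3, 50): 70, (3, 51): 67, (3, 52): 3,
        (2, 50): 70, (2, 51): 35, (2, 52): None,  # printed "<0.1"
    }
    for (ff, c1), dr in printed_dr.items():
        row = df.loc[(ff, c1)]
        if dr is None:
            assert row.dr < 0.1 and row.dr_display == "<0.1"
        else:
            assert round(row.dr) == dr
    for ff in (20, 10, 4, 3, 2):
        assert round(df.loc[(ff, 50)].fpr, 1) == 0.8
    for cell in [(20, 51), (10, 51), (20, 52)]:
        assert round(df.loc[cell].fpr, 3) == 0.002


def test_table1_oapr_identity_every_row(pop):
    df = table1(pop)
    for _, r in df.iterrows():
        assert r.oapr_odds == pytest.approx((r.dr / r.fpr) / 2499, rel=1e-12)


def test_table1_fpr_monotone_in_cutoff(pop):
    df = table1(pop)
    for ff, grp in df.groupby("ff"):
        fprs = grp.sort_values("c1")["fpr"].to_numpy()
        assert (fprs[1:] <= fprs[:-1] + 1e-15).all()


def test_screening_performance_bundle(pop, policy):
    est = screening_performance(policy, 10.0, pop)
    assert est.method == "analytic"
    assert round(est.dr) == 70 and round(est.fpr, 3) == 0.002
    assert round(est.oapr_odds) == 14


def test_population_params_validation():
    with pytest.raises(ValueError):
        PopulationParams(carrier_freq=1.5)
    with pytest.raises(ValueError):
        PopulationParams(cpm_oxx_prev=0.5, cpm_trisomy7_prev=0.2)
    with pytest.raises(ValueError):
        ScreeningPolicy(c1=0.0)
    # random-mating consistency of the defaults: prevalence ~ q^2 / 4
    p = PopulationParams()
    assert p.carrier_freq**2 / 4 == pytest.approx(1 / 2500)
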