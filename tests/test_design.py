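"""Pool-size design: workload formulas, sensitivity constraint, planner."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen._util import round_half_up
from poolscreen.design import (
    AnalyteSpec,
    DesignParams,
    RegulationLimit,
    choose_k_a,
    column_minima,
    compute_k_max,
    compute_loq_from_idl,
    expected_tests_per_sample,
    find_k_opt,
    generate_reference_table,
    plan_composite_test,
    savings,
)

from conftest import Q_GRID, REFERENCE_TABLE

q_st = st.floats(min_value=0.01, max_value=1.0, allow_nan=False)
k_st = st.integers(min_value=2, max_value=60)


# --------------------------------------------------------------------------
# workload formulas


@pytest.mark.parametrize(
    "q,k,expected,dp",
    [
        (0.99, 11, 0.196, 3),
        (0.95, 5, 0.426, 3),
        (0.70, 3, 0.99, 2),
        (1.00, 4, 0.25, 3),
    ],
)
def test_expected_tests_worked_examples(q, k, expected, dp):
    assert round_half_up(expected_tests_per_sample(q, k), dp) == pytest.approx(expected)


@pytest.mark.parametrize(
    "q,k,expected,dp",
    [(0.99, 11, 0.804, 3), (0.70, 3, 0.01, 2), (1.0, 2, 0.5, 3)],
)
def test_savings_worked_examples(q, k, expected, dp):
    assert round_half_up(savings(q, k), dp) == pytest.approx(expected)


@given(q=q_st, k=k_st)
@settings(max_examples=100, deadline=None)
def test_workload_complementarity(q, k):
    """Expected tests per sample and saved fraction always sum to 1."""
    assert expected_tests_per_sample(q, k) + savings(q, k) == pytest.approx(1.0)


@pytest.mark.parametrize("k", [1, 0, -3])
def test_group_of_one_rejected(k):
    with pytest.raises(ValueError):
        expected_tests_per_sample(0.9, k)


def test_non_integer_group_rejected():
    with pytest.raises(ValueError):
        savings(0.9, 2.5)


# --------------------------------------------------------------------------
# K_opt


@pytest.mark.parametrize("q,expected", [(0.99, 11), (0.95, 5), (0.90, 4), (0.80, 3)])
def test_k_opt_worked_examples(q, expected):
    assert find_k_opt(q) == expected


def test_k_opt_none_when_pooling_never_saves():
    """At q = 0.69 every group size needs more than one test per sample."""
    assert find_k_opt(0.69) is None


@given(q=st.floats(min_value=0.70, max_value=0.999))
@settings(max_examples=60, deadline=None)
def test_k_opt_matches_exhaustive_search(q):
    """Oracle check: independent brute-force minimization over the range."""
    best_k, best_v = None, float("inf")
    for k in range(2, 101):
        v = (1 - q**k) + 1 / k
        if v < best_v:
            best_k, best_v = k, v
    expected = best_k if best_v < 1.0 else None
    assert find_k_opt(q) == expected


def test_k_opt_empty_range():
    with pytest.raises(ValueError, match="empty"):
        find_k_opt(0.95, (10, 5))


# --------------------------------------------------------------------------
# sensitivity constraint


@pytest.mark.parametrize(
    "idl,volume,min_mass,expected",
    [(0.4, 25, 1.0, 10.0), (0.4, 25, 0.1, 100.0), (1.672, 2.5, 0.1, 41.8)],
)
def test_loq_from_idl(idl, volume, min_mass, expected):
    assert compute_loq_from_idl(idl, volume, min_mass) == pytest.approx(expected)


@pytest.mark.parametrize(
    "limit,u,loq,i,f,expected",
    [
        (1000, 14, 2.4, 1, 0.8, 286),   # single-substance 0.1 % scenario
        (1000, 18, 20, 4, 0.8, 8),      # four-substance sum scenario
        (1000, 23, 65, 3, 0.8, 3),      # three-substance sum scenario
        (1000, 23.2, 41.8, 1, 1.0, 18),  # routine method, per-substance limit
        (1000, 23.2, 41.8, 4, 1.0, 4),   # routine method, 4-substance sum
    ],
)
def test_k_max_worked_examples(limit, u, loq, i, f, expected):
    assert compute_k_max(limit, u, loq, i, f) == expected


def test_k_max_not_applicable_at_boundary():
    """When even one unpooled measurement has no headroom, K_max <= 1."""
    # loq >= L(1-U/100)F/I makes the ratio <= 1
    assert compute_k_max(1000, 0, 1000, 1, 1.0) is None
    assert compute_k_max(1000, 50, 450, 1, 0.8) is None


@given(
    limit=st.floats(min_value=10, max_value=1e6),
    u=st.floats(min_value=0, max_value=90),
    loq=st.floats(min_value=0.1, max_value=100),
    i=st.integers(min_value=1, max_value=8),
    f=st.floats(min_value=0.1, max_value=1.0),
)
@settings(max_examples=100, deadline=None)
def test_k_max_monotonicity(limit, u, loq, i, f):
    """K_max never increases when LOQ, I or U_rel grow, never decreases
    when L or F grow."""

    def as_int(v):
        return 1 if v is None else v

    base = as_int(compute_k_max(limit, u, loq, i, f))
    assert as_int(compute_k_max(limit, u, loq * 1.5, i, f)) <= base
    assert as_int(compute_k_max(limit, min(u * 1.1, 99.0), loq, i, f)) <= base
    assert as_int(compute_k_max(limit, u, loq, i + 1, f)) <= base
    assert as_int(compute_k_max(limit * 1.5, u, loq, i, f)) >= base
    assert as_int(compute_k_max(limit, u, loq, i, min(f * 1.1, 1.0))) >= base


# --------------------------------------------------------------------------
# K_a


@pytest.mark.parametrize(
    "k_opt,k_max,expected",
    [(11, 286, 10), (5, 8, 5), (4, 2, 2), (11, None, None)],
)
def test_choose_k_a(k_opt, k_max, expected):
    applicable = k_max is not None
    assert choose_k_a(k_opt, k_max, k_max_applicable=applicable) == expected


def test_choose_k_a_requires_some_input():
    with pytest.raises(ValueError):
        choose_k_a(None, None)


# --------------------------------------------------------------------------
# reference table


def test_reference_table_reproduces_published_grid():
    """All 84 printed cells match at 3 dp and the per-column minima sit
    at the published group sizes."""
    df = generate_reference_table(Q_GRID, list(REFERENCE_TABLE))
    for k, row in REFERENCE_TABLE.items():
        for q, expected in zip(Q_GRID, row):
            assert df.loc[k, q] == pytest.approx(expected), (k, q)
    minima = column_minima(df)
    assert minima[0.80] == [3]
    assert minima[0.90] == [4]
    assert minima[0.95] == [5]
    assert minima[0.99] == [10, 11]


def test_reference_table_all_pass_column():
    df = generate_reference_table([1.0], [2, 4, 5])
    assert list(df[1.0]) == [0.5, 0.25, 0.2]


# --------------------------------------------------------------------------
# planner


def _scenario_b_inputs():
    specs = [
        AnalyteSpec("DIBP", loq=2.5, expanded_uncertainty=13.0),
        AnalyteSpec("DBP", loq=3.4, expanded_uncertainty=15.0),
        AnalyteSpec("BBP", loq=20.0, expanded_uncertainty=18.0),
        AnalyteSpec("DEHP", loq=2.4, expanded_uncertainty=14.0),
    ]
    limit = RegulationLimit(
        limit=1000.0, n_substances=4, analytes=("DIBP", "DBP", "BBP", "DEHP")
    )
    return specs, limit


def test_plan_single_substance_scenario():
    specs = [AnalyteSpec("DEHP", loq=2.4, expanded_uncertainty=14.0)]
    limit = RegulationLimit(limit=1000.0, n_substances=1, analytes=("DEHP",))
    plan = plan_composite_test(specs, limit, DesignParams(q=0.99))
    assert plan.applicable
    assert (plan.k_opt, plan.k_max, plan.k_a) == (11, 286, 10)


def test_plan_sum_limit_scenario():
    specs, limit = _scenario_b_inputs()
    plan = plan_composite_test(specs, limit, DesignParams(q=0.95))
    assert plan.applicable
    assert (plan.k_opt, plan.k_max, plan.k_a) == (5, 8, 5)
    assert plan.u_rel_max == 18.0
    assert plan.loq_max == 20.0
    assert plan.tests_per_sample + plan.savings == pytest.approx(1.0)


def test_plan_thin_margin_scenario_warns():
    """The three-substance scenario computes K_max = 3 but sits at the
    edge of applicability, so the plan carries a warning."""
    specs = [
        AnalyteSpec("DNOP", loq=9.5, expanded_uncertainty=21.0),
        AnalyteSpec("DINP", loq=41.0, expanded_uncertainty=23.0),
        AnalyteSpec("DIDP", loq=65.0, expanded_uncertainty=23.0),
    ]
    limit = RegulationLimit(
        limit=1000.0, n_substances=3, analytes=("DNOP", "DINP", "DIDP")
    )
    plan = plan_composite_test(specs, limit, DesignParams(q=0.90))
    assert plan.k_max == 3
    assert plan.k_opt == 4
    assert plan.k_a == 3
    assert any("edge of applicability" in w for w in plan.warnings)


def test_plan_refuses_low_qualification_rate():
    specs, limit = _scenario_b_inputs()
    plan = plan_composite_test(specs, limit, DesignParams(q=0.5))
    assert not plan.applicable
    assert plan.k_a is None
    assert any("individually" in r for r in plan.reasons)


def test_plan_individual_testing_when_sensitivity_fails():
    specs = [AnalyteSpec("DIDP", loq=500.0, expanded_uncertainty=23.0)]
    limit = RegulationLimit(limit=1000.0, n_substances=1, analytes=("DIDP",))
    plan = plan_composite_test(specs, limit, DesignParams(q=0.95))
    assert not plan.applicable
    assert plan.k_max is None
    assert any("individually" in r for r in plan.reasons)


def test_plan_missing_specs_listed():
    specs, limit = _scenario_b_inputs()
    with pytest.raises(ValueError, match="BBP"):
        plan_composite_test(specs[:2], limit, DesignParams(q=0.95))


def test_limit_percent_canonicalization():
    assert RegulationLimit.from_percent(0.1).limit == pytest.approx(1000.0)
    assert RegulationLimit.from_percent(3.0).limit == pytest.approx(30000.0)
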