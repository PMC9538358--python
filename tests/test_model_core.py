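"""Stock-flow engine: projections, flows and balance accumulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ltcifund import (
    ConfigError,
    ContributionSchedule,
    EconomicState,
    GroupContribution,
    GrowthRates,
    LTCIFundModel,
    ParameterSet,
    PopulationState,
    Scheme,
    annual_expenditure,
    annual_revenue,
    project_economy,
    project_population,
    run_simulation,
    severely_disabled_count,
    step_balance,
)


def make_params(employees=100.0, retirees=0.0, residents=0.0, wage=50_000.0,
                pension=30_000.0, income=40_000.0, care=10_000.0,
                growth=None, end=2050, **kw):
    return ParameterSet(
        base_year=2019, horizon=(2020, end),
        initial_population=PopulationState(2019, employees, retirees, residents),
        initial_economy=EconomicState(2019, wage, pension, income, care),
        growth=growth or GrowthRates(care_cost=0.0), **kw)


# ---------------------------------------------------------------------------
# projections


class TestProjectPopulation:
    def test_zero_growth_is_constant(self):
        states = project_population(make_params(employees=100.0))
        assert all(s.insured_employees == 100.0 for s in states)
        assert [s.year for s in states] == list(range(2020, 2051))

    def test_compound_growth(self):
        params = make_params(employees=100.0, growth=GrowthRates(employees=0.1),
                             end=2021)
        states = project_population(params)
        assert [s.insured_employees for s in states] == pytest.approx([110.0, 121.0])

    def test_matches_independent_compounding_at_china_scale(self, china_params):
        # spreadsheet-style oracle: compound each group's rate by hand
        states = project_population(china_params)
        p0, g = china_params.initial_population, china_params.growth
        for s in states:
            dt = s.year - 2019
            assert s.insured_employees == pytest.approx(
                p0.insured_employees * (1 + g.employees) ** dt, rel=1e-9)
            assert s.insured_retirees == pytest.approx(
                p0.insured_retirees * (1 + g.retirees) ** dt, rel=1e-9)
            assert s.insured_residents == pytest.approx(
                p0.insured_residents * (1 + g.residents) ** dt, rel=1e-9)

    def test_nonfinite_projection_is_an_error(self):
        params = make_params(employees=1e308, growth=GrowthRates(employees=0.9))
        with pytest.raises(ConfigError, match="insured_employees"):
            project_population(params)

    def test_employees_override_replaces_path(self):
        params = make_params(employees=100.0)
        states = project_population(params, employees_override={2020: 7.0})
        assert states[0].insured_employees == 7.0
        assert states[1].insured_employees == 100.0

    def test_flow_mode_moves_employees_to_retirees(self):
        params = make_params(employees=1000.0, retirees=100.0,
                             retirement_flow_rate=0.1, end=2021)
        s1, s2 = project_population(params)
        assert s1.insured_employees == pytest.approx(900.0)
        assert s1.insured_retirees == pytest.approx(200.0)
        assert s2.insured_employees == pytest.approx(810.0)
        # total head count is conserved under zero group growth
        assert s2.total_insured == pytest.approx(1000.0 + 100.0)


class TestProjectEconomy:
    def test_zero_growth_constant(self):
        econs = project_economy(make_params(wage=50_000.0))
        assert all(e.wage_base == 50_000.0 for e in econs)

    def test_one_year_growth(self):
        params = make_params(income=40_000.0,
                             growth=GrowthRates(resident_income=0.05, care_cost=0.0),
                             end=2020)
        (e,) = project_economy(params)
        assert e.resident_income_base == pytest.approx(42_000.0)

    def test_31_year_compounding_matches_closed_form(self):
        g = GrowthRates(wage=0.06, pension=0.05, resident_income=0.04, care_cost=0.07)
        params = make_params(growth=g)
        econs = project_economy(params)
        last = econs[-1]
        assert last.year == 2050
        assert last.wage_base == pytest.approx(50_000.0 * 1.06**31, rel=1e-9)
        assert last.care_cost == pytest.approx(10_000.0 * 1.07**31, rel=1e-9)

    def test_care_cost_growth_defaults_to_income_growth(self):
        g = GrowthRates(resident_income=0.05)  # care_cost left None
        params = make_params(growth=g, end=2020)
        (e,) = project_economy(params)
        assert e.care_cost == pytest.approx(10_000.0 * 1.05)


# ---------------------------------------------------------------------------
# flows


class TestFlows:
    def test_disabled_count_direct_product(self):
        pop = PopulationState(2020, 1_000_000, 0, 0)
        scheme = Scheme(0.001, 0.003, 0.8)
        assert severely_disabled_count(pop, scheme) == pytest.approx(3000.0)

    def test_disabled_count_zero_rate(self):
        pop = PopulationState(2020, 1_000_000, 0, 0)
        assert severely_disabled_count(pop, Scheme(0.001, 0.0, 0.8)) == 0.0

    def test_disabled_count_additive_over_groups(self):
        scheme = Scheme(0.001, 0.0025, 0.8)
        grouped = PopulationState(2020, 300_000, 200_000, 500_000)
        total = severely_disabled_count(grouped, scheme)
        parts = sum(severely_disabled_count(
            PopulationState(2020, *(n if i == j else 0 for j in range(3))), scheme)
            for i, n in enumerate([300_000, 200_000, 500_000]))
        assert total == pytest.approx(2500.0)
        assert total == pytest.approx(parts)

    def test_revenue_single_group(self):
        pop = PopulationState(2020, 100_000, 0, 0)
        econ = EconomicState(2020, 50_000, 1, 1, 1)
        rev = annual_revenue(pop, econ, Scheme(0.001, 0.003, 0.8))
        assert rev == pytest.approx(5_000_000.0)

    @given(scale=st.floats(0.1, 10.0))
    def test_revenue_linear_in_rate(self, scale):
        pop = PopulationState(2020, 100_000, 20_000, 500_000)
        econ = EconomicState(2020, 50_000, 30_000, 40_000, 10_000)
        r1 = annual_revenue(pop, econ, Scheme(0.0005, 0.003, 0.8))
        r2 = annual_revenue(pop, econ, Scheme(0.0005 * scale, 0.003, 0.8))
        assert r2 == pytest.approx(r1 * scale, rel=1e-12)

    def test_revenue_uses_schedule_multipliers(self):
        pop = PopulationState(2020, 100_000, 0, 0)
        econ = EconomicState(2020, 50_000, 1, 1, 1)
        sched = ContributionSchedule(employees=GroupContribution(1.0, 1.0, 0.5))
        rev = annual_revenue(pop, econ, Scheme(0.001, 0.003, 0.8), sched)
        assert rev == pytest.approx(5_000_000.0 * 2.5)

    def test_expenditure_direct_product(self):
        pop = PopulationState(2020, 1_000_000, 0, 0)
        econ = EconomicState(2020, 1, 1, 1, 30_000)
        exp = annual_expenditure(pop, econ, Scheme(0.001, 0.003, 0.8))
        assert exp == pytest.approx(72_000_000.0)

    def test_expenditure_zero_reimbursement(self):
        pop = PopulationState(2020, 1_000_000, 0, 0)
        econ = EconomicState(2020, 1, 1, 1, 30_000)
        assert annual_expenditure(pop, econ, Scheme(0.001, 0.003, 0.0)) == 0.0

    def test_expenditure_ratio_oracle(self):
        pop = PopulationState(2020, 1_000_000, 0, 0)
        econ = EconomicState(2020, 1, 1, 1, 30_000)
        e7 = annual_expenditure(pop, econ, Scheme(0.001, 0.003, 0.7))
        e9 = annual_expenditure(pop, econ, Scheme(0.001, 0.003, 0.9))
        assert e9 / e7 == pytest.approx(9.0 / 7.0, rel=1e-12)


class TestStepBalance:
    def test_accumulates(self):
        assert step_balance(100.0, 10.0, 4.0) == 106.0

    def test_deficit_preserved(self):
        assert step_balance(0.0, 0.0, 5.0) == -5.0

    def test_identity_flow(self):
        assert step_balance(123.4, 0.0, 0.0) == 123.4

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ConfigError):
            step_balance(bad, 0.0, 0.0)


# ---------------------------------------------------------------------------
# full simulation


def spreadsheet_simulate(params, scheme):
    """Independent brute-force recomputation: explicit per-year arithmetic
    with no shared code path beyond the parameter containers."""
    rows = []
    balance = params.initial_balance
    p0, e0, g = params.initial_population, params.initial_economy, params.growth
    for year in range(params.horizon[0], params.horizon[1] + 1):
        dt = year - params.base_year
        emp = p0.insured_employees * (1 + g.employees) ** dt
        ret = p0.insured_retirees * (1 + g.retirees) ** dt
        res = p0.insured_residents * (1 + g.residents) ** dt
        wage = e0.wage_base * (1 + g.wage) ** dt
        pens = e0.pension_base * (1 + g.pension) ** dt
        inc = e0.resident_income_base * (1 + g.resident_income) ** dt
        care = e0.care_cost * (1 + g.effective_care_cost) ** dt
        rate = scheme.individual_payment_rate
        sched = params.schedule
        rev = (emp * wage * rate * sched.employees.total
               + ret * pens * rate * sched.retirees.total
               + res * inc * rate * sched.residents.total)
        exp = (emp + ret + res) * scheme.severe_disability_rate \
            * care * scheme.reimbursement_ratio
        balance = balance + rev - exp
        rows.append((year, rev, exp, balance))
    return rows


class TestRunSimulation:
    def test_toy_world_hand_arithmetic(self, toy_params):
        scheme = Scheme(0.001, 0.0025, 0.8)
        traj = run_simulation(toy_params, scheme)
        assert traj.revenue[0] == pytest.approx(40e6)
        assert traj.expenditure[0] == pytest.approx(20e6)
        assert traj.balance[2] == pytest.approx(60e6)

    def test_zero_reimbursement_strictly_increasing(self, toy_params):
        traj = run_simulation(toy_params, Scheme(0.001, 0.0025, 0.0))
        assert np.all(np.diff(traj.balance) > 0)
        assert np.all(traj.balance > 0)

    def test_zero_flow_identity(self, toy_params):
        params = toy_params.replace(initial_balance=123.0)
        traj = run_simulation(params, Scheme(0.0, 0.0, 0.8))
        assert np.all(traj.balance == 123.0)

    @pytest.mark.parametrize("scheme", [
        Scheme(0.001, 0.0025, 0.8),
        Scheme(0.0008, 0.0035, 0.9),
    ])
    def test_matches_spreadsheet_oracle_exactly(self, scheme):
        params = make_params(employees=300_000, retirees=50_000, residents=600_000,
                             growth=GrowthRates(employees=0.01, retirees=0.02,
                                                residents=-0.005, wage=0.05,
                                                pension=0.04, resident_income=0.06,
                                                care_cost=0.07),
                             end=2024)  # 5-year toy
        traj = run_simulation(params, scheme)
        oracle = spreadsheet_simulate(params, scheme)
        for i, (year, rev, exp, bal) in enumerate(oracle):
            assert traj.years[i] == year
            assert traj.revenue[i] == rev
            assert traj.expenditure[i] == exp
            assert traj.balance[i] == pytest.approx(bal, rel=1e-15)

    def test_conservation(self, china_params):
        traj = run_simulation(china_params, Scheme(0.0009, 0.003, 0.85))
        lhs = traj.terminal_balance - china_params.initial_balance
        rhs = float(np.sum(traj.revenue - traj.expenditure))
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_deterministic(self, china_params):
        s = Scheme(0.0009, 0.003, 0.85)
        t1 = run_simulation(china_params, s)
        t2 = run_simulation(china_params, s)
        assert np.array_equal(t1.balance, t2.balance)

    def test_empty_horizon_rejected(self):
        with pytest.raises(ConfigError, match="horizon"):
            make_params(end=2019)


@pytest.fixture()
def model(china_params):
    return LTCIFundModel(china_params)


class TestMonotonicity:
    """Directional effects of the three knobs on the terminal balance."""

    def test_reimbursement_nonincreasing(self, model):
        terms = [model.simulate(Scheme(0.0009, 0.003, m)).terminal_balance
                 for m in np.linspace(0.5, 1.0, 6)]
        assert all(a >= b for a, b in zip(terms, terms[1:]))

    def test_payment_rate_nondecreasing(self, model):
        terms = [model.simulate(Scheme(r, 0.003, 0.8)).terminal_balance
                 for r in np.linspace(0.0005, 0.002, 6)]
        assert all(a <= b for a, b in zip(terms, terms[1:]))

    def test_disability_rate_nonincreasing(self, model):
        terms = [model.simulate(Scheme(0.0009, s, 0.8)).terminal_balance
                 for s in np.linspace(0.002, 0.005, 6)]
        assert all(a >= b for a, b in zip(terms, terms[1:]))


class TestTrajectoryDiagnostics:
    def test_peak_ties_break_late(self):
        from ltcifund.model import FundTrajectory
        years = np.arange(2020, 2025)
        bal = np.array([1.0, 3.0, 2.0, 3.0, 0.0])
        traj = FundTrajectory(years, np.zeros(5), np.zeros(5), bal,
                              Scheme(0.001, 0.003, 0.8))
        assert traj.peak_year == 2023
        assert traj.peak_value == 3.0

    def test_first_deficit_year(self):
        from ltcifund.model import FundTrajectory
        years = np.arange(2020, 2024)
        bal = np.array([1.0, -0.5, -2.0, 1.0])
        traj = FundTrajectory(years, np.zeros(4), np.zeros(4), bal,
                              Scheme(0.001, 0.003, 0.8))
        assert traj.first_deficit_year == 2021

    def test_summary_mentions_peak(self, toy_params):
        traj = run_simulation(toy_params, Scheme(0.001, 0.0025, 0.8))
        text = traj.summary()
        assert "peak balance" in text and "2050" in text
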