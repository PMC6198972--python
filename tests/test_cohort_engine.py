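"""Markov trace construction and cost/QALY accrual."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alkcea.cohort_engine import (
    accrue,
    discount_factor,
    evaluate_subcohort,
    pemetrexed_cycle_cost,
    run_trace,
)
from alkcea.decision_tree import Subcohort
from alkcea.parameters import PapPolicy
from alkcea.survival import WeibullCurve
from alkcea.synthetic_data import generate_parameter_bundle

NEGLIGIBLE = WeibullCurve(1e-12, 1.0, "cycle")   # essentially no progression
HALF_PER_CYCLE = WeibullCurve(np.log(2.0), 1.0, "cycle")  # p(progress) = 0.5


def enumerate_two_cycle_chain(p_prog, p_death):
    """Independent oracle: exhaustive path enumeration of the two-cycle
    chain in which progression and progressed-state death act on
    start-of-cycle occupancy (new progressors are first at risk of death in
    the following cycle)."""
    occ = {"pfs": 1.0, "pd": 0.0, "dead": 0.0}
    for _ in range(2):
        prog = occ["pfs"] * p_prog
        die = occ["pd"] * p_death
        occ = {"pfs": occ["pfs"] - prog,
               "pd": occ["pd"] + prog - die,
               "dead": occ["dead"] + die}
    return occ


class TestRunTrace:
    def test_no_transition_identity(self, defaults):
        trace = run_trace(NEGLIGIBLE, 0.0, defaults.run)
        assert np.allclose(trace.pfs, 1.0)
        assert np.allclose(trace.progressed, 0.0)
        assert np.allclose(trace.dead, 0.0)

    def test_two_cycle_chain_matches_path_enumeration(self, defaults):
        trace = run_trace(HALF_PER_CYCLE, 0.5, defaults.run)
        oracle = enumerate_two_cycle_chain(0.5, 0.5)
        assert oracle == {"pfs": 0.25, "pd": 0.5, "dead": 0.25}
        assert trace.pfs[2] == pytest.approx(oracle["pfs"])
        assert trace.progressed[2] == pytest.approx(oracle["pd"])
        assert trace.dead[2] == pytest.approx(oracle["dead"])

    def test_trace_length_on_21_day_grid(self, defaults):
        settings_21 = defaults.with_run(cycle_days=21.0).run
        trace = run_trace(NEGLIGIBLE, 0.1, settings_21)
        # floor(10 x 365.25 / 21) + 1 rows
        assert len(trace.cycle) == 174
        assert trace.n_cycles == 173

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_fuzzed_bundles_conserve_occupancy(self, seed):
        bundle = generate_parameter_bundle(seed).with_run(horizon_years=3.0)
        for role in ("crizotinib", "chemo", "supportive"):
            sub = Subcohort("TP" if role != "chemo" else "TN",
                            1.0, "crizotinib" if role != "chemo" else "chemo",
                            role)
            trace = run_trace(
                bundle.pfs_crizotinib if role == "crizotinib"
                else bundle.pfs_chemo,
                bundle["p_death_progressed_per_cycle"], bundle.run)
            total = trace.pfs + trace.progressed + trace.dead
            assert np.max(np.abs(total - 1.0)) < 1e-9
            assert np.all(np.diff(trace.dead) >= -1e-12)
            assert np.all(np.diff(trace.pfs) <= 1e-12)
            acc = accrue(trace, sub.treatment, bundle)
            assert acc.cost >= 0 and acc.qalys >= 0
            assert acc.pf_ly <= acc.overall_ly + 1e-12


class TestDiscounting:
    @pytest.mark.parametrize("t, rate, expected", [
        (0.0, 0.05, 1.0),
        (1.0, 0.0, 1.0),
        (1.0, 0.05, 0.9524),
        (10.0, 0.05, 0.6139),
    ])
    def test_values(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected, abs=5e-5)

    def test_zero_discount_never_decreases_accruals(self, defaults):
        sub = Subcohort("untested", 1.0, "chemo", "chemo")
        base = evaluate_subcohort(sub, defaults)
        undiscounted = evaluate_subcohort(
            sub, defaults.with_values({"annual_discount": 0.0}))
        for field in ("cost", "qalys", "pf_ly", "overall_ly"):
            assert getattr(undiscounted, field) >= getattr(base, field)

    def test_discounted_bounded_by_undiscounted(self, defaults):
        acc = evaluate_subcohort(
            Subcohort("untested", 1.0, "chemo", "chemo"), defaults)
        assert acc.cost <= acc.undiscounted_cost
        assert acc.qalys <= acc.undiscounted_qalys
        assert acc.pf_ly <= acc.undiscounted_pf_ly
        assert acc.overall_ly <= acc.undiscounted_overall_ly


class TestAccrual:
    def test_qaly_identity_without_discounting(self, defaults):
        """Utilities (1, 0), no progression, no discounting: QALYs equal
        time spent progression-free, exactly."""
        bundle = defaults.with_values(
            {"annual_discount": 0.0, "u_pfs": 1.0, "u_progressed": 0.0})
        trace = run_trace(NEGLIGIBLE, 0.0, bundle.run)
        acc = accrue(trace, "chemo", bundle)
        expected_years = bundle.run.n_cycles * bundle.run.cycle_years
        assert acc.qalys == pytest.approx(expected_years, rel=1e-9)
        assert acc.pf_ly == pytest.approx(expected_years, rel=1e-9)

    def test_crizotinib_cost_closed_form(self, defaults):
        """Full-price crizotinib for a cohort that never progresses equals
        price/day x cycle days x sum of per-cycle discount factors (plus
        follow-up), checked against an independently coded sum."""
        bundle = defaults.with_run(
            horizon_years=10 * 21.0 / 365.25, cycle_days=21.0,
            pap=PapPolicy(enabled=False, paid_days=0))
        assert bundle.run.n_cycles == 10
        trace = run_trace(NEGLIGIBLE, 0.0, bundle.run)
        acc = accrue(trace, "crizotinib", bundle)
        cyr = 21.0 / 365.25
        factors = [(1.05) ** (-k * cyr) for k in range(10)]
        expected = (238.1 * 21.0 + 55.6) * sum(factors)
        assert acc.cost == pytest.approx(expected, rel=1e-9)

    def test_pap_limits_drug_cost_to_paid_window(self, defaults):
        bundle = defaults.with_run(
            horizon_years=10 * 21.0 / 365.25, cycle_days=21.0,
            pap=PapPolicy(enabled=True, paid_days=30))
        trace = run_trace(NEGLIGIBLE, 0.0, bundle.run)
        acc = accrue(trace, "crizotinib", bundle)
        cyr = 21.0 / 365.25
        # 21 days in cycle 0, 9 days in cycle 1, 0 after
        drug = 238.1 * (21.0 + 9.0 * 1.05 ** (-cyr))
        followup = 55.6 * sum((1.05) ** (-k * cyr) for k in range(10))
        assert acc.cost == pytest.approx(drug + followup, rel=1e-9)

    @pytest.mark.parametrize("whole_vials, expected", [
        (True, 2 * 2083.97),          # 860 mg -> two 500-mg vials
        (False, 860.0 / 500.0 * 2083.97),
    ])
    def test_pemetrexed_billing(self, whole_vials, expected):
        assert pemetrexed_cycle_cost(2083.97, 1.72, whole_vials) == \
            pytest.approx(expected)

    def test_pf_ly_matches_summation_oracle(self, defaults):
        bundle = defaults.with_run(horizon_years=3.0)
        trace = run_trace(bundle.pfs_chemo,
                          bundle["p_death_progressed_per_cycle"], bundle.run)
        acc = accrue(trace, "chemo", bundle)
        # independent summation over the trace rows
        cyr = bundle.run.cycle_years
        expected = sum(
            occ * cyr * (1.0 + bundle.discount) ** (-k * cyr)
            for k, occ in enumerate(trace.pfs[:-1]))
        assert acc.pf_ly == pytest.approx(expected, rel=1e-12)

    def test_life_year_additivity(self, defaults):
        bundle = defaults.with_run(horizon_years=3.0)
        trace = run_trace(bundle.pfs_chemo,
                          bundle["p_death_progressed_per_cycle"], bundle.run)
        acc = accrue(trace, "chemo", bundle)
        cyr = bundle.run.cycle_years
        pd_ly = sum(
            occ * cyr * (1.0 + bundle.discount) ** (-k * cyr)
            for k, occ in enumerate(trace.progressed[:-1]))
        assert acc.overall_ly == pytest.approx(acc.pf_ly + pd_ly, rel=1e-12)

    def test_half_cycle_correction_runs_and_reduces_pf_ly(self, defaults):
        sub = Subcohort("untested", 1.0, "chemo", "chemo")
        plain = evaluate_subcohort(sub, defaults)
        hcc = evaluate_subcohort(sub, defaults.with_run(
            half_cycle_correction=True))
        # occupancy declines, so mid-cycle averaging can only lower PF time
        assert hcc.pf_ly <= plain.pf_ly

    def test_terminal_cost_counted_once_per_death(self, defaults):
        """With all recurring costs zeroed, total cost equals the palliative
        terminal cost times the discounted number of deaths."""
        zeroed = {name: 0.0 for name in (
            "pemetrexed_per_500mg", "chemo_other_per_cycle",
            "crizotinib_per_day", "followup_per_cycle", "salvage_per_cycle",
            "supportive_per_cycle", "sae_initial_chemo_per_cycle")}
        bundle = defaults.with_values(
            {**zeroed, "annual_discount": 0.0}).with_run(horizon_years=3.0)
        trace = run_trace(bundle.pfs_chemo,
                          bundle["p_death_progressed_per_cycle"], bundle.run)
        acc = accrue(trace, "chemo", bundle)
        assert acc.cost == pytest.approx(
            2042.91 * trace.dead[-1], rel=1e-12)
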