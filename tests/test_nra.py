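"""MILP strain design: construction, optimality, enumeration, ranking.

The independent oracle enumerates every signed (enzyme, direction) support
up to the intervention budget and solves one LP per support via
scipy.linprog with an explicitly split (one-sided) constraint system — a
different formulation path from the MILP under test.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import linprog

from strainkit.mca import ControlCoefficients, control_coefficients
from strainkit.nra import (
    NRABounds,
    NRAInfeasibleError,
    build_nra_problem,
    designable_enzymes,
    enumerate_designs,
    evaluate_design_across_models,
    rank_designs,
    solve_nra,
)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def support_lp(problem, support, epsilon=1e-6):
    """Max objective for one signed support via linprog; None if infeasible."""
    b = problem.bounds
    nd = problem.nd
    lb = np.zeros(2 * nd)
    ub = np.zeros(2 * nd)
    for j, e in enumerate(problem.designable):
        if (e, "up") in support:
            lb[j], ub[j] = epsilon, math.log(b.up_fold)
        if (e, "down") in support:
            lb[nd + j], ub[nd + j] = epsilon, math.log(b.down_fold)
    R, rlo, rhi = problem._response_rows()
    A = np.hstack([R, -R])
    rows, rhs = [], []
    for i in range(A.shape[0]):
        if np.isfinite(rhi[i]):
            rows.append(A[i]); rhs.append(rhi[i])
        if np.isfinite(rlo[i]):
            rows.append(-A[i]); rhs.append(-rlo[i])
    w = problem.objective_vector()
    res = linprog(
        c=np.concatenate([-w, w]),
        A_ub=np.array(rows), b_ub=np.array(rhs),
        bounds=list(zip(lb, ub)), method="highs",
    )
    return -res.fun if res.success else None


def brute_force_census(problem, max_interventions=None):
    """Objective value of every feasible signed support within the budget."""
    if max_interventions is None:
        max_interventions = problem.bounds.max_interventions
    census = {}
    enzymes = problem.designable
    for k in range(0, max_interventions + 1):
        for combo in itertools.combinations(enzymes, k):
            for dirs in itertools.product(("up", "down"), repeat=k):
                support = frozenset(zip(combo, dirs))
                val = support_lp(problem, support)
                if val is not None:
                    census[support] = val
    return census


@pytest.fixture(scope="module")
def fb_problems(feedback_bundle, feedback_models):
    designable = designable_enzymes(feedback_bundle.network)
    problems = []
    for m in feedback_models:
        cc = control_coefficients(m)
        problems.append(
            build_nra_problem(
                cc, NRABounds(), growth_id="biomass",
                designable=designable, model_id=m.model_id,
            )
        )
    return problems


class TestBuild:
    def test_response_rows_encode_concentration_bounds(self, fb_problems):
        prob = fb_problems[0]
        R, lo, hi = prob._response_rows()
        n_species = prob.cc.C_x.shape[0]
        assert np.allclose(lo[:n_species], -math.log(3.0))
        assert np.allclose(hi[:n_species], math.log(3.0))
        # growth row: at most 20% reduction
        assert lo[n_species] == pytest.approx(math.log(0.8))

    def test_activity_bounds(self):
        with pytest.raises(ValueError):
            NRABounds(up_fold=1.0)
        with pytest.raises(ValueError):
            NRABounds(growth_drop_max=1.0)

    def test_zero_interventions_gives_null_design(self, feedback_models):
        cc = control_coefficients(feedback_models[0])
        prob = build_nra_problem(
            cc, NRABounds(max_interventions=0), growth_id="biomass"
        )
        d = solve_nra(prob)
        assert d.interventions == ()
        assert d.predicted_objective == pytest.approx(0.0, abs=1e-9)

    def test_unknown_designable_enzyme_rejected(self, feedback_models):
        cc = control_coefficients(feedback_models[0])
        with pytest.raises(ValueError, match="not in model"):
            build_nra_problem(cc, NRABounds(), growth_id="biomass",
                              designable=["nope"])


class TestOptimality:
    def test_milp_matches_brute_force_optimum(self, fb_problems):
        for prob in fb_problems[:5]:
            census = brute_force_census(prob)
            best = max(census.values())
            d = solve_nra(prob)
            assert d.predicted_objective == pytest.approx(best, abs=1e-6)

    def test_growth_conflict_yields_null_design(self):
        """Single useful enzyme whose growth coefficient is negative, with
        no growth reduction allowed: the optimum is no intervention."""
        cc = ControlCoefficients(
            C_v=np.array([[1.0], [0.0], [-0.5]]),  # product, uptake, growth
            C_x=np.zeros((0, 1)),
            C_yield=np.array([1.0]),
            reaction_ids=["prod", "upt", "growth"],
            species_ids=[],
            enzyme_ids=["e1"],
            product_id="prod",
            substrate_id="upt",
        )
        prob = build_nra_problem(
            cc, NRABounds(growth_drop_max=0.0), growth_id="growth",
            designable=["e1"],
        )
        d = solve_nra(prob)
        assert d.predicted_objective == pytest.approx(0.0, abs=1e-5)

    def test_objective_monotone_in_conc_fold(self, feedback_models):
        cc = control_coefficients(feedback_models[0])
        vals = []
        for cf in (2.0, 3.0, 20.0):
            prob = build_nra_problem(
                cc, NRABounds(conc_fold=cf), growth_id="biomass"
            )
            vals.append(solve_nra(prob).predicted_objective)
        assert vals[0] <= vals[1] + 1e-9 <= vals[2] + 2e-9

    def test_objective_monotone_in_budget(self, feedback_models):
        cc = control_coefficients(feedback_models[0])
        vals = []
        for k in (1, 2, 3):
            prob = build_nra_problem(
                cc, NRABounds(max_interventions=k), growth_id="biomass"
            )
            vals.append(solve_nra(prob).predicted_objective)
        assert vals[0] <= vals[1] + 1e-9 <= vals[2] + 2e-9

    def test_fold_changes_within_bounds(self, fb_problems):
        for prob in fb_problems[:5]:
            d = solve_nra(prob)
            for e, direction, fold in d.interventions:
                cap = prob.bounds.up_fold if direction == "up" else prob.bounds.down_fold
                assert 1.0 <= fold <= cap * (1 + 1e-9)


class TestEnumeration:
    def test_census_equivalence(self, fb_problems):
        """Enumerated memberships exactly match the brute-force set of
        supports within 5% of the optimum."""
        prob = fb_problems[0]
        census = brute_force_census(prob, max_interventions=2)
        import dataclasses

        prob2 = dataclasses.replace(
            prob, bounds=NRABounds(max_interventions=2), _cuts=[]
        )
        enum = enumerate_designs(prob2, tolerance=0.05, max_designs=500)
        best = max(census.values())
        expected = {
            s for s, v in census.items() if v >= (1 - 0.05) * best - 1e-9 and s
        }
        got = set(enum.unique_by_membership)
        assert got == expected

    def test_every_design_within_tolerance(self, fb_problems):
        enum = enumerate_designs(fb_problems[1], tolerance=0.05, max_designs=30)
        for d in enum.designs:
            assert d.predicted_objective >= (1 - 0.05) * enum.optimum - 1e-9

    def test_designs_recheck_against_constraints(self, fb_problems):
        """No cut leakage: every enumerated design re-validates post hoc."""
        prob = fb_problems[1]
        enum = enumerate_designs(prob, tolerance=0.05, max_designs=15)
        for d in enum.designs:
            val = support_lp(prob, d.membership)
            assert val is not None
            assert val == pytest.approx(d.predicted_objective, abs=1e-6)

    def test_zero_tolerance_keeps_only_optimal_supports(self, fb_problems):
        prob = fb_problems[2]
        enum = enumerate_designs(prob, tolerance=0.0, max_designs=50)
        for d in enum.designs:
            assert d.predicted_objective == pytest.approx(enum.optimum, abs=1e-6)

    def test_max_designs_one_gives_singleton(self, fb_problems):
        enum = enumerate_designs(fb_problems[0], max_designs=1)
        assert len(enum.designs) == 1


class TestCrossModelEvaluation:
    def test_optimal_support_recovers_unrestricted_optimum(self, fb_problems):
        prob = fb_problems[0]
        d = solve_nra(prob)
        values, mean, feas = evaluate_design_across_models(d.membership, [prob])
        assert values[0] == pytest.approx(d.predicted_objective, abs=1e-6)

    def test_empty_membership_scores_zero(self, fb_problems):
        values, mean, _ = evaluate_design_across_models(frozenset(), fb_problems[:3])
        assert np.allclose(values, 0.0, atol=1e-9)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_ranking_matches_brute_force_sweep(self, fb_problems):
        problems = fb_problems[:5]
        enums = [enumerate_designs(p, max_designs=5) for p in problems]
        ranked = rank_designs(enums, problems, top_k=5)
        # independent recomputation of the mean score per membership
        for rec in ranked:
            vals = [support_lp(p, rec["membership"]) for p in problems]
            vals = [v for v in vals if v is not None]
            assert rec["mean_objective"] == pytest.approx(
                float(np.mean(vals)), abs=1e-6
            )
        means = [r["mean_objective"] for r in ranked]
        assert means == sorted(means, reverse=True)

    def test_ranking_invariant_to_model_order(self, fb_problems):
        problems = fb_problems[:4]
        enums = [enumerate_designs(p, max_designs=4) for p in problems]
        a = rank_designs(enums, problems, top_k=3)
        perm = [2, 0, 3, 1]
        b = rank_designs([enums[i] for i in perm], [problems[i] for i in perm],
                         top_k=3)
        assert [r["membership"] for r in a] == [r["membership"] for r in b]

    def test_single_design_single_model(self, fb_problems):
        prob = fb_problems[3]
        enum = enumerate_designs(prob, max_designs=1)
        ranked = rank_designs([enum], [prob], top_k=5)
        assert ranked[0]["membership"] == enum.designs[0].membership
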