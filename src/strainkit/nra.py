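"""Network Response Analysis: MILP strain design over control coefficients.

The design problem picks up to ``max_interventions`` enzymes and log
activity changes (up to ``ln(up_fold)`` up, ``ln(down_fold)`` down) that
maximise the log yield increase of a product flux over the substrate uptake,

    max  (C_v[product] - C_v[uptake]) . (u - d)

subject to log-linear response bounds that keep the engineered strain close
to the reference phenotype: every internal metabolite concentration within
``conc_fold`` of its reference, the growth flux within ``growth_drop_max``
of the reference, and (optionally) every flux within ``flux_fold``.
Near-optimal alternatives are enumerated with integer cuts on the signed
(enzyme, direction) support, and design sets are ranked across a model
ensemble by their mean predicted objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .mca import ControlCoefficients

__all__ = [
    "NRABounds",
    "NRAProblem",
    "InterventionDesign",
    "DesignEnumeration",
    "NRAInfeasibleError",
    "REFERENCE_PRESET",
    "RELAXED_ACTIVITY_PRESET",
    "build_nra_problem",
    "solve_nra",
    "enumerate_designs",
    "evaluate_design_across_models",
    "rank_designs",
]


class NRAInfeasibleError(RuntimeError):
    pass


def designable_enzymes(net) -> list[str]:
    """Default intervention targets: enzymatic steps only (no transports,
    exchanges, or the biomass lump)."""
    return [
        r.id
        for r in net.reactions
        if not (r.is_transport or r.is_exchange or r.id == net.biomass_reaction)
    ]


@dataclass(frozen=True)
class NRABounds:
    """Phenotype-proximity and intervention bounds (all folds > 1)."""

    conc_fold: float = 3.0
    up_fold: float = 5.0
    down_fold: float = 100.0  # finite stand-in for unrestricted downregulation
    max_interventions: int = 3
    growth_drop_max: float = 0.2
    flux_fold: float | None = None

    def __post_init__(self) -> None:
        for name in ("conc_fold", "up_fold", "down_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        if self.flux_fold is not None and self.flux_fold <= 1:
            raise ValueError("flux_fold must exceed 1")
        if self.max_interventions < 0:
            raise ValueError("max_interventions must be >= 0")
        if not (0 <= self.growth_drop_max < 1):
            raise ValueError("growth_drop_max must be in [0, 1)")


#: bounds used for the reference study: 3-fold concentrations, 5-fold up,
#: unrestricted down, <=3 interventions, <=20% growth reduction
REFERENCE_PRESET = NRABounds()

#: second-study preset: 10-fold activity changes compensated by tighter
#: (2.5-fold) concentration proximity
RELAXED_ACTIVITY_PRESET = NRABounds(conc_fold=2.5, up_fold=10.0)


@dataclass(frozen=True)
class InterventionDesign:
    """A set of (enzyme, direction, fold >= 1) with its predicted log-yield
    objective.  ``membership`` is the signed support identifying the design."""

    interventions: tuple[tuple[str, str, float], ...]
    predicted_objective: float
    source_model: str = ""

    @property
    def membership(self) -> frozenset[tuple[str, str]]:
        return frozenset((e, direction) for e, direction, _ in self.interventions)

    @property
    def yield_increase_percent(self) -> float:
        return (math.exp(self.predicted_objective) - 1.0) * 100.0


@dataclass
class DesignEnumeration:
    designs: list[InterventionDesign]
    optimum: float
    tolerance: float
    complete: bool = True

    @property
    def unique_by_membership(self) -> list[frozenset[tuple[str, str]]]:
        seen, out = set(), []
        for d in self.designs:
            if d.membership not in seen:
                seen.add(d.membership)
                out.append(d.membership)
        return out


@dataclass
class NRAProblem:
    cc: ControlCoefficients
    bounds: NRABounds
    growth_id: str
    designable: list[str]
    epsilon_membership: float = 1e-6
    model_id: str = ""
    _cuts: list[set[tuple[str, str]]] = field(default_factory=list)

    # variable layout: [u (nd), d (nd), bu (nd), bd (nd)]
    @property
    def nd(self) -> int:
        return len(self.designable)

    def _col(self, kind: str, j: int) -> int:
        base = {"u": 0, "d": 1, "bu": 2, "bd": 3}[kind]
        return base * self.nd + j

    def _response_rows(self):
        """(matrix over u,d part, lower, upper) for conc/growth/flux bounds."""
        cc, b = self.cc, self.bounds
        cols = [cc.enzyme_ids.index(e) for e in self.designable]
        rows, lo, hi = [], [], []
        ln_cf = math.log(b.conc_fold)
        for i in range(cc.C_x.shape[0]):
            coef = cc.C_x[i, cols]
            rows.append(coef)
            lo.append(-ln_cf)
            hi.append(ln_cf)
        g = cc.C_v[cc.reaction_ids.index(self.growth_id), cols]
        rows.append(g)
        lo.append(math.log(1.0 - b.growth_drop_max))
        hi.append(np.inf)
        if b.flux_fold is not None:
            ln_ff = math.log(b.flux_fold)
            for k in range(cc.C_v.shape[0]):
                rows.append(cc.C_v[k, cols])
                lo.append(-ln_ff)
                hi.append(ln_ff)
        return np.array(rows), np.array(lo), np.array(hi)

    def objective_vector(self) -> np.ndarray:
        cc = self.cc
        cols = [cc.enzyme_ids.index(e) for e in self.designable]
        i_p = cc.reaction_ids.index(cc.product_id)
        i_s = cc.reaction_ids.index(cc.substrate_id)
        return cc.C_v[i_p, cols] - cc.C_v[i_s, cols]

    def add_membership_cut(self, membership: frozenset[tuple[str, str]]) -> None:
        self._cuts.append(set(membership))

    def clear_cuts(self) -> None:
        self._cuts = []


def build_nra_problem(
    cc: ControlCoefficients,
    bounds: NRABounds,
    growth_id: str,
    designable: list[str] | None = None,
    exclude: set[str] | None = None,
    epsilon_membership: float = 1e-6,
    model_id: str = "",
) -> NRAProblem:
    """Assemble a solver-ready NRA problem from control coefficients.

    ``designable`` defaults to every enzyme except the growth lump; pass
    ``exclude`` to additionally remove e.g. exchange steps from contention.
    """
    exclude = set(exclude or ())
    exclude.add(growth_id)
    if designable is None:
        designable = [e for e in cc.enzyme_ids if e not in exclude]
    else:
        missing = [e for e in designable if e not in cc.enzyme_ids]
        if missing:
            raise ValueError(f"designable enzymes not in model: {missing}")
    return NRAProblem(
        cc=cc,
        bounds=bounds,
        growth_id=growth_id,
        designable=list(designable),
        epsilon_membership=epsilon_membership,
        model_id=model_id,
    )


def _solve_milp(problem: NRAProblem):
    nd = problem.nd
    b = problem.bounds
    nvar = 4 * nd
    ln_up, ln_dn = math.log(b.up_fold), math.log(b.down_fold)
    eps = problem.epsilon_membership

    lb = np.zeros(nvar)
    ub = np.concatenate(
        [np.full(nd, ln_up), np.full(nd, ln_dn), np.ones(nd), np.ones(nd)]
    )
    integrality = np.concatenate([np.zeros(2 * nd), np.ones(2 * nd)])

    rows, lo, hi = [], [], []

    def add(coeffs: dict[int, float], l: float, h: float) -> None:
        rows.append(coeffs)
        lo.append(l)
        hi.append(h)

    for j in range(nd):
        add({problem._col("u", j): 1.0, problem._col("bu", j): -ln_up}, -np.inf, 0.0)
        add({problem._col("d", j): 1.0, problem._col("bd", j): -ln_dn}, -np.inf, 0.0)
        add({problem._col("u", j): 1.0, problem._col("bu", j): -eps}, 0.0, np.inf)
        add({problem._col("d", j): 1.0, problem._col("bd", j): -eps}, 0.0, np.inf)
        add({problem._col("bu", j): 1.0, problem._col("bd", j): 1.0}, -np.inf, 1.0)
    add(
        {problem._col("bu", j): 1.0 for j in range(nd)}
        | {problem._col("bd", j): 1.0 for j in range(nd)},
        -np.inf,
        float(b.max_interventions),
    )
    R, rlo, rhi = problem._response_rows()
    for row, l, h in zip(R, rlo, rhi):
        coeffs = {}
        for j, c in enumerate(row):
            if c != 0.0:
                coeffs[problem._col("u", j)] = c
                coeffs[problem._col("d", j)] = -c
        add(coeffs, l, h)
    # integer cuts excluding previously found signed supports exactly
    name_to_j = {e: j for j, e in enumerate(problem.designable)}
    for cut in problem._cuts:
        coeffs = {}
        for e, direction in cut:
            j = name_to_j[e]
            coeffs[problem._col("bu" if direction == "up" else "bd", j)] = 1.0
        for j in range(nd):
            for kind, direction in (("bu", "up"), ("bd", "down")):
                if (problem.designable[j], direction) not in cut:
                    coeffs[problem._col(kind, j)] = coeffs.get(problem._col(kind, j), 0.0) - 1.0
        add(coeffs, -np.inf, float(len(cut) - 1))

    data, ri, ci = [], [], []
    for k, coeffs in enumerate(rows):
        for j, c in coeffs.items():
            ri.append(k)
            ci.append(j)
            data.append(c)
    A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), nvar))

    cobj = np.zeros(nvar)
    w = problem.objective_vector()
    cobj[:nd] = -w
    cobj[nd : 2 * nd] = w
    res = milp(
        c=cobj,
        constraints=[LinearConstraint(A, np.array(lo), np.array(hi))],
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": 1e-9},
    )
    return res


def _design_from_solution(problem: NRAProblem, x: np.ndarray, value: float, model_id: str):
    nd = problem.nd
    interventions = []
    for j, e in enumerate(problem.designable):
        if x[problem._col("bu", j)] > 0.5:
            interventions.append((e, "up", float(math.exp(x[problem._col("u", j)]))))
        elif x[problem._col("bd", j)] > 0.5:
            interventions.append((e, "down", float(math.exp(x[problem._col("d", j)]))))
    interventions.sort(key=lambda t: t[0])
    return InterventionDesign(
        interventions=tuple(interventions),
        predicted_objective=float(value),
        source_model=model_id or problem.model_id,
    )


def solve_nra(problem: NRAProblem) -> InterventionDesign:
    """Solve the design MILP; the optimum is the maximal log yield increase."""
    res = _solve_milp(problem)
    if not res.success:
        raise NRAInfeasibleError(
            "NRA MILP infeasible; binding constraint families: concentration "
            "proximity, growth floor, activity bounds, intervention budget"
        )
    return _design_from_solution(problem, res.x, -res.fun, problem.model_id)


def enumerate_designs(
    problem: NRAProblem,
    tolerance: float = 0.05,
    max_designs: int = 100,
) -> DesignEnumeration:
    """All signed-support designs within ``tolerance`` of the optimum,
    found by iterating integer cuts on each discovered support."""
    problem.clear_cuts()
    best = solve_nra(problem)
    designs = [best]
    optimum = best.predicted_objective
    threshold = (1.0 - tolerance) * optimum - 1e-9
    complete = True
    while len(designs) < max_designs:
        problem.add_membership_cut(designs[-1].membership)
        try:
            nxt = solve_nra(problem)
        except NRAInfeasibleError:
            break
        if nxt.predicted_objective < threshold:
            break
        designs.append(nxt)
    else:
        complete = False
    problem.clear_cuts()
    return DesignEnumeration(
        designs=designs, optimum=optimum, tolerance=tolerance, complete=complete
    )


def evaluate_design_across_models(
    membership: frozenset[tuple[str, str]],
    problems: list[NRAProblem],
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, float, list[bool]]:
    """Fix a design's signed support in every problem, maximise the
    objective per model, and return (objectives, mean, feasibility flags).

    Non-member activity changes are fixed at zero; members must move at
    least ``epsilon`` in log space in their assigned direction.  Infeasible
    models are flagged and excluded from the mean.
    """
    values = np.full(len(problems), -np.inf)
    feasible = []
    for i, problem in enumerate(problems):
        b = problem.bounds
        nd = problem.nd
        missing = [e for e, _ in membership if e not in problem.designable]
        if missing:
            raise ValueError(f"membership enzymes absent from problem: {missing}")
        lb = np.zeros(2 * nd)
        ub = np.zeros(2 * nd)
        for j, e in enumerate(problem.designable):
            if (e, "up") in membership:
                lb[j], ub[j] = epsilon, math.log(b.up_fold)
            if (e, "down") in membership:
                lb[nd + j], ub[nd + j] = epsilon, math.log(b.down_fold)
        R, rlo, rhi = problem._response_rows()
        A = np.hstack([R, -R])
        w = problem.objective_vector()
        # two-sided rows: solve as a continuous MILP (HiGHS LP under the hood)
        res = milp(
            c=np.concatenate([-w, w]),
            constraints=[LinearConstraint(A, rlo, rhi)],
            integrality=np.zeros(2 * nd),
            bounds=Bounds(lb, ub),
        )
        if res.success:
            values[i] = -res.fun
            feasible.append(True)
        else:
            feasible.append(False)
    ok = np.isfinite(values)
    mean = float(values[ok].mean()) if ok.any() else -np.inf
    return values, mean, feasible


def rank_designs(
    enumerations: list[DesignEnumeration],
    problems: list[NRAProblem],
    top_k: int = 5,
    epsilon: float = 1e-6,
) -> list[dict]:
    """Deduplicate designs by signed membership, score each by its mean
    cross-model objective, and return the ``top_k`` (deterministic
    lexicographic tie-break)."""
    seen: dict[frozenset, None] = {}
    for enum in enumerations:
        for mem in enum.unique_by_membership:
            seen.setdefault(mem, None)
    scored = []
    for mem in seen:
        values, mean, feas = evaluate_design_across_models(mem, problems, epsilon)
        scored.append(
            {
                "membership": mem,
                "mean_objective": mean,
                "per_model": values,
                "feasible": feas,
            }
        )
    scored.sort(
        key=lambda rec: (
            -rec["mean_objective"],
            tuple(sorted(rec["membership"])),
        )
    )
    return scored[:top_k]
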