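"""Thermodynamics-based steady-state sampling (TFA).

Couples mass balance (N v = 0), flux bounds, metabolite concentration bounds,
and the second law of thermodynamics: a reaction may only carry flux in the
direction of negative transformed Gibbs energy,

    dG' = dG'0 + RT * sum_i n_i ln x_i,    sign(v) * dG' < 0.

The coupling is encoded with one binary direction variable per reaction that
has a standard Gibbs energy, using per-reaction big-M constants derived from
the flux and concentration bounds.  Steady-state profiles are drawn by
optimising random objective directions over the feasible polytope restricted
to near-maximal growth, which yields reproducible vertex samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "ThermoData",
    "SteadyStateProfile",
    "TFAProblem",
    "InfeasibleProblemError",
    "max_growth",
    "sample_steady_states",
    "validate_profile",
    "profile_to_csv",
    "profile_from_csv",
]

#: RT in kcal/mol at 298.15 K
RT_DEFAULT = 0.5925

#: default physiological concentration envelope, mol/L
CONC_BOUNDS_DEFAULT = (1e-8, 0.1)

#: minimum |dG'| (kcal/mol) imposed on every thermo-active reaction: the
#: thermodynamic resolution of the sampler.  Besides making the strict
#: second-law inequality MILP-representable, it bounds the log-linear
#: elasticities (~RT/|dG'|) of near-equilibrium reactions and with it the
#: conditioning of the control-coefficient system.
EPS_DISPLACEMENT = 1e-3


class InfeasibleProblemError(RuntimeError):
    """Raised when the TFA problem has no feasible point; carries a hint
    about which constraint families are in play."""


@dataclass
class ThermoData:
    """Gibbs energies and concentration bounds.

    ``dG0`` maps reaction id -> standard transformed Gibbs energy (kcal/mol);
    reactions absent from ``dG0`` (e.g. the biomass lump) carry no
    thermodynamic constraint.  ``displacement_floor`` maps reaction id ->
    minimum |dG'| in kcal/mol (the paper-style push away from equilibrium).
    """

    dG0: dict[str, float]
    conc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    RT: float = RT_DEFAULT
    displacement_floor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError("RT must be positive")
        for m, (lo, hi) in self.conc_bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bad concentration bounds for {m!r}: ({lo}, {hi})")

    def bounds_for(self, mid: str) -> tuple[float, float]:
        return self.conc_bounds.get(mid, CONC_BOUNDS_DEFAULT)

    def keq(self, rid: str) -> float:
        return float(np.exp(-self.dG0[rid] / self.RT))


@dataclass
class SteadyStateProfile:
    """One TFA sample: fluxes (mmol/gDW/h), ln-concentrations (ln mol/L),
    transformed Gibbs energies (kcal/mol), and the growth rate (1/h)."""

    fluxes: dict[str, float]
    ln_conc: dict[str, float]
    dG: dict[str, float]
    growth_rate: float

    def displacement(self, rid: str, RT: float = RT_DEFAULT) -> float:
        """Thermodynamic displacement Gamma = exp(dG'/RT); 1 at equilibrium."""
        return float(np.exp(self.dG[rid] / RT))


class TFAProblem:
    """Mixed-integer encoding of the thermodynamic flux sampling polytope.

    Variable layout: ``[v (n_rxn), ln x (n_met), dG (n_thermo), z (n_thermo)]``
    with z the binary forward-direction indicator of each thermo-active
    reaction (z=1: v >= 0 and dG' <= -floor; z=0: v <= 0 and dG' >= floor).
    """

    def __init__(
        self,
        net: MetabolicNetwork,
        thermo: ThermoData,
        flux_bounds: dict[str, tuple[float, float]],
        big_m_factor: float = 1.1,
    ):
        self.net = net
        self.thermo = thermo
        self.flux_bounds = dict(flux_bounds)
        self.big_m_factor = big_m_factor
        self._floors = dict(thermo.displacement_floor)
        self._growth_min: float | None = None
        self._build()

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        net, thermo = self.net, self.thermo
        self.rxn_ids = net.reaction_ids
        self.met_ids = net.metabolite_ids
        self.thermo_rxns = [r for r in self.rxn_ids if r in thermo.dG0]
        nr, nm, nt = len(self.rxn_ids), len(self.met_ids), len(self.thermo_rxns)
        self.nr, self.nm, self.nt = nr, nm, nt
        self.n_var = nr + nm + 2 * nt
        self._i_v = {r: j for j, r in enumerate(self.rxn_ids)}
        self._i_x = {m: nr + i for i, m in enumerate(self.met_ids)}
        self._i_g = {r: nr + nm + k for k, r in enumerate(self.thermo_rxns)}
        self._i_z = {r: nr + nm + nt + k for k, r in enumerate(self.thermo_rxns)}

        lb = np.empty(self.n_var)
        ub = np.empty(self.n_var)
        for r in self.rxn_ids:
            dflt = (-100.0, 100.0) if net.reaction(r).reversible else (0.0, 100.0)
            lo, hi = self.flux_bounds.get(r, dflt)
            lb[self._i_v[r]], ub[self._i_v[r]] = lo, hi
        for m in self.met_ids:
            clo, chi = thermo.bounds_for(m)
            lb[self._i_x[m]], ub[self._i_x[m]] = np.log(clo), np.log(chi)
        # dG bounds implied by dG0 and concentration bounds (with slack)
        for r in self.thermo_rxns:
            g0 = thermo.dG0[r]
            span = sum(
                abs(c)
                * thermo.RT
                * max(abs(lb[self._i_x[m]]), abs(ub[self._i_x[m]]))
                for m, c in net.reaction(r).stoichiometry.items()
            )
            self_big = abs(g0) + span + 1.0
            lb[self._i_g[r]], ub[self._i_g[r]] = -self_big, self_big
        for r in self.thermo_rxns:
            lb[self._i_z[r]], ub[self._i_z[r]] = 0.0, 1.0
        self.lb, self.ub = lb, ub
        self.integrality = np.zeros(self.n_var)
        for r in self.thermo_rxns:
            self.integrality[self._i_z[r]] = 1

        rows, lo_rhs, hi_rhs = [], [], []

        def add(coeffs: dict[int, float], lo: float, hi: float) -> None:
            rows.append(coeffs)
            lo_rhs.append(lo)
            hi_rhs.append(hi)

        # mass balance on internal metabolites
        N = stoichiometric_matrix(net, scope="all")
        internal = set(net.internal_metabolite_ids)
        for i, m in enumerate(self.met_ids):
            if m not in internal:
                continue
            coeffs = {
                self._i_v[r]: N[i, j]
                for j, r in enumerate(self.rxn_ids)
                if N[i, j] != 0
            }
            add(coeffs, 0.0, 0.0)
        # dG definition rows: dG - RT * sum n ln x = dG0
        for r in self.thermo_rxns:
            coeffs = {self._i_g[r]: 1.0}
            for m, c in net.reaction(r).stoichiometry.items():
                coeffs[self._i_x[m]] = coeffs.get(self._i_x[m], 0.0) - thermo.RT * c
            add(coeffs, thermo.dG0[r], thermo.dG0[r])
        # direction coupling with per-reaction big-M
        for r in self.thermo_rxns:
            jv, jg, jz = self._i_v[r], self._i_g[r], self._i_z[r]
            v_lo, v_hi = lb[jv], ub[jv]
            Mv_hi = self.big_m_factor * max(abs(v_hi), 1e-6)
            Mv_lo = self.big_m_factor * max(abs(v_lo), 1e-6)
            Mg = max(abs(lb[jg]), abs(ub[jg]))
            eps = max(self._floors.get(r, 0.0), EPS_DISPLACEMENT)
            # v <= Mv_hi * z         (z=0 forces v <= 0)
            add({jv: 1.0, jz: -Mv_hi}, -np.inf, 0.0)
            # v >= -Mv_lo * (1 - z)  (z=1 forces v >= 0)
            add({jv: 1.0, jz: -Mv_lo}, -Mv_lo, np.inf)
            # dG + (Mg + eps) z in [eps, Mg]:
            #   z=1 -> dG in [-Mg, -eps];  z=0 -> dG in [eps, Mg]
            add({jg: 1.0, jz: Mg + eps}, eps, Mg)
        self._rows, self._lo_rhs, self._hi_rhs = rows, lo_rhs, hi_rhs

    def _constraints(self) -> LinearConstraint:
        rows = self._rows
        data, ri, ci = [], [], []
        for k, coeffs in enumerate(rows):
            for j, c in coeffs.items():
                ri.append(k)
                ci.append(j)
                data.append(c)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), self.n_var))
        return LinearConstraint(A, np.array(self._lo_rhs), np.array(self._hi_rhs))

    # -- modifiers ---------------------------------------------------------
    def apply_displacement_floor(self, rid: str, floor: float) -> "TFAProblem":
        """Require |dG'| >= ``floor`` kcal/mol for ``rid`` in all subsequent
        solves; returns self (rebuilt)."""
        if rid not in self.thermo_rxns:
            raise KeyError(f"{rid!r} has no Gibbs energy in this problem")
        self._floors[rid] = float(floor)
        growth_min = self._growth_min
        self.thermo.displacement_floor[rid] = float(floor)
        self._build()
        self._growth_min = growth_min
        return self

    def set_growth_minimum(self, value: float | None) -> None:
        self._growth_min = value

    # -- solving -----------------------------------------------------------
    def _solve(self, c: np.ndarray):
        cons = [self._constraints()]
        lb, ub = self.lb.copy(), self.ub.copy()
        if self._growth_min is not None:
            j = self._i_v[self.net.biomass_reaction]
            lb[j] = max(lb[j], self._growth_min)
        from scipy.optimize import Bounds

        res = milp(
            c=c,
            constraints=cons,
            integrality=self.integrality,
            bounds=Bounds(lb, ub),
        )
        return res

    def optimize(self, objective: dict[str, float], sense: str = "max"):
        """Optimise a linear objective over flux variables; returns (value, raw x)."""
        c = np.zeros(self.n_var)
        for r, w in objective.items():
            c[self._i_v[r]] = w
        if sense == "max":
            c = -c
        res = self._solve(c)
        if not res.success:
            raise InfeasibleProblemError(
                "TFA problem infeasible; binding constraint families: mass balance, "
                "flux bounds, concentration bounds, Gibbs-energy sign coupling"
                + (", growth minimum" if self._growth_min is not None else "")
                + (", displacement floors" if self._floors else "")
            )
        val = -res.fun if sense == "max" else res.fun
        return val, res.x

    def _random_vertex(self, rng: np.random.Generator) -> np.ndarray:
        c = np.zeros(self.n_var)
        c[: self.nr + self.nm] = rng.standard_normal(self.nr + self.nm)
        res = self._solve(c)
        if not res.success:
            raise InfeasibleProblemError("TFA sampling subproblem infeasible")
        return res.x

    def _balance_projector(self) -> np.ndarray:
        # orthogonal projector onto {v : N_int v = 0}; repairs solver-tolerance
        # residuals so profiles satisfy mass balance to ~machine precision
        if not hasattr(self, "_proj"):
            N = stoichiometric_matrix(self.net, scope="internal")
            self._proj = np.eye(N.shape[1]) - np.linalg.pinv(N) @ N
        return self._proj

    def profile_from_x(self, x: np.ndarray, repair: bool = True) -> SteadyStateProfile:
        v = np.array([x[self._i_v[r]] for r in self.rxn_ids])
        if repair:
            v = self._balance_projector() @ v
        fluxes = {r: float(v[j]) for j, r in enumerate(self.rxn_ids)}
        ln_conc = {m: float(x[self._i_x[m]]) for m in self.met_ids}
        # recompute dG from the definition so the identity holds to machine precision
        dG = {}
        for r in self.thermo_rxns:
            g = self.thermo.dG0[r] + self.thermo.RT * sum(
                c * ln_conc[m] for m, c in self.net.reaction(r).stoichiometry.items()
            )
            dG[r] = float(g)
        return SteadyStateProfile(
            fluxes=fluxes,
            ln_conc=ln_conc,
            dG=dG,
            growth_rate=fluxes.get(self.net.biomass_reaction, 0.0),
        )

    def flux_range(self, rid: str) -> tuple[float, float]:
        """Min/max attainable flux for one reaction (variability analysis)."""
        lo, _ = self.optimize({rid: 1.0}, sense="min")
        hi, _ = self.optimize({rid: 1.0}, sense="max")
        return lo, hi

    def dG_range(self, rid: str) -> tuple[float, float]:
        c = np.zeros(self.n_var)
        c[self._i_g[rid]] = 1.0
        res = self._solve(c)
        if not res.success:
            raise InfeasibleProblemError("dG range subproblem infeasible")
        lo = res.x[self._i_g[rid]]
        res = self._solve(-c)
        hi = res.x[self._i_g[rid]]
        return float(lo), float(hi)


# ---------------------------------------------------------------------------
# High-level operations
# ---------------------------------------------------------------------------

def max_growth(
    net: MetabolicNetwork,
    thermo: ThermoData,
    flux_bounds: dict[str, tuple[float, float]],
) -> float:
    """Maximal biomass flux under mass balance, bounds, and the second law."""
    problem = TFAProblem(net, thermo, flux_bounds)
    val, _ = problem.optimize({net.biomass_reaction: 1.0}, sense="max")
    return float(val)


def sample_steady_states(
    net: MetabolicNetwork,
    thermo: ThermoData,
    flux_bounds: dict[str, tuple[float, float]],
    n: int,
    growth_fraction: float = 0.8,
    seed: int | np.random.Generator = 0,
    max_attempts_factor: int = 5,
    problem: TFAProblem | None = None,
) -> list[SteadyStateProfile]:
    """Draw ``n`` steady-state profiles at >= ``growth_fraction`` of maximal
    growth.  Deterministic under a fixed seed.  If fewer than ``n`` valid
    profiles are found within the attempt budget, the partial list is
    returned with a warning attribute ``sample_steady_states.last_failures``.
    """
    rng = np.random.default_rng(seed)
    if problem is None:
        problem = TFAProblem(net, thermo, flux_bounds)
    mu_max, _ = problem.optimize({net.biomass_reaction: 1.0}, sense="max")
    if mu_max <= 0:
        raise InfeasibleProblemError("maximal growth is zero; nothing to sample")
    problem.set_growth_minimum(growth_fraction * mu_max)
    profiles: list[SteadyStateProfile] = []
    failures = 0
    budget = max_attempts_factor * n
    attempts = 0
    while len(profiles) < n and attempts < budget:
        attempts += 1
        x = problem._random_vertex(rng)
        prof = problem.profile_from_x(x)
        try:
            validate_profile(net, thermo, prof)
        except AssertionError:
            failures += 1
            continue
        profiles.append(prof)
    problem.set_growth_minimum(None)
    sample_steady_states.last_failures = failures
    return profiles


sample_steady_states.last_failures = 0


def validate_profile(
    net: MetabolicNetwork,
    thermo: ThermoData,
    prof: SteadyStateProfile,
    balance_tol: float = 1e-8,
    flux_tol: float = 1e-9,
) -> None:
    """Assert every SteadyStateProfile invariant (raises AssertionError)."""
    N = stoichiometric_matrix(net, scope="internal")
    v = np.array([prof.fluxes[r] for r in net.reaction_ids])
    resid = np.abs(N @ v)
    assert resid.max(initial=0.0) <= balance_tol, (
        f"mass balance violated: max residual {resid.max():.3g}"
    )
    for r in net.reaction_ids:
        if r in prof.dG and abs(prof.fluxes[r]) > flux_tol:
            assert prof.fluxes[r] * prof.dG[r] < 0, (
                f"second law violated for {r}: v={prof.fluxes[r]:.4g}, dG'={prof.dG[r]:.4g}"
            )
    for m in net.metabolite_ids:
        lo, hi = thermo.bounds_for(m)
        x = np.exp(prof.ln_conc[m])
        assert lo * (1 - 1e-9) <= x <= hi * (1 + 1e-9), (
            f"concentration of {m} out of bounds: {x:.3g} not in [{lo:.3g}, {hi:.3g}]"
        )
    for r, g in prof.dG.items():
        g_chk = thermo.dG0[r] + thermo.RT * sum(
            c * prof.ln_conc[m] for m, c in net.reaction(r).stoichiometry.items()
        )
        assert abs(g - g_chk) <= 1e-8, f"dG' identity violated for {r}"


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def profile_to_csv(prof: SteadyStateProfile, path_or_buf) -> None:
    rows = []
    for r, v in prof.fluxes.items():
        rows.append(
            {"kind": "reaction", "id": r, "flux": v, "dG": prof.dG.get(r, np.nan),
             "ln_conc": np.nan}
        )
    for m, lx in prof.ln_conc.items():
        rows.append({"kind": "metabolite", "id": m, "flux": np.nan, "dG": np.nan,
                     "ln_conc": lx})
    rows.append({"kind": "growth", "id": "growth_rate", "flux": prof.growth_rate,
                 "dG": np.nan, "ln_conc": np.nan})
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def profile_from_csv(path_or_buf) -> SteadyStateProfile:
    df = pd.read_csv(path_or_buf)
    fluxes, ln_conc, dG = {}, {}, {}
    growth = 0.0
    for _, row in df.iterrows():
        if row["kind"] == "reaction":
            fluxes[row["id"]] = float(row["flux"])
            if pd.notna(row["dG"]):
                dG[row["id"]] = float(row["dG"])
        elif row["kind"] == "metabolite":
            ln_conc[row["id"]] = float(row["ln_conc"])
        elif row["kind"] == "growth":
            growth = float(row["flux"])
    return SteadyStateProfile(fluxes=fluxes, ln_conc=ln_conc, dG=dG, growth_rate=growth)
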