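"""Rate laws and ensemble kinetic-parameter sampling.

Rate-law dialects
-----------------
All reversible laws are written in displacement form

    v = e * Vmax * psi_s * (1 - Gamma^h) * (reg factors) / D

where ``psi_s = prod (s/Km_s)^a`` is the substrate occupancy,
``Gamma = exp(dG'/RT)`` the thermodynamic displacement (1 at equilibrium),
and ``D`` the law-specific binding denominator.  This form satisfies the
Haldane relation by construction for any positive Km values, vanishes exactly
at equilibrium, and always carries flux down the Gibbs-energy gradient.

* generalized reversible Hill (Hofmeyr/Cornish-Bowden form; h=1 reduces to
  reversible Michaelis-Menten): D = 1 + (psi_s + psi_p)^h
* convenience kinetics (Liebermeister/Klipp): D = prod_s sum_m (s/Km)^m
  + prod_p sum_m (p/Km)^m - 1
* mass action: v = e * k * prod s^a * (1 - Gamma); transports from the cell
  to the extracellular space always use this law

Allosteric modifiers multiply the core law: competitive inhibitors add
``i/Ki`` to the denominator, uncompetitive inhibitors scale the rate by
``1/(1+i/Ki)``, mixed inhibition does both with one constant, and activation
contributes a hyperbolic factor ``(a/Ka)/(1+a/Ka)``.

Parameter back-calculation (ensemble sampling)
----------------------------------------------
Instead of sampling Km directly, we sample each binding-site saturation
``sigma in (0,1)`` and invert ``sigma = x_ss/(x_ss + Km)``, so every Km is
consistent with the anchoring steady-state concentration; Vmax (or k) is then
solved in closed form so the rate at the anchor concentrations equals the
anchor flux exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .network import MetabolicNetwork, RegulatoryInteraction
from .thermo import SteadyStateProfile, ThermoData

__all__ = [
    "ReactionLaw",
    "RateLawAssignment",
    "SaturationSample",
    "KineticParameterSet",
    "KineticModel",
    "assign_rate_laws",
    "binding_sites",
    "sample_saturations",
    "parameterize_from_saturation",
    "build_model",
    "evaluate_rate",
    "sample_kinetic_models",
]

LAWS = ("generalized_reversible_hill", "convenience", "mass_action")


@dataclass
class ReactionLaw:
    law: str
    hill_coefficient: float = 1.0
    modifiers: list[RegulatoryInteraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}")
        if self.hill_coefficient < 1:
            raise ValueError("hill coefficient must be >= 1")


@dataclass
class RateLawAssignment:
    laws: dict[str, ReactionLaw]

    def __getitem__(self, rid: str) -> ReactionLaw:
        return self.laws[rid]

    def __iter__(self):
        return iter(self.laws)


@dataclass
class SaturationSample:
    """One sigma value per binding site, all strictly inside (0, 1)."""

    sigma: dict[tuple[str, str, str], float]  # (kind, reaction, metabolite)

    def __post_init__(self) -> None:
        for key, s in self.sigma.items():
            if not (0.0 < s < 1.0):
                raise ValueError(f"saturation {key} = {s} not in (0,1)")


@dataclass
class KineticParameterSet:
    Km: dict[tuple[str, str], float] = field(default_factory=dict)
    Ki: dict[tuple[str, str], float] = field(default_factory=dict)
    Ka: dict[tuple[str, str], float] = field(default_factory=dict)
    Vmax: dict[str, float] = field(default_factory=dict)
    k: dict[str, float] = field(default_factory=dict)

    def validate_positive(self) -> None:
        for name, table in (("Km", self.Km), ("Ki", self.Ki), ("Ka", self.Ka)):
            for key, val in table.items():
                if val <= 0:
                    raise ValueError(f"{name}{key} = {val} must be positive")


# ---------------------------------------------------------------------------
# Law assignment
# ---------------------------------------------------------------------------

def _is_secretion_transport(net: MetabolicNetwork, rid: str) -> bool:
    """Transport whose products lie in the extracellular compartment."""
    r = net.reaction(rid)
    if not (r.is_transport or r.is_exchange):
        return False
    ext = net.extracellular_compartment
    return any(net.metabolite(m).compartment == ext for m in r.products)


def assign_rate_laws(
    net: MetabolicNetwork, hill: float = 1.0
) -> RateLawAssignment:
    """Deterministic stoichiometry-class -> mechanism mapping.

    Single-substrate reactions (uni-uni, uni-bi) take the generalized
    reversible Hill law; multi-substrate reactions take convenience kinetics;
    transports into the extracellular compartment take mass action.
    """
    laws: dict[str, ReactionLaw] = {}
    for r in net.reactions:
        mods = net.regulations_of(r.id)
        if _is_secretion_transport(net, r.id):
            laws[r.id] = ReactionLaw("mass_action", modifiers=mods)
            continue
        n_sub_species = len(r.substrates)
        total_sub = sum(r.substrates.values())
        if n_sub_species <= 1 and total_sub <= 1:
            laws[r.id] = ReactionLaw(
                "generalized_reversible_hill", hill_coefficient=hill, modifiers=mods
            )
        else:
            laws[r.id] = ReactionLaw("convenience", modifiers=mods)
    return RateLawAssignment(laws)


def binding_sites(
    net: MetabolicNetwork, assignment: RateLawAssignment, thermo: ThermoData
) -> list[tuple[str, str, str]]:
    """All (kind, reaction, metabolite) sites that demand a saturation draw.

    Kinds: 'Km' (substrate/product half-saturation), 'Ki' (inhibition),
    'Ka' (activation).  Mass-action reactions have no Km sites; product Km
    sites exist only for thermodynamically reversible (dG0-carrying) laws.
    """
    sites: list[tuple[str, str, str]] = []
    seen = set()
    for r in net.reactions:
        law = assignment[r.id]
        if law.law != "mass_action":
            for m in r.substrates:
                sites.append(("Km", r.id, m))
            if r.id in thermo.dG0:
                for m in r.products:
                    sites.append(("Km", r.id, m))
        for mod in law.modifiers:
            kind = "Ka" if mod.mode == "activation" else "Ki"
            key = (kind, r.id, mod.regulator)
            if key not in seen:
                seen.add(key)
                sites.append(key)
    return sites


def sample_saturations(
    net: MetabolicNetwork,
    assignment: RateLawAssignment,
    thermo: ThermoData,
    rng: np.random.Generator,
    low: float = 0.01,
    high: float = 0.99,
) -> SaturationSample:
    sites = binding_sites(net, assignment, thermo)
    draws = rng.uniform(low, high, size=len(sites))
    return SaturationSample(sigma=dict(zip(sites, draws)))


# ---------------------------------------------------------------------------
# Symbolic compilation (shared across an ensemble)
# ---------------------------------------------------------------------------

class CompiledKinetics:
    """Rate vector and its concentration Jacobian, compiled once per
    (network, assignment, thermo) triple with concentrations ``x``, enzyme
    activities ``e``, and kinetic parameters ``theta`` all as arguments."""

    def __init__(
        self,
        net: MetabolicNetwork,
        assignment: RateLawAssignment,
        thermo: ThermoData,
    ):
        self.net = net
        self.assignment = assignment
        self.thermo = thermo
        self.met_ids = net.metabolite_ids
        self.rxn_ids = net.reaction_ids
        self.internal_idx = [
            i for i, m in enumerate(self.met_ids) if not net.metabolite(m).is_boundary
        ]
        self._build()

    def _build(self) -> None:
        net, thermo = self.net, self.thermo
        x_syms = {m: sp.Symbol(f"x_{i}", positive=True) for i, m in enumerate(self.met_ids)}
        e_syms = {r: sp.Symbol(f"e_{j}", positive=True) for j, r in enumerate(self.rxn_ids)}

        self.param_slots: list[tuple] = []
        p_syms: dict[tuple, sp.Symbol] = {}

        def par(key: tuple) -> sp.Symbol:
            if key not in p_syms:
                p_syms[key] = sp.Symbol(f"p_{len(self.param_slots)}", positive=True)
                self.param_slots.append(key)
            return p_syms[key]

        exprs = []
        for r in net.reactions:
            law = self.assignment[r.id]
            subs = r.substrates
            prods = r.products
            has_thermo = r.id in thermo.dG0

            gamma = None
            if has_thermo:
                lnG = thermo.dG0[r.id] / thermo.RT
                gamma = sp.exp(
                    lnG
                    + sp.Add(*[c * sp.log(x_syms[m]) for m, c in r.stoichiometry.items()])
                )

            comp_sum = sp.Integer(0)
            factor = sp.Integer(1)
            for mod in law.modifiers:
                i_sym = x_syms[mod.regulator]
                if mod.mode == "activation":
                    Ka = par(("Ka", r.id, mod.regulator))
                    factor *= (i_sym / Ka) / (1 + i_sym / Ka)
                else:
                    Ki = par(("Ki", r.id, mod.regulator))
                    if mod.mode in ("competitive_inhibition", "mixed_inhibition"):
                        comp_sum += i_sym / Ki
                    if mod.mode in ("uncompetitive_inhibition", "mixed_inhibition"):
                        factor *= 1 / (1 + i_sym / Ki)

            if law.law == "mass_action":
                k = par(("k", r.id))
                core = k * sp.Mul(*[x_syms[m] ** a for m, a in subs.items()])
                if has_thermo:
                    core *= 1 - gamma
                if comp_sum != 0:
                    core /= 1 + comp_sum
                exprs.append(e_syms[r.id] * factor * core)
                continue

            Vmax = par(("Vmax", r.id))
            psi_s = sp.Mul(
                *[(x_syms[m] / par(("Km", r.id, m))) ** a for m, a in subs.items()]
            )
            if has_thermo:
                psi_p = sp.Mul(
                    *[(x_syms[m] / par(("Km", r.id, m))) ** b for m, b in prods.items()]
                )
                drive = 1 - gamma
            else:
                psi_p = sp.Integer(0)
                drive = sp.Integer(1)

            if law.law == "generalized_reversible_hill":
                h = sp.Float(law.hill_coefficient)
                u = psi_s + psi_p
                if law.hill_coefficient == 1.0:
                    num = psi_s * drive
                    den = 1 + u + comp_sum
                else:
                    num = psi_s * drive * u ** (h - 1)
                    den = 1 + u**h + comp_sum
            else:  # convenience
                Ds = sp.Mul(
                    *[
                        sp.Add(
                            *[
                                (x_syms[m] / par(("Km", r.id, m))) ** i
                                for i in range(int(round(a)) + 1)
                            ]
                        )
                        for m, a in subs.items()
                    ]
                )
                if has_thermo:
                    Dp = sp.Mul(
                        *[
                            sp.Add(
                                *[
                                    (x_syms[m] / par(("Km", r.id, m))) ** i
                                    for i in range(int(round(b)) + 1)
                                ]
                            )
                            for m, b in prods.items()
                        ]
                    )
                else:
                    Dp = sp.Integer(1)
                num = psi_s * drive
                den = Ds + Dp - 1 + comp_sum
            exprs.append(e_syms[r.id] * factor * Vmax * num / den)

        x_list = [x_syms[m] for m in self.met_ids]
        e_list = [e_syms[r] for r in self.rxn_ids]
        p_list = [p_syms[key] for key in self.param_slots]
        rates = sp.Matrix(exprs)
        x_int = [x_list[i] for i in self.internal_idx]
        dvdx_int = rates.jacobian(x_int)
        self._v_fn = sp.lambdify([x_list, e_list, p_list], rates, "numpy")
        self._dvdx_fn = sp.lambdify([x_list, e_list, p_list], dvdx_int, "numpy")

    def theta(self, params: KineticParameterSet) -> np.ndarray:
        out = np.empty(len(self.param_slots))
        for i, slot in enumerate(self.param_slots):
            kind = slot[0]
            if kind == "Km":
                out[i] = params.Km[(slot[1], slot[2])]
            elif kind == "Ki":
                out[i] = params.Ki[(slot[1], slot[2])]
            elif kind == "Ka":
                out[i] = params.Ka[(slot[1], slot[2])]
            elif kind == "Vmax":
                out[i] = params.Vmax[slot[1]]
            else:
                out[i] = params.k[slot[1]]
        return out

    def rates(self, x: np.ndarray, e: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self._v_fn(x, e, theta), dtype=float).ravel()

    def dvdx_internal(self, x: np.ndarray, e: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self._dvdx_fn(x, e, theta), dtype=float)


_COMPILE_CACHE: list[tuple] = []


def get_compiled(
    net: MetabolicNetwork, assignment: RateLawAssignment, thermo: ThermoData
) -> CompiledKinetics:
    for n, a, t, compiled in _COMPILE_CACHE:
        if n is net and a is assignment and t is thermo:
            return compiled
    compiled = CompiledKinetics(net, assignment, thermo)
    _COMPILE_CACHE.append((net, assignment, thermo, compiled))
    if len(_COMPILE_CACHE) > 32:
        _COMPILE_CACHE.pop(0)
    return compiled


# ---------------------------------------------------------------------------
# Parameterization and the model object
# ---------------------------------------------------------------------------

def parameterize_from_saturation(
    net: MetabolicNetwork,
    assignment: RateLawAssignment,
    thermo: ThermoData,
    profile: SteadyStateProfile,
    saturations: SaturationSample,
    zero_flux_tol: float = 1e-12,
) -> KineticParameterSet:
    """Back-calculate a kinetic parameter set from saturations.

    Every binding constant follows ``K = x_ss (1 - sigma)/sigma``; Vmax (or
    the mass-action k) is solved so the rate at the anchor concentrations
    equals the anchor flux.  Reactions whose anchor flux is exactly zero get
    Vmax = 0 (a dead reaction), which keeps the anchoring identity exact.
    """
    params = KineticParameterSet()
    for kind, rid, mid in binding_sites(net, assignment, thermo):
        x_ss = float(np.exp(profile.ln_conc[mid]))
        sigma = saturations.sigma[(kind, rid, mid)]
        K = x_ss * (1 - sigma) / sigma
        getattr(params, kind)[(rid, mid)] = K
    # unit-scale placeholders, replaced by the closed-form solve below
    for r in net.reactions:
        if assignment[r.id].law == "mass_action":
            params.k[r.id] = 1.0
        else:
            params.Vmax[r.id] = 1.0
    compiled = get_compiled(net, assignment, thermo)
    x_ss = np.array([np.exp(profile.ln_conc[m]) for m in compiled.met_ids])
    e = np.ones(len(compiled.rxn_ids))
    rest = compiled.rates(x_ss, e, compiled.theta(params))
    for j, rid in enumerate(compiled.rxn_ids):
        v_ss = profile.fluxes[rid]
        scale = 0.0 if abs(v_ss) <= zero_flux_tol else v_ss / rest[j]
        if scale < 0:
            raise RuntimeError(
                f"anchor flux and thermodynamic drive disagree for {rid}: "
                f"v_ss={v_ss:.4g}, unscaled rate={rest[j]:.4g}"
            )
        if assignment[rid].law == "mass_action":
            params.k[rid] = scale
        else:
            params.Vmax[rid] = scale
    return params


@dataclass
class KineticModel:
    """A rate-law assignment plus parameter set anchored to one profile."""

    network: MetabolicNetwork
    assignment: RateLawAssignment
    params: KineticParameterSet
    anchor: SteadyStateProfile
    thermo: ThermoData
    enzyme_scale: dict[str, float] = field(default_factory=dict)
    model_id: str = ""

    # -- compiled access ---------------------------------------------------
    @property
    def compiled(self) -> CompiledKinetics:
        return get_compiled(self.network, self.assignment, self.thermo)

    @property
    def met_ids(self) -> list[str]:
        return self.compiled.met_ids

    @property
    def rxn_ids(self) -> list[str]:
        return self.compiled.rxn_ids

    def _e_vec(self) -> np.ndarray:
        return np.array([self.enzyme_scale.get(r, 1.0) for r in self.rxn_ids])

    def _theta(self) -> np.ndarray:
        return self.compiled.theta(self.params)

    @property
    def anchor_x(self) -> np.ndarray:
        return np.array([np.exp(self.anchor.ln_conc[m]) for m in self.met_ids])

    @property
    def anchor_v(self) -> np.ndarray:
        return np.array([self.anchor.fluxes[r] for r in self.rxn_ids])

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Rate vector at concentration vector ``x`` (ordered like met_ids)."""
        if np.any(np.asarray(x) <= 0):
            raise ValueError("concentrations must be strictly positive")
        return self.compiled.rates(np.asarray(x, dtype=float), self._e_vec(), self._theta())

    def dvdx_internal(self, x: np.ndarray) -> np.ndarray:
        return self.compiled.dvdx_internal(
            np.asarray(x, dtype=float), self._e_vec(), self._theta()
        )

    def with_enzyme_scale(self, scale: dict[str, float]) -> "KineticModel":
        merged = dict(self.enzyme_scale)
        merged.update(scale)
        return replace(self, enzyme_scale=merged)

    # -- structural reduction ---------------------------------------------
    def _reduction(self):
        """(N_int, N_R, L, independent-species indices) with N_int = L @ N_R."""
        if not hasattr(self, "_red_cache"):
            from .network import stoichiometric_matrix

            N = stoichiometric_matrix(self.network, scope="internal")
            indep: list[int] = []
            for i in range(N.shape[0]):
                trial = N[indep + [i], :]
                if np.linalg.matrix_rank(trial, tol=1e-9) > len(indep):
                    indep.append(i)
            N_R = N[indep, :]
            L = N @ np.linalg.pinv(N_R)
            # snap exact-integer links
            L[np.abs(L) < 1e-10] = 0.0
            self._red_cache = (N, N_R, L, indep)
        return self._red_cache

    def jacobian_reduced(self, volume_factor: float = 1.0) -> np.ndarray:
        """Jacobian of the independent internal-species dynamics at the anchor,
        with conserved-moiety (structural zero) directions removed."""
        N, N_R, L, indep = self._reduction()
        dvdx = self.dvdx_internal(self.anchor_x)
        return volume_factor * N_R @ dvdx @ L

    def n_conserved(self) -> int:
        N, N_R, _, _ = self._reduction()
        return N.shape[0] - N_R.shape[0]


def build_model(
    net: MetabolicNetwork,
    assignment: RateLawAssignment,
    thermo: ThermoData,
    profile: SteadyStateProfile,
    saturations: SaturationSample,
    model_id: str = "",
) -> KineticModel:
    params = parameterize_from_saturation(net, assignment, thermo, profile, saturations)
    return KineticModel(
        network=net,
        assignment=assignment,
        params=params,
        anchor=profile,
        thermo=thermo,
        model_id=model_id,
    )


def evaluate_rate(model: KineticModel, ln_conc: dict[str, float]) -> dict[str, float]:
    """Rates at the given ln-concentrations, as a reaction-id map."""
    x = np.array([np.exp(ln_conc[m]) for m in model.met_ids])
    v = model.rates(x)
    return dict(zip(model.rxn_ids, v))


def anchoring_residual(model: KineticModel) -> float:
    """Max relative deviation between model rates at the anchor concentrations
    and the anchor fluxes (the anchoring identity)."""
    v = model.rates(model.anchor_x)
    v_ss = model.anchor_v
    scale = np.maximum(np.abs(v_ss), 1e-30)
    rel = np.abs(v - v_ss) / np.where(np.abs(v_ss) > 0, scale, 1.0)
    return float(rel.max())


def sample_kinetic_models(
    net: MetabolicNetwork,
    assignment: RateLawAssignment,
    thermo: ThermoData,
    profiles: list[SteadyStateProfile],
    per_profile: int,
    stability_prune: bool = True,
    seed: int | np.random.Generator = 0,
    max_attempts_factor: int = 10,
) -> list[KineticModel]:
    """ORACLE-style ensemble generation: for each steady-state profile draw
    saturation samples, back-calculate parameters, and (optionally) retain
    only models whose reduced Jacobian has all eigenvalue real parts < 0."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    models: list[KineticModel] = []
    for p_idx, prof in enumerate(profiles):
        kept = 0
        attempts = 0
        budget = max_attempts_factor * per_profile
        while kept < per_profile and attempts < budget:
            attempts += 1
            sat = sample_saturations(net, assignment, thermo, rng)
            model = build_model(
                net, assignment, thermo, prof, sat,
                model_id=f"p{p_idx}m{kept}",
            )
            if stability_prune:
                eig = np.linalg.eigvals(model.jacobian_reduced())
                if eig.size and eig.real.max() >= 0:
                    continue
            models.append(model)
            kept += 1
    return models
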