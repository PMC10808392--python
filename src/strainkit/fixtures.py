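"""Synthetic toy fixtures: networks, ground-truth models, pseudo-experiments.

Every pipeline stage is exercised on small (5-11 reaction) two-compartment
networks with a substrate uptake, a secreted product (an anthranilate
analogue), a lumped biomass reaction, and — depending on topology — a
regulated branch point, a conserved cofactor pair, an engineered bistability,
or an elementally closed carbon backbone:

* ``chain``       linear pathway, biomass drawn mid-chain
* ``branched10``  10 reactions with an ATP/ADP conserved moiety and a side
                  branch (one conservation relation)
* ``feedback_branch``  branch point whose product-branch entry enzyme is
                  competitively inhibited by the end product of the biomass
                  branch (the planted bottleneck, mimicking feedback
                  inhibition of a pathway-entry synthase)
* ``bistable_toy``  autocatalytic step with sigmoidal self-activation; has a
                  trivial washed-out attractor besides the anchor
* ``carbon_closed`` chain with explicit carbon counts for conservation audits

Enzymatic steps carry a small positive flux floor (0.01 mmol/gDW/h) so every
enzyme stays expressed in every sampled steady state.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioreactor import BioreactorConfig, simulate_batch
from .kinetics import (
    KineticModel,
    assign_rate_laws,
    build_model,
    sample_saturations,
)
from .network import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    RegulatoryInteraction,
)
from .screening import eigen_summary
from .thermo import SteadyStateProfile, ThermoData, sample_steady_states

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_fixture",
    "make_toy_network",
    "make_ground_truth_model",
    "generate_pseudo_experiment",
    "write_fixture",
]

TOPOLOGIES = ("chain", "branched10", "feedback_branch", "bistable_toy", "carbon_closed")

#: minimum flux carried by every enzymatic step, mmol/gDW/h
FLUX_FLOOR = 0.01
#: minimum product-export flux, mmol/gDW/h
EXPORT_FLOOR = 0.2

_INTERNAL_BOUNDS = (1e-5, 1e-2)
_SUBSTRATE_BOUNDS = (1e-2, 5.6e-2)  # ~1.8-10 g/L glucose analogue
_PRODUCT_EXT_BOUNDS = (1e-8, 1e-5)
_COFACTOR_BOUNDS = (1e-4, 1e-2)


@dataclass
class FixtureSpec:
    topology: str = "chain"
    n_reactions: int = 5
    regulations: list[RegulatoryInteraction] = field(default_factory=list)
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    network: MetabolicNetwork
    thermo: ThermoData
    flux_bounds: dict[str, tuple[float, float]]
    molar_masses: dict[str, float]
    carbon_counts: dict[str, float]
    planted_target: str | None = None
    biomass_precursor_coeff: float = 5.0

    def default_config(
        self, profile: SteadyStateProfile, t_end: float = 20.0
    ) -> BioreactorConfig:
        """Batch setup whose medium matches the profile's boundary state."""
        medium = {
            m: float(np.exp(profile.ln_conc[m]))
            for m in self.network.boundary_metabolite_ids
        }
        return BioreactorConfig(
            initial_biomass=0.01,
            medium=medium,
            t_end=t_end,
            molar_masses=self.molar_masses,
        )


# ---------------------------------------------------------------------------
# Topology builders
# ---------------------------------------------------------------------------

def _met(mid, comp="c", bnd=False):
    return Metabolite(id=mid, name=mid, compartment=comp, is_boundary=bnd)


def _base_masses(extra: dict[str, float] | None = None) -> dict[str, float]:
    masses = {"S_e": 180.0, "S_c": 180.0, "P_c": 137.0, "P_e": 137.0}
    masses.update(extra or {})
    return masses


def _chain(spec: FixtureSpec) -> FixtureBundle:
    n = max(spec.n_reactions, 3)
    mids = [f"M{i}" for i in range(1, n)]
    mets = (
        [_met("S_e", "e", True), _met("S_c")]
        + [_met(m) for m in mids]
        + [_met("P_c"), _met("P_e", "e", True)]
    )
    chain_species = ["S_c"] + mids + ["P_c"]
    rxns = [Reaction("upt", {"S_e": -1, "S_c": 1}, is_transport=True)]
    for i in range(n):
        rxns.append(
            Reaction(f"R{i + 1}", {chain_species[i]: -1, chain_species[i + 1]: 1})
        )
    rxns.append(Reaction("expP", {"P_c": -1, "P_e": 1}, is_transport=True))
    bio_precursor = mids[min(len(mids) - 1, (n - 1) // 2 + 1)]
    rxns.append(Reaction("biomass", {bio_precursor: -10.0}, reversible=False))
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        regulations=list(spec.regulations),
        biomass_reaction="biomass",
        objective_product="expP",
        substrate_uptake="upt",
    )
    dG0 = {"upt": -0.5, "expP": -0.5}
    dG0.update({f"R{i + 1}": -2.0 for i in range(n)})
    bounds = _default_flux_bounds(net)
    thermo = ThermoData(dG0=dG0, conc_bounds=_default_conc_bounds(net))
    return FixtureBundle(
        spec=spec,
        network=net,
        thermo=thermo,
        flux_bounds=bounds,
        molar_masses=_base_masses(),
        carbon_counts={m.id: 6.0 for m in mets},
        biomass_precursor_coeff=10.0,
    )


def _branched10(spec: FixtureSpec) -> FixtureBundle:
    mets = [
        _met("S_e", "e", True), _met("S_c"), _met("A"), _met("B"), _met("C"),
        _met("Q_c"), _met("Q_e", "e", True), _met("P_c"), _met("P_e", "e", True),
        _met("ATP"), _met("ADP"),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "S_c": 1}, is_transport=True),
        Reaction("R1", {"S_c": -1, "ATP": -1, "A": 1, "ADP": 1}),
        Reaction("R2", {"A": -1, "B": 1}),
        Reaction("R3", {"B": -1, "ADP": -2, "C": 1, "ATP": 2}),
        Reaction("R4", {"B": -1, "Q_c": 1}),
        Reaction("expQ", {"Q_c": -1, "Q_e": 1}, is_transport=True),
        Reaction("R5", {"C": -1, "P_c": 1}),
        Reaction("expP", {"P_c": -1, "P_e": 1}, is_transport=True),
        Reaction("atpase", {"ATP": -1, "ADP": 1}, reversible=False),
        Reaction("biomass", {"C": -5.0}, reversible=False),
    ]
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        regulations=list(spec.regulations),
        biomass_reaction="biomass",
        objective_product="expP",
        substrate_uptake="upt",
    )
    dG0 = {
        "upt": -0.5, "R1": -2.0, "R2": -2.0, "R3": -2.0, "R4": -2.0,
        "expQ": -0.5, "R5": -2.0, "expP": -0.5, "atpase": -5.0,
    }
    conc = _default_conc_bounds(net)
    conc["ATP"] = _COFACTOR_BOUNDS
    conc["ADP"] = _COFACTOR_BOUNDS
    conc["Q_e"] = _PRODUCT_EXT_BOUNDS
    thermo = ThermoData(dG0=dG0, conc_bounds=conc)
    return FixtureBundle(
        spec=spec,
        network=net,
        thermo=thermo,
        flux_bounds=_default_flux_bounds(net),
        molar_masses=_base_masses({"Q_c": 146.0, "Q_e": 146.0}),
        carbon_counts={m.id: 6.0 for m in mets if m.id not in ("ATP", "ADP")},
    )


def _feedback_branch(spec: FixtureSpec) -> FixtureBundle:
    mets = [
        _met("S_e", "e", True), _met("S_c"), _met("A"), _met("B"),
        _met("P_c"), _met("P_e", "e", True), _met("C1"), _met("C2"),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "S_c": 1}, is_transport=True),
        Reaction("R1", {"S_c": -1, "A": 1}),
        Reaction("R2", {"A": -1, "B": 1}),
        Reaction("Eprod", {"B": -1, "P_c": 1}, gene_label="branch entry (DDPA analogue)"),
        Reaction("expP", {"P_c": -1, "P_e": 1}, is_transport=True),
        Reaction("Ebio", {"B": -1, "C1": 1}),
        Reaction("R3", {"C1": -1, "C2": 1}),
        Reaction("biomass", {"C2": -5.0}, reversible=False),
    ]
    regs = [RegulatoryInteraction("C2", "Eprod", "competitive_inhibition")]
    regs.extend(spec.regulations)
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        regulations=regs,
        biomass_reaction="biomass",
        objective_product="expP",
        substrate_uptake="upt",
    )
    dG0 = {
        "upt": -0.5, "R1": -2.0, "R2": -2.0, "Eprod": -3.0,
        "expP": -0.5, "Ebio": -2.0, "R3": -2.0,
    }
    # keep the planted bottleneck displaced from equilibrium so it can exert
    # flux control (a near-equilibrium entry step would be undesignable)
    thermo = ThermoData(
        dG0=dG0,
        conc_bounds=_default_conc_bounds(net),
        displacement_floor={"Eprod": 1.25},
    )
    return FixtureBundle(
        spec=spec,
        network=net,
        thermo=thermo,
        flux_bounds=_default_flux_bounds(net),
        molar_masses=_base_masses(),
        carbon_counts={m.id: 6.0 for m in mets},
        planted_target="Eprod",
    )


def _bistable(spec: FixtureSpec) -> FixtureBundle:
    mets = [
        _met("S_e", "e", True), _met("S_c"), _met("M"),
        _met("P_c"), _met("P_e", "e", True),
    ]
    # the same activation listed twice yields a squared (sigmoidal) factor
    regs = [
        RegulatoryInteraction("M", "Rauto", "activation"),
        RegulatoryInteraction("M", "Rauto", "activation"),
    ]
    regs.extend(spec.regulations)
    rxns = [
        Reaction("upt", {"S_e": -1, "S_c": 1}, is_transport=True),
        Reaction("Rauto", {"S_c": -1, "M": 1}),
        Reaction("R2", {"M": -1, "P_c": 1}),
        Reaction("expP", {"P_c": -1, "P_e": 1}, is_transport=True),
        Reaction("biomass", {"M": -2.0}, reversible=False),
    ]
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        regulations=regs,
        biomass_reaction="biomass",
        objective_product="expP",
        substrate_uptake="upt",
    )
    dG0 = {"upt": -0.5, "Rauto": -2.5, "R2": -2.5, "expP": -0.5}
    thermo = ThermoData(dG0=dG0, conc_bounds=_default_conc_bounds(net))
    return FixtureBundle(
        spec=spec,
        network=net,
        thermo=thermo,
        flux_bounds=_default_flux_bounds(net),
        molar_masses=_base_masses(),
        carbon_counts={m.id: 6.0 for m in mets},
        biomass_precursor_coeff=2.0,
    )


def _carbon_closed(spec: FixtureSpec) -> FixtureBundle:
    mets = [
        _met("S_e", "e", True), _met("S_c"), _met("M1"),
        _met("P_c"), _met("P_e", "e", True),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "S_c": 1}, is_transport=True),
        Reaction("R1", {"S_c": -1, "M1": 1}),
        Reaction("R2", {"M1": -1, "P_c": 1}),
        Reaction("expP", {"P_c": -1, "P_e": 1}, is_transport=True),
        Reaction("biomass", {"M1": -5.0}, reversible=False),
    ]
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        regulations=list(spec.regulations),
        biomass_reaction="biomass",
        objective_product="expP",
        substrate_uptake="upt",
    )
    dG0 = {"upt": -0.5, "R1": -2.0, "R2": -2.0, "expP": -0.5}
    thermo = ThermoData(dG0=dG0, conc_bounds=_default_conc_bounds(net))
    return FixtureBundle(
        spec=spec,
        network=net,
        thermo=thermo,
        flux_bounds=_default_flux_bounds(net),
        molar_masses=_base_masses(),
        carbon_counts={m.id: 6.0 for m in mets},
    )


def _default_conc_bounds(net: MetabolicNetwork) -> dict[str, tuple[float, float]]:
    conc: dict[str, tuple[float, float]] = {}
    for m in net.metabolites:
        if m.id == "S_e":
            conc[m.id] = _SUBSTRATE_BOUNDS
        elif m.is_boundary:
            conc[m.id] = _PRODUCT_EXT_BOUNDS
        else:
            conc[m.id] = _INTERNAL_BOUNDS
    return conc


def _default_flux_bounds(net: MetabolicNetwork) -> dict[str, tuple[float, float]]:
    bounds: dict[str, tuple[float, float]] = {}
    for r in net.reactions:
        if r.id == net.substrate_uptake:
            bounds[r.id] = (FLUX_FLOOR, 10.0)
        elif r.id == net.objective_product:
            bounds[r.id] = (EXPORT_FLOOR, 100.0)
        elif r.id == net.biomass_reaction:
            bounds[r.id] = (0.0, 10.0)
        else:
            bounds[r.id] = (FLUX_FLOOR, 100.0)
    return bounds


_BUILDERS = {
    "chain": _chain,
    "branched10": _branched10,
    "feedback_branch": _feedback_branch,
    "bistable_toy": _bistable,
    "carbon_closed": _carbon_closed,
}


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    return _BUILDERS[spec.topology](spec)


def make_toy_network(spec: FixtureSpec) -> MetabolicNetwork:
    return make_fixture(spec).network


# ---------------------------------------------------------------------------
# Ground-truth model
# ---------------------------------------------------------------------------

def make_ground_truth_model(
    bundle: FixtureBundle,
    seed: int = 0,
    growth_fraction: float = 0.8,
    max_tries: int = 300,
) -> tuple[KineticModel, SteadyStateProfile]:
    """A stable anchored model with tau_d below a fifth of the doubling time,
    found by resampling saturations; bistable fixtures additionally must
    escape the anchor basin under a strong downward perturbation."""
    rng = np.random.default_rng(seed)
    net, thermo = bundle.network, bundle.thermo
    profiles = sample_steady_states(
        net, thermo, bundle.flux_bounds, n=1,
        growth_fraction=growth_fraction,
        seed=int(rng.integers(2**31)),
    )
    if not profiles:
        raise RuntimeError("no feasible steady-state profile for fixture")
    prof = profiles[0]
    assignment = assign_rate_laws(net)
    tau_max_h = math.log(2.0) / prof.growth_rate / 5.0
    for attempt in range(max_tries):
        sat = sample_saturations(net, assignment, thermo, rng)
        model = build_model(net, assignment, thermo, prof, sat,
                            model_id=f"gt{attempt}")
        summary = eigen_summary(model)
        if not (summary.stable and summary.dominant_time_constant < tau_max_h):
            continue
        if bundle.spec.topology == "bistable_toy" and not _has_second_attractor(model):
            continue
        return model, prof
    raise RuntimeError(
        f"no ground-truth model found in {max_tries} tries "
        f"(topology {bundle.spec.topology!r})"
    )


def _has_second_attractor(model: KineticModel, k_fold: float = 20.0) -> bool:
    """Does dividing the autocatalytic species by ``k_fold`` leave the anchor
    basin (relaxes to a different steady state)?"""
    from .bioreactor import SimulationError, relax_intracellular

    compiled = model.compiled
    x_ref = model.anchor_x[compiled.internal_idx]
    int_ids = [compiled.met_ids[i] for i in compiled.internal_idx]
    x0 = x_ref.copy()
    x0[int_ids.index("M")] = x_ref[int_ids.index("M")] / k_fold
    try:
        _, y = relax_intracellular(model, x0_int=x0, t_end=50.0)
    except SimulationError:
        return True
    rel = np.abs(y[:, -1] - x_ref) / np.maximum(np.abs(x_ref), 1e-30)
    return rel.max() > 0.5


def make_adversarial_model(
    seed: int = 0,
    n_profiles: int = 3,
    per_profile: int = 5,
) -> tuple[FixtureBundle, KineticModel]:
    """A feedback-branch model on which naive control-coefficient design is
    dangerous: among its top-3 yield-control targets is a 5-fold
    *down*-regulation of the biomass branch (Ebio or R3), which starves
    growth when applied without phenotype-proximity constraints."""
    from .mca import control_coefficients, top_k_targets
    from .nra import designable_enzymes

    bundle = make_fixture(FixtureSpec(topology="feedback_branch", seed=seed))
    profiles = sample_steady_states(
        bundle.network, bundle.thermo, bundle.flux_bounds, n=n_profiles, seed=seed
    )
    assignment = assign_rate_laws(bundle.network)
    from .kinetics import sample_kinetic_models

    models = sample_kinetic_models(
        bundle.network, assignment, bundle.thermo, profiles, per_profile, seed=seed
    )
    designable = set(designable_enzymes(bundle.network))
    for model in models:
        cc = control_coefficients(model)
        targets = top_k_targets(cc, k=3, exclude=set(cc.enzyme_ids) - designable)
        if any(e in ("Ebio", "R3") and d == "down" for e, d, _ in targets):
            return bundle, model
    raise RuntimeError("no adversarial model found; enlarge the ensemble")


# ---------------------------------------------------------------------------
# Pseudo-experiment
# ---------------------------------------------------------------------------

def generate_pseudo_experiment(
    model: KineticModel,
    config: BioreactorConfig,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    n_points: int = 10,
) -> pd.DataFrame:
    """Simulated triplicate fermentation curves: batch-simulate, subsample
    ~``n_points`` times, add multiplicative Gaussian noise per replicate,
    return a mean +/- sd table (biomass gDW/L, substrate/product g/L)."""
    rng = np.random.default_rng(seed)
    traj = simulate_batch(model, config)
    idx = np.linspace(0, len(traj.t) - 1, n_points).round().astype(int)
    t = traj.t[idx]
    series = {
        "biomass": traj.biomass[idx],
        "substrate": traj.series_gL(traj.substrate_species)[idx],
        "product": traj.series_gL(traj.product_species)[idx],
    }
    out = {"time": t}
    for name, clean in series.items():
        if noise_cv > 0:
            reps = clean[None, :] * (
                1.0 + noise_cv * rng.standard_normal((n_replicates, clean.size))
            )
        else:
            reps = np.tile(clean, (n_replicates, 1))
        out[name] = reps.mean(axis=0)
        out[f"{name}_sd"] = reps.std(axis=0, ddof=1) if n_replicates > 1 else 0.0
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_fixture(bundle: FixtureBundle, directory: str, seed: int = 0) -> None:
    """Write network TSV + SBML, thermodynamic CSV, pseudo-experimental
    curves CSV, and a run-config YAML into ``directory``."""
    import yaml

    from .network import save_network

    os.makedirs(directory, exist_ok=True)
    save_network(bundle.network, os.path.join(directory, "network"), format="tsv")
    save_network(bundle.network, os.path.join(directory, "network.xml"), format="sbml")
    rows = [
        {"kind": "dG0", "id": r, "value": g, "lo": np.nan, "hi": np.nan}
        for r, g in bundle.thermo.dG0.items()
    ]
    rows += [
        {"kind": "conc_bounds", "id": m, "value": np.nan, "lo": lo, "hi": hi}
        for m, (lo, hi) in bundle.thermo.conc_bounds.items()
    ]
    rows += [
        {"kind": "flux_bounds", "id": r, "value": np.nan, "lo": lo, "hi": hi}
        for r, (lo, hi) in bundle.flux_bounds.items()
    ]
    pd.DataFrame(rows).to_csv(os.path.join(directory, "thermo.csv"), index=False)
    model, prof = make_ground_truth_model(bundle, seed=seed)
    config = bundle.default_config(prof)
    curves = generate_pseudo_experiment(
        model, config, noise_cv=bundle.spec.noise_cv, seed=seed
    )
    curves.to_csv(os.path.join(directory, "curves.csv"), index=False)
    with open(os.path.join(directory, "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "initial_biomass": config.initial_biomass,
                "medium": {k: float(v) for k, v in config.medium.items()},
                "t_end": config.t_end,
                "molar_masses": {k: float(v) for k, v in config.molar_masses.items()},
                "seed": seed,
                "topology": bundle.spec.topology,
            },
            fh,
        )
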