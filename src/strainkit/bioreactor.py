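"""Nonlinear batch-fermentation simulation and design evaluation.

The batch reactor couples the intracellular kinetic model to biomass and
extracellular dynamics:

    dX/dt  = mu * X                                    (biomass, gDW/L)
    dc/dt  = 1e-3 * (sum_r n_cr v_r) * X               (extracellular, mol/L)
    dx/dt  = c_x * N v  -  mu * x                      (intracellular, mol/L)

with specific fluxes v in mmol/gDW/h, mu the instantaneous biomass-reaction
flux (1/h), and ``c_x = 1e-3 / v_cell`` the mmol/gDW -> mol/L(cell volume)
conversion (default cell specific volume 1e-3 L/gDW, i.e. c_x = 1).  The
intracellular growth-dilution term is toggleable.  With dilution on, total
elemental mass (medium + intracellular + biomass pools) is conserved exactly
for elementally balanced networks.

Also here: applying intervention designs (enzyme activity fold changes),
regulation editing (e.g. making an inhibition-resistant enzyme), design
sensitivity analysis under expression uncertainty, Jaccard clustering of
design memberships, and nonlinear ranking of designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticModel
from .nra import InterventionDesign

__all__ = [
    "BioreactorConfig",
    "Trajectory",
    "SimulationError",
    "simulate_batch",
    "relax_intracellular",
    "steady_state_growth",
    "apply_design",
    "edit_regulation",
    "sensitivity_analysis",
    "cluster_designs",
    "rank_designs_nonlinear",
]


class SimulationError(RuntimeError):
    def __init__(self, msg: str, last_time: float | None = None):
        super().__init__(msg)
        self.last_time = last_time


@dataclass
class BioreactorConfig:
    initial_biomass: float  # gDW/L
    medium: dict[str, float]  # extracellular species -> mol/L
    t_end: float = 24.0  # h
    rtol: float = 1e-8
    atol: float = 1e-10
    n_points: int = 200
    molar_masses: dict[str, float] = field(default_factory=dict)  # g/mol
    dilution: bool = True
    volume_factor: float = 1.0  # c_x above
    exhaustion_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.initial_biomass < 0:
            raise ValueError("initial_biomass must be non-negative")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


@dataclass
class Trajectory:
    t: np.ndarray  # h
    biomass: np.ndarray  # gDW/L
    extracellular: dict[str, np.ndarray]  # mol/L
    intracellular: dict[str, np.ndarray]  # mol/L
    substrate_species: str | None
    product_species: str | None
    config: BioreactorConfig

    def series_gL(self, species: str) -> np.ndarray:
        mm = self.config.molar_masses.get(species)
        if mm is None:
            raise KeyError(f"no molar mass configured for {species!r}")
        return self.extracellular[species] * mm

    @property
    def final_biomass(self) -> float:
        return float(self.biomass[-1])

    def final_titer(self, species: str | None = None, as_gL: bool = True) -> float:
        species = species or self.product_species
        if as_gL and species in self.config.molar_masses:
            return float(self.series_gL(species)[-1])
        return float(self.extracellular[species][-1])

    @property
    def fermentation_time(self) -> float:
        """First time the substrate falls below ``exhaustion_frac`` of its
        initial level; inf if it never does."""
        if self.substrate_species is None:
            return float("inf")
        s = self.extracellular[self.substrate_species]
        thresh = self.config.exhaustion_frac * s[0]
        below = np.nonzero(s <= thresh)[0]
        return float(self.t[below[0]]) if below.size else float("inf")

    @property
    def productivity(self) -> float:
        """Final product titer divided by fermentation (or run) time, g/L/h."""
        t = self.fermentation_time
        if not np.isfinite(t):
            t = float(self.t[-1])
        return self.final_titer() / t if t > 0 else 0.0

    def time_to_titer_fraction(self, fraction: float = 0.9) -> float:
        p = self.extracellular[self.product_species]
        target = fraction * p.max()
        above = np.nonzero(p >= target)[0]
        return float(self.t[above[0]]) if above.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"t": self.t, "series": "biomass", "value": self.biomass})]
        for m, arr in self.extracellular.items():
            rows.append(pd.DataFrame({"t": self.t, "series": m, "value": arr}))
        for m, arr in self.intracellular.items():
            rows.append(pd.DataFrame({"t": self.t, "series": m, "value": arr}))
        return pd.concat(rows, ignore_index=True)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.biomass, label="biomass (gDW/L)")
        for m in self.extracellular:
            ax.plot(self.t, self.extracellular[m], label=m)
        ax.set_xlabel("time (h)")
        ax.legend(fontsize=7)
        return ax


def _dynamic_boundary_species(model: KineticModel, config: BioreactorConfig) -> list[str]:
    net = model.network
    return [
        m.id
        for m in net.metabolites
        if m.is_boundary and m.id in config.medium
    ]


def simulate_batch(model: KineticModel, config: BioreactorConfig) -> Trajectory:
    """Integrate a batch fermentation with a stiff (BDF) integrator."""
    net = model.network
    compiled = model.compiled
    met_ids = compiled.met_ids
    int_idx = compiled.internal_idx
    int_ids = [met_ids[i] for i in int_idx]
    dyn_ext = _dynamic_boundary_species(model, config)
    ext_pos = {m: met_ids.index(m) for m in dyn_ext}

    N_int = model._reduction()[0]
    # extracellular stoichiometry rows
    N_ext = np.zeros((len(dyn_ext), len(compiled.rxn_ids)))
    for j, r in enumerate(net.reactions):
        for m, c in r.stoichiometry.items():
            if m in ext_pos:
                N_ext[dyn_ext.index(m), j] = c
    bio_j = compiled.rxn_ids.index(net.biomass_reaction)
    e_vec = model._e_vec()
    theta = model._theta()
    x_full0 = model.anchor_x.copy()

    n_ext = len(dyn_ext)
    y0 = np.concatenate(
        [
            [config.initial_biomass],
            [config.medium[m] for m in dyn_ext],
            x_full0[int_idx],
        ]
    )
    cx = config.volume_factor

    def rhs(t, y):
        X = max(y[0], 0.0)
        x_full = x_full0.copy()
        for i, m in enumerate(dyn_ext):
            x_full[ext_pos[m]] = max(y[1 + i], 1e-12)
        x_full[int_idx] = np.maximum(y[1 + n_ext :], 1e-12)
        v = compiled.rates(x_full, e_vec, theta)
        mu = v[bio_j]
        dX = mu * X
        dext = 1e-3 * (N_ext @ v) * X
        dint = cx * (N_int @ v)
        if config.dilution:
            dint = dint - mu * x_full[int_idx]
        return np.concatenate([[dX], dext, dint])

    t_eval = np.linspace(0.0, config.t_end, config.n_points)
    sol = solve_ivp(
        rhs,
        (0.0, config.t_end),
        y0,
        method="BDF",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise SimulationError(
            f"stiff integration failed: {sol.message}",
            last_time=float(sol.t[-1]) if sol.t.size else 0.0,
        )
    upt = net.reaction(net.substrate_uptake)
    prod = net.reaction(net.objective_product)
    ext = net.extracellular_compartment
    sub_sp = next(
        (m for m in upt.substrates if net.metabolite(m).compartment == ext), None
    )
    prod_sp = next(
        (m for m in prod.products if net.metabolite(m).compartment == ext), None
    )
    return Trajectory(
        t=sol.t,
        biomass=sol.y[0],
        extracellular={m: sol.y[1 + i] for i, m in enumerate(dyn_ext)},
        intracellular={m: sol.y[1 + n_ext + i] for i, m in enumerate(int_ids)},
        substrate_species=sub_sp if sub_sp in dyn_ext else None,
        product_species=prod_sp if prod_sp in dyn_ext else None,
        config=config,
    )


# ---------------------------------------------------------------------------
# Intracellular-only integration (fixed boundary)
# ---------------------------------------------------------------------------

def relax_intracellular(
    model: KineticModel,
    x0_int: np.ndarray | None = None,
    t_end: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    volume_factor: float = 1.0,
    n_points: int = 100,
):
    """Integrate dx/dt = c_x N v at fixed boundary concentrations.

    Returns (t, x_int trajectory array n_int x n_points).  The anchor is a
    steady state of these dynamics, so relaxations measure the model's
    intrinsic time constants.
    """
    compiled = model.compiled
    int_idx = compiled.internal_idx
    x_full0 = model.anchor_x.copy()
    if x0_int is None:
        x0_int = x_full0[int_idx].copy()
    N_int = model._reduction()[0]
    e_vec = model._e_vec()
    theta = model._theta()

    def rhs(t, x):
        x_full = x_full0.copy()
        x_full[int_idx] = np.maximum(x, 1e-15)
        return volume_factor * (N_int @ compiled.rates(x_full, e_vec, theta))

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), x0_int, method="BDF", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"intracellular integration failed: {sol.message}")
    return sol.t, sol.y


def steady_state_growth(
    model: KineticModel, t_relax: float = 200.0, volume_factor: float = 1.0
) -> float:
    """Specific growth rate after relaxing the intracellular state to steady
    state at reference boundary conditions (e.g. after an intervention)."""
    _, y = relax_intracellular(model, t_end=t_relax, volume_factor=volume_factor)
    compiled = model.compiled
    x_full = model.anchor_x.copy()
    x_full[compiled.internal_idx] = np.maximum(y[:, -1], 1e-15)
    v = compiled.rates(x_full, model._e_vec(), model._theta())
    return float(v[compiled.rxn_ids.index(model.network.biomass_reaction)])


# ---------------------------------------------------------------------------
# Design application and regulation editing
# ---------------------------------------------------------------------------

def apply_design(model: KineticModel, design: InterventionDesign) -> KineticModel:
    """Scale enzyme activities per the design; one direction per enzyme.

    The anchor profile is retained as metadata but the anchoring identity no
    longer holds for the edited model.
    """
    seen = set()
    scale: dict[str, float] = {}
    for enzyme, direction, fold in design.interventions:
        if enzyme in seen:
            raise ValueError(f"enzyme {enzyme!r} appears twice in the design")
        seen.add(enzyme)
        if enzyme not in model.compiled.rxn_ids:
            raise KeyError(f"unknown enzyme {enzyme!r}")
        if fold < 1:
            raise ValueError(f"fold change must be >= 1, got {fold}")
        factor = fold if direction == "up" else 1.0 / fold
        scale[enzyme] = model.enzyme_scale.get(enzyme, 1.0) * factor
    return model.with_enzyme_scale(scale)


def edit_regulation(
    model: KineticModel,
    target: str,
    regulator: str,
    action: str = "remove",
    factor: float | None = None,
) -> KineticModel:
    """Remove or rescale one allosteric interaction's constant.

    ``remove`` sets the constant to 1e12 x the anchor regulator concentration
    (effectively inert, mirroring a feedback-resistant enzyme variant);
    ``scale`` multiplies it by ``factor``.
    """
    from dataclasses import replace as _replace

    regs = [r for r in model.network.regulations_of(target) if r.regulator == regulator]
    if not regs:
        raise KeyError(f"no regulation of {target!r} by {regulator!r}")
    kind = "Ka" if regs[0].mode == "activation" else "Ki"
    table = dict(getattr(model.params, kind))
    key = (target, regulator)
    if key not in table:
        raise KeyError(f"no {kind} constant for {key}")
    if action == "remove":
        table[key] = 1e12 * float(np.exp(model.anchor.ln_conc[regulator]))
    elif action == "scale":
        if factor is None or factor <= 0:
            raise ValueError("scale action needs a positive factor")
        table[key] = table[key] * factor
    else:
        raise ValueError(f"unknown action {action!r}")
    params = _replace(model.params, **{kind: table})
    return _replace(model, params=params)


# ---------------------------------------------------------------------------
# Sensitivity, clustering, nonlinear ranking
# ---------------------------------------------------------------------------

def sensitivity_analysis(
    models: list[KineticModel],
    design: InterventionDesign,
    config: BioreactorConfig,
    spread: float = 0.5,
    reps: int = 10,
    mode: str = "all",
    seed: int | np.random.Generator = 0,
) -> dict:
    """Perturb the design's fold changes by +/- ``spread`` (uniform) and
    collect titer statistics across (reps x models) trials.

    ``mode='all'`` perturbs every enzyme per trial; ``mode='each'`` runs one
    batch per enzyme, perturbing only that enzyme and pinning the others at
    their mean folds.  Failed integrations are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    enzymes = [e for e, _, _ in design.interventions]
    mean_fold = {e: f for e, _, f in design.interventions}
    direction = {e: d for e, d, _ in design.interventions}

    batches = [tuple(enzymes)] if mode == "all" else [(e,) for e in enzymes]
    if mode not in ("all", "each"):
        raise ValueError("mode must be 'all' or 'each'")
    records = []
    failures = 0
    for batch in batches:
        for mi, model in enumerate(models):
            for rep in range(reps):
                folds = {}
                for e in enzymes:
                    if e in batch and spread > 0:
                        folds[e] = rng.uniform(
                            mean_fold[e] * (1 - spread), mean_fold[e] * (1 + spread)
                        )
                    else:
                        folds[e] = mean_fold[e]
                trial = InterventionDesign(
                    interventions=tuple(
                        (e, direction[e], max(folds[e], 1.0)) for e in enzymes
                    ),
                    predicted_objective=design.predicted_objective,
                    source_model=design.source_model,
                )
                try:
                    traj = simulate_batch(apply_design(model, trial), config)
                except SimulationError:
                    failures += 1
                    continue
                records.append(
                    {
                        "batch": "+".join(batch),
                        "model": mi,
                        "rep": rep,
                        "final_titer": traj.final_titer(),
                        "final_biomass": traj.final_biomass,
                        **{f"fold_{e}": folds[e] for e in enzymes},
                    }
                )
    table = pd.DataFrame(records)
    means = (
        table.groupby("batch")[["final_titer", "final_biomass"]].mean()
        if len(table)
        else pd.DataFrame()
    )
    return {"trials": table, "mean_response": means, "n_failed": failures}


def cluster_designs(
    memberships: list[frozenset],
    n_clusters: int | None = None,
) -> np.ndarray:
    """Hierarchical (average-linkage) clustering of designs on Jaccard
    distance between their enzyme-set membership vectors; deterministic."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    if len(memberships) < 2:
        return np.ones(len(memberships), dtype=int)
    enzymes = sorted({item for mem in memberships for item in mem})
    B = np.array(
        [[1.0 if e in mem else 0.0 for e in enzymes] for mem in memberships]
    )
    D = pdist(B, metric="jaccard")
    if np.all(D == 0):
        return np.ones(len(memberships), dtype=int)
    Z = linkage(D, method="average")
    if n_clusters is not None:
        return fcluster(Z, t=n_clusters, criterion="maxclust")
    # default cut: largest gap between successive merge heights
    heights = Z[:, 2]
    if len(heights) == 1:
        return fcluster(Z, t=1, criterion="maxclust")
    gaps = np.diff(heights)
    cut = (heights[np.argmax(gaps)] + heights[np.argmax(gaps) + 1]) / 2
    return fcluster(Z, t=cut, criterion="distance")


def rank_designs_nonlinear(
    models: list[KineticModel],
    designs: list[InterventionDesign],
    config: BioreactorConfig,
    reference_time: float | None = None,
) -> pd.DataFrame:
    """Simulate every design on every model and rank by median titer at the
    reference fermentation time (productivity breaks ties)."""
    rows = []
    for di, design in enumerate(designs):
        titers, prods, t90s = [], [], []
        for model in models:
            try:
                traj = simulate_batch(apply_design(model, design), config)
            except SimulationError:
                continue
            if reference_time is not None:
                idx = np.searchsorted(traj.t, reference_time)
                idx = min(idx, len(traj.t) - 1)
                mm = config.molar_masses.get(traj.product_species, 1.0)
                titers.append(traj.extracellular[traj.product_species][idx] * mm)
            else:
                titers.append(traj.final_titer())
            prods.append(traj.productivity)
            t90s.append(traj.time_to_titer_fraction(0.9))
        rows.append(
            {
                "design": di,
                "label": "+".join(
                    f"{e}{'^' if d == 'up' else 'v'}" for e, d, _ in design.interventions
                )
                or "(reference)",
                "median_titer": float(np.median(titers)) if titers else np.nan,
                "iqr_titer": float(np.subtract(*np.percentile(titers, [75, 25])))
                if titers
                else np.nan,
                "median_productivity": float(np.median(prods)) if prods else np.nan,
                "median_t90": float(np.median(t90s)) if t90s else np.nan,
                "n_models": len(titers),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["median_titer", "median_productivity"], ascending=False
    ).reset_index(drop=True)
    return table
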