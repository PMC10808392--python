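"""Ensemble screening by dynamics, data fit, and robustness.

A sampled kinetic model is kept for strain design only if it

1. is locally stable with a dominant time constant well below the cell's
   doubling time (linearized dynamics; structural zero eigenvalues from
   conserved moieties are removed first),
2. damps out finite ("k-fold") concentration perturbations,
3. reproduces batch-fermentation observations (final growth and product
   titer, fermentation time), and
4. keeps growing under random enzyme-expression noise.

Each criterion is a pure predicate on a model, so the retained set does not
depend on the order the screens are applied in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioreactor import (
    BioreactorConfig,
    SimulationError,
    relax_intracellular,
    simulate_batch,
)
from .kinetics import KineticModel

__all__ = [
    "EigenSummary",
    "ScreeningReport",
    "compute_jacobian",
    "dominant_time_constant",
    "recovery_fraction",
    "doubling_time",
    "screen_linear_dynamics",
    "screen_concentration_robustness",
    "screen_fermentation_fit",
    "screen_enzyme_robustness",
]


@dataclass
class EigenSummary:
    eigenvalues: np.ndarray  # 1/h
    dominant_time_constant: float  # h; inf if unstable
    n_structural_zeros: int
    stable: bool


@dataclass
class ScreeningReport:
    """Per-model pass/fail per criterion plus the metrics behind them."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def retained(self) -> list[int]:
        crit = [c for c in self.table.columns if c.startswith("pass_")]
        mask = self.table[crit].all(axis=1)
        return list(self.table.index[mask])


def compute_jacobian(model: KineticModel, volume_factor: float = 1.0) -> np.ndarray:
    """Reduced Jacobian N_R (dv/dx) L at the anchor (independent internal
    species only, conserved-moiety zero eigenvalues removed)."""
    return model.jacobian_reduced(volume_factor=volume_factor)


def dominant_time_constant(eigenvalues: np.ndarray) -> float:
    """tau_d = 1 / min_i |Re(lambda_i)|; inf (unstable flag) if any
    Re(lambda) >= 0."""
    eigenvalues = np.asarray(eigenvalues)
    if eigenvalues.size == 0:
        return 0.0
    re = eigenvalues.real
    if re.max() >= 0:
        return float("inf")
    return float(1.0 / np.abs(re).min())


def eigen_summary(model: KineticModel, volume_factor: float = 1.0) -> EigenSummary:
    J = compute_jacobian(model, volume_factor)
    eig = np.linalg.eigvals(J) if J.size else np.array([])
    tau = dominant_time_constant(eig)
    return EigenSummary(
        eigenvalues=eig,
        dominant_time_constant=tau,
        n_structural_zeros=model.n_conserved(),
        stable=math.isfinite(tau),
    )


def recovery_fraction(t: float, tau: float) -> float:
    """Fraction 1 - exp(-t/tau) of a linear relaxation completed by time t
    (e.g. 0.993 after five dominant time constants)."""
    if t <= 0 or tau <= 0:
        raise ValueError("t and tau must be positive")
    return 1.0 - math.exp(-t / tau)


def doubling_time(mu: float) -> float:
    """ln(2)/mu in minutes for a growth rate in 1/h."""
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / mu * 60.0


def screen_linear_dynamics(
    models: list[KineticModel],
    tau_max: float,
    volume_factor: float = 1.0,
) -> tuple[list[int], list[EigenSummary]]:
    """Retain stable models with dominant time constant < ``tau_max`` hours.

    The reference policy sets tau_max to a fifth of the doubling time so
    relaxations reach ~99.3% completion within one generation.
    """
    summaries = [eigen_summary(m, volume_factor) for m in models]
    retained = [
        i
        for i, s in enumerate(summaries)
        if s.stable and s.dominant_time_constant < tau_max
    ]
    return retained, summaries


def screen_concentration_robustness(
    model: KineticModel,
    k_fold: float = 2.0,
    n: int = 10,
    horizon: float = 10.0,
    seed: int | np.random.Generator = 0,
    band: float = 0.01,
    volume_factor: float = 1.0,
) -> bool:
    """True iff ``n`` random k-fold concentration perturbations all relax
    back to within ``band`` (relative) of the anchor by the horizon.

    Each internal species is scaled by ``k_fold**u`` with u drawn from
    {-1, +1}.  Integrator failures count as a failed trial.
    """
    rng = np.random.default_rng(seed)
    compiled = model.compiled
    x_ref = model.anchor_x[compiled.internal_idx]
    for _ in range(n):
        u = rng.choice([-1.0, 1.0], size=x_ref.size)
        x0 = x_ref * np.power(k_fold, u)
        try:
            _, y = relax_intracellular(
                model, x0_int=x0, t_end=horizon, volume_factor=volume_factor
            )
        except SimulationError:
            return False
        rel = np.abs(y[:, -1] - x_ref) / np.maximum(np.abs(x_ref), 1e-30)
        if rel.max() > band:
            return False
    return True


def screen_fermentation_fit(
    model: KineticModel,
    data: pd.DataFrame,
    config: BioreactorConfig,
    tol_biomass: float = 0.05,
    tol_product: float = 0.10,
    t_max: float = 20.0,
) -> tuple[bool, dict]:
    """Batch-simulate the model and compare with fermentation curves.

    ``data`` needs columns ``time``, ``biomass`` (gDW/L) and ``product``
    (g/L).  Pass iff the simulated final biomass and final product titer are
    within the stated relative tolerances of the data's final values and the
    substrate is exhausted before ``t_max`` hours.
    """
    t = data["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    try:
        traj = simulate_batch(model, config)
    except SimulationError as exc:
        return False, {"error": str(exc)}
    bio_ref = float(data["biomass"].iloc[-1])
    prod_ref = float(data["product"].iloc[-1])
    bio_sim = traj.final_biomass
    prod_sim = traj.final_titer()
    err_bio = abs(bio_sim - bio_ref) / abs(bio_ref) if bio_ref else float("inf")
    err_prod = abs(prod_sim - prod_ref) / abs(prod_ref) if prod_ref else float("inf")
    t_ferm = traj.fermentation_time
    ok = (err_bio <= tol_biomass) and (err_prod <= tol_product) and (t_ferm < t_max)
    return ok, {
        "final_biomass": bio_sim,
        "final_product": prod_sim,
        "err_biomass": err_bio,
        "err_product": err_prod,
        "fermentation_time": t_ferm,
    }


def screen_enzyme_robustness(
    model: KineticModel,
    config: BioreactorConfig,
    cv: float = 0.10,
    n: int = 50,
    growth_floor: float = 0.5,
    seed: int | np.random.Generator = 0,
    reference_biomass: float | None = None,
) -> bool:
    """True iff all ``n`` random expression perturbations (each enzyme's
    Vmax scaled by 1 + N(0, cv^2)) still reach at least ``growth_floor`` of
    the reference final biomass in a batch simulation."""
    rng = np.random.default_rng(seed)
    if reference_biomass is None:
        reference_biomass = simulate_batch(model, config).final_biomass
    rxns = model.compiled.rxn_ids
    for _ in range(n):
        factors = 1.0 + cv * rng.standard_normal(len(rxns))
        factors = np.clip(factors, 1e-3, None)
        perturbed = model.with_enzyme_scale(
            {r: model.enzyme_scale.get(r, 1.0) * f for r, f in zip(rxns, factors)}
        )
        try:
            traj = simulate_batch(perturbed, config)
        except SimulationError:
            return False
        if traj.final_biomass < growth_floor * reference_biomass:
            return False
    return True


def screen_ensemble(
    models: list[KineticModel],
    tau_max: float,
    data: pd.DataFrame | None = None,
    config: BioreactorConfig | None = None,
    cv: float = 0.10,
    n_enzyme_trials: int = 50,
    growth_floor: float = 0.5,
    seed: int = 0,
    tol_biomass: float = 0.05,
    tol_product: float = 0.10,
    t_max: float = 20.0,
    volume_factor: float = 1.0,
) -> ScreeningReport:
    """Run all applicable screens over an ensemble and tabulate the result."""
    rows = []
    retained_lin, summaries = screen_linear_dynamics(models, tau_max, volume_factor)
    lin_set = set(retained_lin)
    for i, model in enumerate(models):
        row = {
            "model": model.model_id or str(i),
            "tau_d": summaries[i].dominant_time_constant,
            "pass_linear_dynamics": i in lin_set,
        }
        if data is not None and config is not None:
            if i in lin_set:
                ok, metrics = screen_fermentation_fit(
                    model, data, config, tol_biomass, tol_product, t_max
                )
                row["pass_fermentation_fit"] = ok
                row.update(metrics)
                if ok:
                    row["pass_enzyme_robustness"] = screen_enzyme_robustness(
                        model,
                        config,
                        cv=cv,
                        n=n_enzyme_trials,
                        growth_floor=growth_floor,
                        seed=seed + i,
                        reference_biomass=metrics.get("final_biomass"),
                    )
                else:
                    row["pass_enzyme_robustness"] = False
            else:
                row["pass_fermentation_fit"] = False
                row["pass_enzyme_robustness"] = False
        rows.append(row)
    return ScreeningReport(table=pd.DataFrame(rows))
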