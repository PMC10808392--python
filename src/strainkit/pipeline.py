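"""End-to-end orchestration: profiles -> models -> screens -> designs.

Convenience driver used by the command line, the examples, and the
validation studies; every stage simply delegates to the corresponding
module, so custom pipelines can be assembled from the parts directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioreactor import BioreactorConfig, rank_designs_nonlinear
from .fixtures import FixtureBundle, generate_pseudo_experiment, make_ground_truth_model
from .kinetics import KineticModel, assign_rate_laws, sample_kinetic_models
from .mca import control_coefficients
from .nra import (
    NRABounds,
    InterventionDesign,
    build_nra_problem,
    designable_enzymes,
    enumerate_designs,
    rank_designs,
)
from .screening import screen_ensemble
from .thermo import SteadyStateProfile, sample_steady_states

__all__ = ["PipelineResult", "run_strain_design"]


@dataclass
class PipelineResult:
    profiles: list[SteadyStateProfile]
    models: list[KineticModel]
    retained: list[KineticModel]
    screening_table: pd.DataFrame
    ranked_designs: list[dict]
    nonlinear_table: pd.DataFrame | None
    config: BioreactorConfig
    data: pd.DataFrame

    @property
    def top_design(self) -> dict | None:
        return self.ranked_designs[0] if self.ranked_designs else None


def run_strain_design(
    bundle: FixtureBundle,
    seed: int = 0,
    n_profiles: int = 3,
    per_profile: int = 5,
    bounds: NRABounds = NRABounds(),
    tolerance: float = 0.05,
    max_designs: int = 20,
    top_k: int = 5,
    n_robustness_trials: int = 5,
    min_retained: int = 2,
    nonlinear_rank: bool = True,
) -> PipelineResult:
    """Full study on a fixture bundle, seeded and deterministic.

    Steps: sample near-maximal-growth steady states; build a stability-pruned
    kinetic ensemble; screen against pseudo-experimental fermentation curves
    generated from the bundle's ground-truth model; compute control
    coefficients per retained model; enumerate NRA designs within
    ``tolerance`` of each model's optimum; rank unique designs by mean
    cross-model objective; optionally re-rank the top designs in nonlinear
    batch simulations.
    """
    rng = np.random.default_rng(seed)
    net, thermo = bundle.network, bundle.thermo
    profiles = sample_steady_states(
        net, thermo, bundle.flux_bounds, n=n_profiles,
        seed=int(rng.integers(2**31)),
    )
    assignment = assign_rate_laws(net)
    models = sample_kinetic_models(
        net, assignment, thermo, profiles, per_profile,
        seed=int(rng.integers(2**31)),
    )
    gt_model, gt_prof = make_ground_truth_model(bundle, seed=int(rng.integers(2**31)))
    config = bundle.default_config(gt_prof)
    data = generate_pseudo_experiment(
        gt_model, config, noise_cv=bundle.spec.noise_cv,
        seed=int(rng.integers(2**31)),
    )
    tau_max = math.log(2.0) / gt_prof.growth_rate / 5.0
    report = screen_ensemble(
        models, tau_max, data=data, config=config,
        n_enzyme_trials=n_robustness_trials,
        seed=int(rng.integers(2**31)),
    )
    retained = [models[i] for i in report.retained]
    if len(retained) < min_retained:
        # fall back to the models passing the dynamic screens only, so small
        # ensembles still yield a design study
        mask = report.table["pass_linear_dynamics"] & (
            report.table.get("pass_fermentation_fit", True)
        )
        retained = [models[i] for i in report.table.index[mask]] or models

    designable = designable_enzymes(net)
    problems, enums = [], []
    for m in retained:
        cc = control_coefficients(m)
        prob = build_nra_problem(
            cc, bounds, growth_id=net.biomass_reaction,
            designable=designable, model_id=m.model_id,
        )
        problems.append(prob)
        enums.append(enumerate_designs(prob, tolerance=tolerance, max_designs=max_designs))
    ranked = rank_designs(enums, problems, top_k=top_k)

    nonlinear = None
    if nonlinear_rank and ranked:
        designs = []
        for rec in ranked:
            folds = _mean_folds(rec["membership"], enums)
            designs.append(
                InterventionDesign(
                    interventions=tuple(
                        (e, d, folds.get((e, d), 2.0)) for e, d in sorted(rec["membership"])
                    ),
                    predicted_objective=rec["mean_objective"],
                )
            )
        nonlinear = rank_designs_nonlinear(retained, designs, config)
    return PipelineResult(
        profiles=profiles,
        models=models,
        retained=retained,
        screening_table=report.table,
        ranked_designs=ranked,
        nonlinear_table=nonlinear,
        config=config,
        data=data,
    )


def _mean_folds(membership: frozenset, enums) -> dict[tuple[str, str], float]:
    """Mean fold change per (enzyme, direction) over all enumerated designs
    carrying that membership."""
    acc: dict[tuple[str, str], list[float]] = {}
    for enum in enums:
        for d in enum.designs:
            if d.membership == membership:
                for e, direction, fold in d.interventions:
                    acc.setdefault((e, direction), []).append(fold)
    return {k: float(np.mean(v)) for k, v in acc.items()}
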