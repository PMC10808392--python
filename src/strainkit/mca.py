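"""Metabolic control analysis: elasticities and control coefficients.

At the anchoring steady state, the scaled elasticity of reaction k to
species i is ``E_x[k,i] = d ln v_k / d ln x_i``; with one enzyme per
reaction and enzyme-proportional laws the enzyme elasticity matrix ``Pi``
is the identity.  The system-level control coefficients follow from the
log-linear steady-state balance on the independent internal species:

    C_x(ind) = -(N_R V E_x L)^-1 N_R V Pi,      C_v = E_x L C_x(ind) + Pi

with V the diagonal of the anchor fluxes, N_R the independent rows of the
internal stoichiometric matrix, and L the conserved-moiety link matrix
rescaled into log-concentration space.  The summation theorems (flux rows
sum to 1, concentration rows to 0) hold because N_R v = 0 at the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticModel

__all__ = [
    "ElasticityMatrices",
    "ControlCoefficients",
    "SingularControlError",
    "elasticity_matrix",
    "control_coefficients",
    "top_k_targets",
    "near_equilibrium_report",
]


class SingularControlError(RuntimeError):
    """The log-linear system matrix is singular; the model cannot be used
    for control-coefficient-based design."""


@dataclass
class ElasticityMatrices:
    E_x: np.ndarray  # reactions x internal species, d ln v / d ln x
    Pi: np.ndarray  # reactions x enzymes, d ln v / d ln e
    reaction_ids: list[str]
    species_ids: list[str]
    enzyme_ids: list[str]
    absolute_scale_rows: list[str] = field(default_factory=list)


@dataclass
class ControlCoefficients:
    C_v: np.ndarray  # reactions x enzymes
    C_x: np.ndarray  # internal species x enzymes
    C_yield: np.ndarray  # enzymes
    reaction_ids: list[str]
    species_ids: list[str]
    enzyme_ids: list[str]
    product_id: str
    substrate_id: str

    def flux_row(self, rid: str) -> np.ndarray:
        return self.C_v[self.reaction_ids.index(rid)]

    def yield_series(self) -> pd.Series:
        return pd.Series(self.C_yield, index=self.enzyme_ids, name="C_yield")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cv = pd.DataFrame(self.C_v, index=self.reaction_ids, columns=self.enzyme_ids)
        cx = pd.DataFrame(self.C_x, index=self.species_ids, columns=self.enzyme_ids)
        return cv, cx


def elasticity_matrix(model: KineticModel, zero_flux_tol: float = 1e-9) -> ElasticityMatrices:
    """Analytic scaled elasticities at the anchor.

    Rows of reactions with (near-)zero anchor flux cannot be log-scaled; they
    fall back to the absolute-scale derivative ``x_i * dv/dx_i`` and are
    flagged in ``absolute_scale_rows``.
    """
    compiled = model.compiled
    x = model.anchor_x
    v = model.anchor_v
    dvdx = model.dvdx_internal(x)
    x_int = x[compiled.internal_idx]
    species = [compiled.met_ids[i] for i in compiled.internal_idx]
    E = dvdx * x_int[None, :]
    flagged = []
    for k, rid in enumerate(compiled.rxn_ids):
        if abs(v[k]) > zero_flux_tol:
            E[k, :] /= v[k]
        else:
            flagged.append(rid)
    return ElasticityMatrices(
        E_x=E,
        Pi=np.eye(len(compiled.rxn_ids)),
        reaction_ids=list(compiled.rxn_ids),
        species_ids=species,
        enzyme_ids=list(compiled.rxn_ids),
        absolute_scale_rows=flagged,
    )


def control_coefficients(
    model: KineticModel,
    elasticities: ElasticityMatrices | None = None,
    cond_max: float = 1e12,
) -> ControlCoefficients:
    """Flux and concentration control coefficients w.r.t. enzyme activities."""
    if elasticities is None:
        elasticities = elasticity_matrix(model)
    E_x, Pi = elasticities.E_x, elasticities.Pi
    v = model.anchor_v
    _, N_R, L, indep = model._reduction()
    compiled = model.compiled
    x_int = model.anchor_x[compiled.internal_idx]
    x_ind = x_int[indep]
    # link matrix rescaled to log space: d ln x = L_z d ln x_ind
    L_z = L * x_ind[None, :] / x_int[:, None]
    V = np.diag(v)
    M = N_R @ V @ E_x @ L_z
    if M.size:
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > cond_max:
            raise SingularControlError(
                f"log-linear system matrix is singular (cond={cond:.3g})"
            )
        B = N_R @ V @ Pi
        C_x_ind = -np.linalg.solve(M, B)
        # one step of iterative refinement: ill-conditioned near-equilibrium
        # elasticities otherwise erode the summation theorems
        resid = M @ C_x_ind + B
        C_x_ind -= np.linalg.solve(M, resid)
    else:
        C_x_ind = np.zeros((0, Pi.shape[1]))
    C_x = L_z @ C_x_ind
    C_v = E_x @ C_x + Pi
    net = model.network
    i_p = elasticities.reaction_ids.index(net.objective_product)
    i_s = elasticities.reaction_ids.index(net.substrate_uptake)
    return ControlCoefficients(
        C_v=C_v,
        C_x=C_x,
        C_yield=C_v[i_p] - C_v[i_s],
        reaction_ids=list(elasticities.reaction_ids),
        species_ids=list(elasticities.species_ids),
        enzyme_ids=list(elasticities.enzyme_ids),
        product_id=net.objective_product,
        substrate_id=net.substrate_uptake,
    )


def top_k_targets(
    cc: ControlCoefficients,
    objective: str = "yield",
    k: int = 3,
    flux_id: str | None = None,
    exclude: set[str] | None = None,
) -> list[tuple[str, str, float]]:
    """Enzymes ranked by |control coefficient|, with intervention direction.

    Returns ``[(enzyme, 'up'|'down', coefficient), ...]``; a positive
    coefficient recommends upregulation.  Ties break lexicographically.
    """
    if objective == "yield":
        coef = cc.C_yield
    elif objective == "flux":
        coef = cc.flux_row(flux_id or cc.product_id)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    exclude = exclude or set()
    order = sorted(
        (e for e in cc.enzyme_ids if e not in exclude),
        key=lambda e: (-abs(coef[cc.enzyme_ids.index(e)]), e),
    )
    out = []
    for e in order[:k]:
        c = coef[cc.enzyme_ids.index(e)]
        out.append((e, "up" if c >= 0 else "down", float(c)))
    return out


def near_equilibrium_report(
    model: KineticModel, threshold: float = 1.25
) -> pd.DataFrame:
    """Reactions operating within ``threshold`` kcal/mol of equilibrium.

    Such reactions carry large elasticities and exert little flux control;
    the report helps interpret designs that skip them.
    """
    rows = []
    for rid, g in model.anchor.dG.items():
        rows.append(
            {
                "reaction": rid,
                "dG_prime": g,
                "displacement": model.anchor.displacement(rid, model.thermo.RT),
                "near_equilibrium": abs(g) < threshold,
            }
        )
    return pd.DataFrame(rows).set_index("reaction")
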