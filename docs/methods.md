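# Methods

`strainkit` implements a rational strain-design workflow built on ensembles
of nonlinear kinetic models of metabolism.  The design philosophy is that an
engineered strain should deviate as little as possible from the reference
phenotype: intervention targets are chosen by a mixed-integer program over
metabolic control coefficients that bounds the network-wide response, and the
surviving candidates are validated in nonlinear batch-fermentation
simulations.

## 1. Thermodynamics-based steady-state sampling

Reference steady states are drawn from the polytope

    N v = 0,   v_lb <= v <= v_ub,   ln x_lb <= ln x <= ln x_hi,
    dG'_r = dG'0_r + RT sum_i n_ir ln x_i,   sign(v_r) dG'_r < 0,

with one binary direction indicator per reaction that carries a standard
Gibbs energy, and per-reaction big-M constants derived from the bounds.  The
strict second-law inequality is made MILP-representable by a minimum
displacement `|dG'| >= 1e-3 kcal/mol`.  This constant is also the sampler's
*thermodynamic resolution*: log-linear elasticities of a reversible reaction
scale like RT/|dG'|, so the floor caps them near ~600 and keeps the
control-coefficient linear systems well conditioned.  Per-reaction floors can
be raised (e.g. to 1.25 kcal/mol) to force a specific enzyme away from
equilibrium — a near-equilibrium enzyme exerts essentially no flux control
and is therefore undesignable, which is why the feedback-branch fixture
applies such a floor to its planted bottleneck.

Samples are vertices found by optimising random objective directions over
fluxes and log-concentrations at >= 80% of the maximal growth rate (the
reference condition for all studies here).  Vertex solutions are repaired by
orthogonal projection onto the null space of the internal stoichiometric
matrix so that mass balance holds to ~1e-12 rather than the solver's 1e-7
feasibility tolerance.  RT defaults to 0.5925 kcal/mol (298.15 K);
concentration bounds default to 1e-8–0.1 mol/L when a species has none.
All MILPs and LPs go through HiGHS (scipy.optimize.milp/linprog) with a
relative MIP gap of 1e-9.

## 2. Rate laws and parameter back-calculation

Every reversible law is written in displacement form

    v = e * Vmax * psi_s * (1 - Gamma) / D,     Gamma = exp(dG'/RT),

where `psi_s = prod (s/Km)^a` and `D` is the law-specific denominator
(generalized reversible Hill with h=1 by default, i.e. reversible
Michaelis–Menten; convenience kinetics for multi-substrate reactions;
mass action, without a saturable denominator, for transports into the
extracellular compartment).  This form satisfies the Haldane relation
identically for any positive Km, vanishes exactly at equilibrium, and always
carries flux down the Gibbs gradient — the thermodynamic sign consistency the
tests assert on random states.  Allosteric regulation multiplies the core
law: competitive inhibitors add `i/Ki` to `D`, uncompetitive inhibitors scale
by `1/(1+i/Ki)`, mixed inhibition does both with one constant, activation
contributes `(a/Ka)/(1+a/Ka)`.  Listing the same activation twice squares the
factor; the bistable fixture uses this to obtain a sigmoidal autocatalysis.

Parameters are back-calculated from the anchoring steady state: each binding
site gets a saturation `sigma ~ U(0.01, 0.99)` and `K = x_ss (1-sigma)/sigma`;
Vmax (or the mass-action k) is then solved in closed form so the rate at the
anchor concentrations equals the anchor flux exactly.  A reaction whose
anchor flux is exactly zero receives Vmax = 0 (the fixtures avoid this by
giving every enzymatic step a small flux floor of 0.01 mmol/gDW/h, i.e. every
enzyme stays expressed in every sample).  One steady-state profile plus one
saturation draw is one kinetic model; ensembles keep a configurable number of
models per profile whose reduced Jacobian has all eigenvalue real parts
negative.  Rate vectors and their concentration Jacobians are sympy
expressions compiled once per (network, law assignment) with concentrations,
enzyme activities, and parameters as arguments, so thousand-model ensembles
evaluate in milliseconds; central finite differences serve as the test
oracle for all derivatives.

## 3. Model screening

Conserved moieties are removed with a link-matrix reduction (`N = L N_R`,
independent rows chosen greedily by rank with a 1e-9 tolerance) before any
eigenvalue analysis, so structural zeros never masquerade as slow dynamics.
The screens, each a pure predicate on a model:

* **Linearized dynamics** — dominant time constant
  `tau_d = 1/min_i |Re lambda_i|` below a threshold; the default policy is a
  fifth of the doubling time (`ln 2 / mu`), so relaxations are ~99.3%
  complete within one generation; 24- and 43-minute presets correspond to
  99.5%/95% recovery at a 130-minute doubling time.
* **Concentration robustness** — each internal species scaled by
  `k^±1` (sign uniform per species); pass iff every trial returns to within
  1% of the anchor by the horizon.  Used when no fermentation data exist.
* **Fermentation reproduction** — batch simulation must hit the observed
  final biomass within 5%, final product titer within 10%, and exhaust the
  substrate (below 1% of its initial level) within 20 h.
* **Enzyme robustness** — 50 trials with every Vmax scaled by
  `1 + N(0, 0.1^2)`; pass iff all retain >= 50% of the reference final
  biomass.  (The end-to-end fixture studies use 5–10 trials to keep a
  ten-run study at desk scale; the single-model screens use the full 50.)

## 4. Control analysis

Scaled elasticities `E_x = d ln v / d ln x` are evaluated analytically at
the anchor (rows with zero anchor flux fall back to absolute scale and are
flagged).  With one enzyme per reaction (`Pi = I`), concentration and flux
control coefficients follow from

    C_x = -(N_R V E_x L_z)^-1 N_R V Pi,     C_v = E_x L_z C_x + Pi,

with `V = diag(v_ss)` and `L_z` the link matrix rescaled to log space.  One
step of iterative refinement is applied to the linear solve; the summation
theorems (flux rows sum to 1, concentration rows to 0) then hold to ~1e-10
across ensembles.  The yield control vector is
`C_yield = C_v[product] - C_v[uptake]`.

## 5. Intervention design (NRA)

The design MILP selects up to `max_interventions` enzymes with log activity
changes `u_j - d_j` (up to ln 5 up; "unrestricted" downregulation is encoded
as a finite 100-fold cap, configurable, since a MILP needs a finite big-M),
maximising `(C_v[product] - C_v[uptake]) . (u - d)` subject to

* every internal log-concentration response within ln(conc_fold), default 3,
* growth reduced by at most 20%,
* optional per-flux bounds (off by default),
* a 1e-6 minimum log change for any selected enzyme (membership epsilon).

A second preset (10-fold activity, 2.5-fold concentrations) mirrors a
relaxed-activity study design.  Alternatives within 5% of the optimum are
enumerated with integer cuts that exclude the exact signed (enzyme,
direction) support; designs are identified by that support, scored across a
model ensemble by the mean objective with non-members pinned to zero, and
ranked (lexicographic tie-break).  Designable enzymes default to
non-transport, non-exchange, non-biomass reactions.

## 6. Bioreactor coupling and units

    dX/dt = mu X,   dc/dt = 1e-3 (N_ext v) X,   dx/dt = c_x N v - mu x,

with fluxes in mmol/gDW/h, extracellular concentrations in mol/L, biomass in
gDW/L, and mu read directly from the biomass-reaction flux (1/h; no separate
Monod layer).  `c_x = 1e-3 / v_cell` converts specific rates to
intracellular mol/L/h; the default cell specific volume of 1e-3 L/gDW makes
`c_x = 1`.  The intracellular dilution term `-mu x` is on by default and
toggleable; with it on, total elemental mass (medium + cell pools + biomass)
is conserved exactly on elementally balanced networks, which the
carbon-closed fixture verifies to 0.1%.  Integration uses BDF with
rtol 1e-8 / atol 1e-10.  Fermentation time is the first time the substrate
falls below 1% of its initial level; titers are reported in g/L via
configured molar masses; productivity is titer over fermentation time.

Design application scales enzyme activities (one direction per enzyme);
regulation editing sets an inhibition constant to 1e12 x the anchor
regulator concentration ("remove", emulating a feedback-resistant enzyme) or
multiplies it by a factor.  Sensitivity analysis perturbs the mean design
folds by ±50% uniformly, either all enzymes at once or one at a time, with
10 repetitions per model.  Design memberships are clustered by average-
linkage hierarchical clustering on Jaccard distances; without a requested
cluster count the tree is cut at the largest merge-height gap.

## 7. Synthetic fixtures — what they emulate and what they do not

The fixtures stand in for a reduced metabolic model of a production strain
plus triplicate batch-fermentation data.  They are 5–11 reaction,
two-compartment networks with substrate uptake, a secreted product, a lumped
biomass reaction, and, by topology: a regulated branch point whose
product-branch entry is competitively inhibited by the competing branch's
end product (the planted bottleneck, mimicking feedback inhibition of a
pathway-entry synthase), an ATP/ADP conserved pair, an engineered bistable
autocatalysis, and a carbon-closed chain.  Pseudo-experiments subsample ~10
time points and add multiplicative Gaussian noise (cv 5%, 3 replicates).

What passing on these fixtures shows: the machinery is internally consistent
(anchoring, thermodynamic signs, control theorems, MILP optimality against
exhaustive search) and the workflow's scientific claims hold where the
ground truth is known (planted bottlenecks are recovered; proximity
constraints preserve growth where naive top-k control designs need not).
What it does not show: quantitative behaviour on genome-scale reductions
with dozens of regulatory interactions, realistic parameter identifiability,
or the error structure of real fermentation assays.

## 8. Numerical choices and limitations

* Study sizes (3 profiles x 5 models per profile per run; 1000-model
  anchoring sweeps; 10-seed recovery studies) are chosen to keep a complete
  study on one desk-scale CPU core while leaving each statistic
  well-resolved.
* HiGHS vertex sampling yields deterministic, reproducible ensembles but
  explores vertices only; an optional hit-and-run refinement of interior
  points is deliberately out of scope.
* The relaxation-time oracle perturbs along the slowest eigenvector and fits
  the decay tail over [3, 7] dominant time constants; models whose dominant
  eigenvalue pair is strongly oscillatory (|Im| > 0.2 |Re|) would need an
  envelope fit instead and are excluded from that comparison.
* Control coefficients are computed per model, never on a consensus
  linearisation; rankings across models use the per-model MILPs.
* Unbounded downregulation, gene-level (as opposed to enzyme-level)
  interventions, knock-ins, fed-batch/chemostat operation, and pH/oxygen
  dynamics are out of scope.
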