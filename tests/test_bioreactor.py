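"""Batch fermentation, design application, sensitivity, clustering, ranking."""

import numpy as np
import pytest

from strainkit.bioreactor import (
    BioreactorConfig,
    apply_design,
    cluster_designs,
    edit_regulation,
    rank_designs_nonlinear,
    sensitivity_analysis,
    simulate_batch,
    steady_state_growth,
)
from strainkit.nra import InterventionDesign


def _design(*triples):
    return InterventionDesign(interventions=tuple(triples), predicted_objective=0.0)


class TestSimulateBatch:
    def test_zero_inoculum_freezes_extracellular_state(self, feedback_bundle,
                                                       feedback_gt):
        model, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        config.initial_biomass = 0.0
        traj = simulate_batch(model, config)
        assert np.all(traj.biomass == 0.0)
        for arr in traj.extracellular.values():
            assert arr[-1] == pytest.approx(arr[0], abs=1e-12)

    def test_initial_rates_equal_anchor_fluxes(self, feedback_bundle, feedback_gt):
        """Coupling consistency: at t=0 under anchor conditions the model's
        specific rates are exactly the anchor fluxes."""
        model, prof = feedback_gt
        v0 = model.rates(model.anchor_x)
        assert v0 == pytest.approx(model.anchor_v, rel=1e-10)

    def test_resimulation_is_bitwise_reproducible(self, feedback_bundle,
                                                  feedback_gt):
        model, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        a = simulate_batch(model, config)
        b = simulate_batch(model, config)
        assert np.array_equal(a.biomass, b.biomass)
        for sp in a.extracellular:
            assert np.array_equal(a.extracellular[sp], b.extracellular[sp])

    def test_biomass_grows_until_substrate_exhaustion(self, feedback_bundle,
                                                      feedback_gt):
        model, prof = feedback_gt
        traj = simulate_batch(model, feedback_bundle.default_config(prof))
        t_f = traj.fermentation_time
        growing = traj.t < t_f
        dX = np.diff(traj.biomass[growing])
        assert np.all(dX > -1e-10)
        assert traj.final_biomass > 10 * traj.biomass[0]

    def test_carbon_conservation_audit(self, carbon_bundle, carbon_gt):
        """Total carbon in medium + intracellular pools + biomass stays
        within 0.1% over the whole run (elementally closed fixture)."""
        model, prof = carbon_gt
        config = carbon_bundle.default_config(prof)
        traj = simulate_batch(model, config)
        nC = carbon_bundle.carbon_counts
        v_cell = 1e-3  # L per gDW at the default volume conversion
        kappa = 1e-3 * carbon_bundle.biomass_precursor_coeff * nC["M1"]
        total = np.zeros_like(traj.t)
        for sp, arr in traj.extracellular.items():
            total += nC[sp] * arr
        for sp, arr in traj.intracellular.items():
            total += v_cell * traj.biomass * nC[sp] * arr
        total += kappa * traj.biomass
        assert np.abs(total - total[0]).max() / total[0] < 1e-3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BioreactorConfig(initial_biomass=-1.0, medium={})
        with pytest.raises(ValueError):
            BioreactorConfig(initial_biomass=0.1, medium={}, t_end=0.0)


class TestApplyDesign:
    def test_empty_design_is_identity(self, feedback_models):
        m = feedback_models[0]
        m2 = apply_design(m, _design())
        assert m2.enzyme_scale == m.enzyme_scale
        assert np.array_equal(m2.rates(m.anchor_x), m.rates(m.anchor_x))

    def test_duplicate_enzyme_rejected(self, feedback_models):
        with pytest.raises(ValueError, match="twice"):
            apply_design(
                feedback_models[0],
                _design(("Eprod", "up", 5.0), ("Eprod", "down", 5.0)),
            )

    def test_unknown_enzyme_rejected(self, feedback_models):
        with pytest.raises(KeyError):
            apply_design(feedback_models[0], _design(("nope", "up", 2.0)))

    def test_fold_below_one_rejected(self, feedback_models):
        with pytest.raises(ValueError):
            apply_design(feedback_models[0], _design(("Eprod", "up", 0.5)))

    def test_upregulating_chain_enzyme_raises_steady_flux(self, chain_bundle):
        """Monotone response on a linear chain: doubling one pathway enzyme
        increases the steady-state product flux."""
        from strainkit.fixtures import make_ground_truth_model

        model, prof = make_ground_truth_model(chain_bundle, seed=1)
        mu0 = steady_state_growth(model)
        up = apply_design(model, _design(("R2", "up", 2.0)))
        mu1 = steady_state_growth(up)
        assert mu1 > mu0


class TestEditRegulation:
    def test_removal_never_decreases_anchor_rate(self, feedback_models):
        m = feedback_models[0]
        edited = edit_regulation(m, "Eprod", "C2", action="remove")
        v0 = m.rates(m.anchor_x)
        v1 = edited.rates(m.anchor_x)
        j = m.rxn_ids.index("Eprod")
        assert v1[j] >= v0[j] - 1e-12

    def test_scale_factor_one_is_identity(self, feedback_models):
        m = feedback_models[0]
        edited = edit_regulation(m, "Eprod", "C2", action="scale", factor=1.0)
        assert np.allclose(edited.rates(m.anchor_x), m.rates(m.anchor_x))

    def test_missing_interaction_rejected(self, feedback_models):
        with pytest.raises(KeyError):
            edit_regulation(feedback_models[0], "R1", "C2", action="remove")

    def test_feedback_removal_raises_branch_flux(self, feedback_models):
        """Releasing the planted inhibition increases the steady-state flux
        into the product branch (resimulation oracle)."""
        m = feedback_models[0]
        edited = edit_regulation(m, "Eprod", "C2", action="remove")
        from strainkit.bioreactor import relax_intracellular

        def branch_flux(model):
            _, y = relax_intracellular(model, t_end=5.0)
            x = model.anchor_x.copy()
            x[model.compiled.internal_idx] = y[:, -1]
            return model.rates(x)[model.rxn_ids.index("Eprod")]

        assert branch_flux(edited) > branch_flux(m) * (1 + 1e-6)


class TestSensitivity:
    def test_zero_spread_gives_identical_trials(self, feedback_bundle,
                                                feedback_models, feedback_gt):
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        design = _design(("Eprod", "up", 3.0), ("Ebio", "down", 1.5))
        out = sensitivity_analysis(
            feedback_models[:2], design, config, spread=0.0, reps=3, seed=0
        )
        per_model = out["trials"].groupby("model")["final_titer"].nunique()
        assert (per_model == 1).all()

    def test_each_mode_perturbs_one_enzyme_per_batch(self, feedback_bundle,
                                                     feedback_models, feedback_gt):
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        design = _design(("Eprod", "up", 3.0), ("Ebio", "down", 1.5))
        out = sensitivity_analysis(
            feedback_models[:1], design, config, spread=0.5, reps=3,
            mode="each", seed=0,
        )
        trials = out["trials"]
        assert set(trials["batch"]) == {"Eprod", "Ebio"}
        eprod_batch = trials[trials["batch"] == "Eprod"]
        assert eprod_batch["fold_Ebio"].nunique() == 1  # pinned at mean
        assert eprod_batch["fold_Eprod"].nunique() > 1

    def test_reported_mean_recomputable_from_trial_table(
        self, feedback_bundle, feedback_models, feedback_gt
    ):
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        design = _design(("Eprod", "up", 3.0))
        out = sensitivity_analysis(
            feedback_models[:2], design, config, spread=0.5, reps=3, seed=7
        )
        table = out["trials"]
        recomputed = table.groupby("batch")["final_titer"].mean()
        for batch, mean in out["mean_response"]["final_titer"].items():
            assert mean == pytest.approx(recomputed[batch])

    def test_deterministic_under_seed(self, feedback_bundle, feedback_models,
                                      feedback_gt):
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        design = _design(("Eprod", "up", 3.0))
        a = sensitivity_analysis(feedback_models[:1], design, config, reps=2, seed=3)
        b = sensitivity_analysis(feedback_models[:1], design, config, reps=2, seed=3)
        assert a["trials"]["final_titer"].tolist() == b["trials"]["final_titer"].tolist()


class TestClusterDesigns:
    def test_disjoint_sets_separate(self):
        mems = [frozenset({("a", "up"), ("b", "up")}),
                frozenset({("c", "down"), ("d", "up")})]
        labels = cluster_designs(mems, n_clusters=2)
        assert labels[0] != labels[1]

    def test_identical_sets_form_one_cluster(self):
        mems = [frozenset({("a", "up")}), frozenset({("a", "up")})]
        labels = cluster_designs(mems)
        assert len(set(labels)) == 1

    def test_planted_motifs_recovered(self):
        """Three groups of designs sharing within-group cores cluster into
        exactly three groups at the automatic cut."""
        rng = np.random.default_rng(0)
        motifs = [
            [("a", "up"), ("b", "up"), ("c", "down")],
            [("d", "down"), ("e", "up"), ("f", "up")],
            [("g", "up"), ("h", "down"), ("i", "up")],
        ]
        mems, truth = [], []
        for gi, motif in enumerate(motifs):
            for _ in range(4):
                keep = [motif[i] for i in rng.choice(3, size=2, replace=False)]
                extra = (f"x{rng.integers(100)}", "up")
                mems.append(frozenset(keep + [extra]))
                truth.append(gi)
        labels = cluster_designs(mems, n_clusters=3)
        # same-group designs share labels, cross-group never do
        for i in range(len(mems)):
            for j in range(i + 1, len(mems)):
                if truth[i] == truth[j]:
                    assert labels[i] == labels[j]
                else:
                    assert labels[i] != labels[j]

    def test_deterministic(self):
        mems = [
            frozenset({("a", "up"), ("b", "up")}),
            frozenset({("a", "up"), ("c", "up")}),
            frozenset({("d", "down")}),
        ]
        assert np.array_equal(cluster_designs(mems), cluster_designs(mems))


class TestNonlinearRanking:
    def test_single_design_single_model_recomputable(self, feedback_bundle,
                                                     feedback_models, feedback_gt):
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        design = _design(("Eprod", "up", 3.0))
        table = rank_designs_nonlinear(feedback_models[:1], [design], config)
        traj = simulate_batch(apply_design(feedback_models[0], design), config)
        assert table.loc[0, "median_titer"] == pytest.approx(traj.final_titer())

    def test_noop_design_ranks_at_reference_titer(self, feedback_bundle,
                                                  feedback_models, feedback_gt):
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        table = rank_designs_nonlinear(feedback_models[:2], [_design()], config)
        ref = np.median(
            [simulate_batch(m, config).final_titer() for m in feedback_models[:2]]
        )
        assert table.loc[0, "median_titer"] == pytest.approx(ref)

    def test_bottleneck_relief_ranks_first(self, feedback_bundle, feedback_models,
                                           feedback_gt):
        """The design that relieves the planted bottleneck beats decoy
        single-enzyme designs elsewhere in the network."""
        _, prof = feedback_gt
        config = feedback_bundle.default_config(prof)
        candidates = [
            _design(("Eprod", "up", 5.0)),
            _design(("R1", "down", 5.0)),
            _design(("R2", "down", 5.0)),
            _design(("R3", "up", 5.0)),
            _design(("Ebio", "up", 5.0)),
        ]
        table = rank_designs_nonlinear(feedback_models[:3], candidates, config)
        assert table.loc[0, "design"] == 0
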