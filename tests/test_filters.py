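"""Design-selection filters: TM-score, composite score, prediction
agreement/convergence, fragment quality, ensemble RMSF and similarity
networks."""

import numpy as np
import pytest

from igtandem.filters import (tm_d0, tm_from_distances, tm_score,
                              tm_score_models, composite_score,
                              composite_score_single, af2_agreement_filter,
                              fragment_quality_filter, ensemble_rmsf,
                              similarity_network, ModelConfidence)
from igtandem.fixtures import (SandwichRecipe, make_ideal_sandwich, make_helix,
                               make_ensemble, random_rigid_copy, perturb_model)
from igtandem.geometry import random_rotation


class TestTmScore:
    def test_identical_structures(self, ig_sandwich):
        ca = ig_sandwich[0].ca_coords()
        assert tm_score(ca, ca) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_copy(self, ig_sandwich, rng):
        ca = ig_sandwich[0].ca_coords()
        moved = ca @ random_rotation(rng).T + np.array([5.0, -3.0, 8.0])
        assert tm_score(ca, moved) == pytest.approx(1.0, abs=1e-6)

    def test_frozen_distances_half(self):
        """With every distance equal to d0, the score is exactly 0.5."""
        d = np.full(100, tm_d0(100))
        assert tm_from_distances(d, 100) == pytest.approx(0.5, abs=1e-12)

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            tm_d0(15)
        with pytest.raises(ValueError):
            tm_score(np.zeros((15, 3)), np.zeros((15, 3)))

    def test_perturbation_lowers_score(self, ig_sandwich):
        model, _ = ig_sandwich
        noisy = perturb_model(model, 2.0, seed=3)
        tm = tm_score(model.ca_coords(), noisy.ca_coords())
        assert 0.2 < tm < 1.0


class TestCompositeScore:
    def test_perfect_model(self):
        assert composite_score_single(1.0, 100.0, 1.0) == 1.0

    def test_single_model_product(self):
        r = composite_score([(0.8, 90.0, 0.9)])
        assert r.score == pytest.approx(0.648, abs=1e-9)
        assert r.flagged        # fewer than 3 models available

    def test_threshold_semantics(self):
        assert composite_score([(0.7, 85.0, 0.95)] * 3).verdict == "discard"
        assert composite_score([(0.95, 95.0, 0.95)] * 3).verdict == "select"
        assert composite_score([(0.8, 90.0, 0.9)] * 3).verdict == "undecided"

    def test_top3_ranked_by_plddt(self):
        records = [(0.9, 95.0, 0.9), (0.9, 94.0, 0.9), (0.9, 93.0, 0.9),
                   (0.1, 50.0, 0.1)]
        r = composite_score(records)
        expected = np.mean([composite_score_single(0.9, p, 0.9)
                            for p in (95.0, 94.0, 93.0)])
        assert r.score == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_each_factor(self):
        base = composite_score_single(0.8, 90.0, 0.9)
        assert composite_score_single(0.9, 90.0, 0.9) > base
        assert composite_score_single(0.8, 95.0, 0.9) > base
        assert composite_score_single(0.8, 90.0, 0.95) > base

    def test_range_validation(self):
        with pytest.raises(ValueError):
            composite_score_single(1.2, 90.0, 0.9)
        with pytest.raises(ValueError):
            ModelConfidence("m", 120.0, 0.5)


class TestAgreementFilter:
    def test_all_models_pass(self):
        stats = [{"plddt": 95.0, "rmsd": 0.5}] * 5
        assert af2_agreement_filter(stats, min_passing=5).passed

    def test_counting(self):
        stats = [{"plddt": 95.0, "rmsd": 0.5}] * 3 + \
                [{"plddt": 80.0, "rmsd": 0.5}] * 2
        v = af2_agreement_filter(stats, min_passing=4)
        assert not v.passed and v.n_passing == 3
        assert af2_agreement_filter(stats, min_passing=1).passed

    def test_strict_inequalities(self):
        stats = [{"plddt": 90.0, "rmsd": 0.5}]      # pLDDT not > 90
        assert not af2_agreement_filter(stats).passed
        stats = [{"plddt": 95.0, "rmsd": 1.0}]      # RMSD not < 1
        assert not af2_agreement_filter(stats).passed

    def test_graft_mode_table(self):
        """Grafted-design rule: all decomposition RMSDs (total excluded)
        below 1 Å, at least 4 of 5 models passing — verified against a hand
        count."""
        keys = ("rmsd_scaffold", "rmsd_linker1", "rmsd_linker2", "rmsd_motif")
        rows = [
            {"plddt": 93, "rmsd_total": 1.8, "rmsd_scaffold": 0.5,
             "rmsd_linker1": 0.7, "rmsd_linker2": 0.6, "rmsd_motif": 0.9},
            {"plddt": 92, "rmsd_total": 2.5, "rmsd_scaffold": 0.4,
             "rmsd_linker1": 0.8, "rmsd_linker2": 0.5, "rmsd_motif": 0.8},
            {"plddt": 96, "rmsd_total": 1.2, "rmsd_scaffold": 0.6,
             "rmsd_linker1": 0.9, "rmsd_linker2": 0.7, "rmsd_motif": 0.7},
            {"plddt": 94, "rmsd_total": 1.1, "rmsd_scaffold": 0.3,
             "rmsd_linker1": 0.6, "rmsd_linker2": 0.9, "rmsd_motif": 0.6},
            # fails: motif RMSD over the bound
            {"plddt": 95, "rmsd_total": 3.0, "rmsd_scaffold": 0.5,
             "rmsd_linker1": 0.8, "rmsd_linker2": 0.7, "rmsd_motif": 1.4},
        ]
        v = af2_agreement_filter(rows, min_passing=4, rmsd_keys=keys)
        assert v.passed and v.n_passing == 4
        rows[1]["rmsd_linker1"] = 1.2   # second failure breaks convergence
        v = af2_agreement_filter(rows, min_passing=4, rmsd_keys=keys)
        assert not v.passed and v.n_passing == 3


class TestFragmentFilter:
    def test_all_good(self):
        v = fragment_quality_filter([[0.4, 0.8]] * 10, 1.0)
        assert v.passed and not v.failing_positions

    def test_failing_position_reported(self):
        rmsds = [[0.4]] * 5 + [[1.2, 1.5]] + [[0.4]] * 4
        v = fragment_quality_filter(rmsds, 1.0)
        assert not v.passed and v.failing_positions == [5]

    def test_boundary_is_strict(self):
        assert not fragment_quality_filter([[1.0]], 1.0).passed
        assert fragment_quality_filter([[0.999]], 1.0).passed

    def test_monotone_in_threshold(self):
        rmsds = [[0.9], [1.2], [0.7]]
        assert not fragment_quality_filter(rmsds, 1.0).passed
        assert fragment_quality_filter(rmsds, 1.3).passed

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fragment_quality_filter([])
        with pytest.raises(ValueError):
            fragment_quality_filter([[]])


class TestEnsembleRmsf:
    def test_identical_frames_zero(self):
        model = make_helix(10)
        frames = [model, model, model]
        stats = ensemble_rmsf(frames)
        np.testing.assert_allclose(stats.rmsf, 0.0, atol=1e-9)

    def test_rigid_copies_zero_after_superposition(self):
        model = make_helix(12)
        frames = [model] + [random_rigid_copy(model, seed=s) for s in (1, 2, 3)]
        stats = ensemble_rmsf(frames)
        np.testing.assert_allclose(stats.rmsf, 0.0, atol=1e-6)

    def test_single_jittered_residue_sqrt3(self):
        """One residue jittered with per-coordinate σ = 1 Å has RMSF ≈ √3
        when frames are superposed on the rigid scaffold."""
        model, _ = make_ideal_sandwich(SandwichRecipe(3, 7, 10.0, 0.0))
        n = len(model.residues())
        target = model.residues()[20].residue_number
        rigid = [(r.residue_number, r.residue_number)
                 for r in model.residues() if r.residue_number != target]
        profile = np.zeros(n)
        profile[20] = np.sqrt(3.0)     # make_ensemble takes target RMSF
        frames = make_ensemble(model, profile, 800, seed=7)
        stats = ensemble_rmsf(frames, selection=rigid)
        assert stats.rmsf[20] == pytest.approx(np.sqrt(3.0), rel=0.10)
        others = np.delete(stats.rmsf, 20)
        assert np.all(others < 0.2)

    def test_step_profile_recovered(self):
        model = make_helix(12)
        profile = np.array([0.1] * 8 + [1.0] * 4)
        rigid = [(1, 8)]
        frames = make_ensemble(model, profile, 1000, seed=9)
        stats = ensemble_rmsf(frames, selection=rigid)
        assert np.all(np.abs(stats.rmsf[8:] - 1.0) < 0.15)

    def test_distance_traces(self):
        model = make_helix(8)
        frames = [model, model]
        stats = ensemble_rmsf(frames, atom_pairs=[(1, "CA", 8, "CA")])
        trace = stats.distance_traces["1CA-8CA"]
        assert len(trace) == 2 and trace[0] == trace[1]

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_rmsf([make_helix(8), make_helix(9)])
        with pytest.raises(ValueError):
            ensemble_rmsf([make_helix(8)])


class TestSimilarityNetwork:
    def test_identical_models_complete_graph(self, small_sandwich):
        model, _ = small_sandwich
        models = [random_rigid_copy(model, seed=s) for s in (1, 2, 3)]
        for k, m in enumerate(models):
            m.label = f"m{k}"
        g = similarity_network(models, 0.9)
        assert g.number_of_edges() == 3
        assert all(d["tm"] == pytest.approx(1.0, abs=1e-4)
                   for _, _, d in g.edges(data=True))
        assert all(g.nodes[n]["n_strands"] == 6 for n in g.nodes)

    def test_unrelated_models_no_edge(self, small_sandwich):
        sandwich, _ = small_sandwich
        helix = make_helix(len(sandwich.residues()))
        helix.label = "helix"
        g = similarity_network([sandwich, helix], 0.6)
        assert g.number_of_edges() == 0

    def test_symmetry(self, small_sandwich, rng):
        model, _ = small_sandwich
        noisy = perturb_model(model, 1.0, seed=2)
        assert tm_score_models(model, noisy) == \
            pytest.approx(tm_score_models(noisy, model), abs=1e-6)
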