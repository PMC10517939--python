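"""Edge-to-edge pose construction, connector backbones, closure screening,
edge-strand exposure counting and the face-to-face sampler."""

import numpy as np
import pytest

from igtandem.fixtures import (SandwichRecipe, make_ideal_sandwich,
                               random_rigid_copy, _generic_ig)
from igtandem.fusion import (build_edge_to_edge_pose, build_connector_backbone,
                             closure_feasible, sample_face_to_face,
                             count_exposed_edge_strands, clash_count,
                             closable_fraction, merge_models, ConnectorSpec,
                             ROTATION_RANGE, TRANSLATION_RANGE, TILT_RANGE)
from igtandem.secstruct import detect_sandwich, sandwich_compatibility
from igtandem.topology import enumerate_fusions
from igtandem.geometry import build_backbone


def local_arrangement():
    return next(a for a in enumerate_fusions(_generic_ig(6), _generic_ig(6))
                if a.is_local)


@pytest.fixture(scope="module")
def ideal_domain():
    return make_ideal_sandwich(SandwichRecipe(3, 7, 10.0, 0.0))[0]


@pytest.fixture(scope="module")
def local_poses(ideal_domain):
    return build_edge_to_edge_pose(ideal_domain, ideal_domain,
                                   local_arrangement(), register_window=2)


class TestEdgeToEdgePose:
    def test_ideal_fixture_realizes_both_ladders(self, ideal_domain, local_poses):
        """At register 0 the pose realizes the generator's full hydrogen-bond
        ladder in both interface layers (6 bonds per new pairing) with no
        clashes."""
        best = local_poses[0]
        assert best.register == 0
        assert best.hbond_count == 12      # 2 layers x 6 planned bonds
        assert best.clash_count == 0
        assert best.paired_layers == 2
        assert best.exposed_edge_strands == 4

    def test_register_zero_dominates(self, local_poses):
        best = {p.register: p.hbond_count for p in local_poses}
        assert all(best[0] >= best[r] for r in best)

    def test_register_shift_translates_one_rung(self, ideal_domain, local_poses):
        """Adjacent registers place domain B one strand rung (~3.4 Å) apart."""
        by_reg = {p.register: p for p in local_poses}
        ca = ideal_domain.ca_coords()
        moved0 = ca @ by_reg[0].rotation.T + by_reg[0].translation
        moved1 = ca @ by_reg[1].rotation.T + by_reg[1].translation
        shift = np.linalg.norm((moved1 - moved0).mean(axis=0))
        assert shift == pytest.approx(3.465, abs=0.4)

    def test_mismatched_geometry_scores_lower(self, ideal_domain, local_poses):
        """Partners with dissimilar inter-sheet separations pair worse: 3 Å
        of mismatch strains every interface bond (strictly weaker summed
        energy) and fails the compatibility screen; 6 Å breaks the ladder
        outright."""
        strained = make_ideal_sandwich(SandwichRecipe(3, 7, 13.0, 0.0))[0]
        best_strained = build_edge_to_edge_pose(ideal_domain, strained,
                                                local_arrangement(), 0)[0]
        assert best_strained.hbond_count <= local_poses[0].hbond_count
        assert best_strained.hbond_energy > local_poses[0].hbond_energy + 1.0
        comp = sandwich_compatibility(detect_sandwich(ideal_domain),
                                      detect_sandwich(strained))
        assert not comp.compatible

        broken = make_ideal_sandwich(SandwichRecipe(3, 7, 16.0, 0.0))[0]
        best_broken = build_edge_to_edge_pose(ideal_domain, broken,
                                              local_arrangement(), 0)[0]
        assert best_broken.hbond_count < local_poses[0].hbond_count

    def test_score_invariant_under_joint_rigid_transform(self, ideal_domain,
                                                         local_poses):
        a2 = random_rigid_copy(ideal_domain, seed=11)
        poses2 = build_edge_to_edge_pose(a2, a2, local_arrangement(), 2)
        assert [(p.register, p.hbond_count, p.clash_count) for p in poses2] == \
               [(p.register, p.hbond_count, p.clash_count) for p in local_poses]


class TestClashCount:
    def test_distant_domains(self, ideal_domain):
        far = ideal_domain.transformed(np.eye(3), np.array([50.0, 0, 0]))
        assert clash_count(ideal_domain, far) == 0

    def test_superposed_domains(self, ideal_domain):
        assert clash_count(ideal_domain, ideal_domain) > 0


class TestExposureCounting:
    def test_edge_to_edge_four(self):
        assert count_exposed_edge_strands(local_arrangement()) == 4

    def test_face_to_face_eight(self):
        assert count_exposed_edge_strands("face_to_face") == 8

    def test_single_domain_four(self, ideal_domain):
        assert count_exposed_edge_strands(detect_sandwich(ideal_domain)) == 4

    def test_exposure_conservation(self, local_poses):
        """Buried + exposed in the edge-to-edge pose equals the face-to-face
        total for any two-sandwich pair."""
        pose = local_poses[0]
        buried = 2 * pose.paired_layers
        assert pose.exposed_edge_strands + buried == \
            count_exposed_edge_strands("face_to_face")


class TestClosure:
    @pytest.mark.parametrize("gap,n,expected", [
        (5.5, 2, True),      # 3.8 * 3 = 11.4 >= 5.5
        (12.0, 2, False),    # 11.4 < 12.0
        (0.0, 3, True),
        (15.0, 3, True),     # 3.8 * 4 = 15.2
        (15.3, 3, False),
    ])
    def test_examples(self, gap, n, expected):
        assert closure_feasible(gap, n) is expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            closure_feasible(-1.0, 2)
        with pytest.raises(ValueError):
            closure_feasible(1.0, 0)


class TestConnectorBackbone:
    def anchors(self, span):
        a = np.array([[0.0, 0, 0], [1.46, 0, 0], [2.0, 1.3, 0.4]])
        b = a + np.array([span, 0.0, 0.0])
        return a, b

    def test_beta_alpha_beta_length(self):
        spec = ConnectorSpec("beta_alpha_beta", helix_length=14,
                             abego_ba="BAB", abego_ab="GBA")
        frag, report = build_connector_backbone(spec, *self.anchors(20.0))
        assert len(frag["CA"]) == 14 + 3 + 3
        assert report.n_residues == 20

    def test_hairpin_close_anchors_closable(self):
        spec = ConnectorSpec("beta_hairpin", hairpin_loop_length=2)
        _, report = build_connector_backbone(spec, *self.anchors(5.5))
        assert report.closable

    def test_hairpin_distant_anchors_not_closable(self):
        spec = ConnectorSpec("beta_hairpin", hairpin_loop_length=2)
        _, report = build_connector_backbone(spec, *self.anchors(15.0))
        assert not report.closable

    def test_helix_axis_near_sheet_plane(self, ideal_domain):
        """The βαβ connector helix runs within 45° of the sheet plane when
        grown from a strand-end anchor."""
        res = ideal_domain.residues()
        anchor_a = np.vstack([res[6].n, res[6].ca, res[6].c])
        anchor_b = np.vstack([res[7].n, res[7].ca, res[7].c])
        spec = ConnectorSpec("beta_alpha_beta", 14, "BAB", "GBA")
        frag, _ = build_connector_backbone(spec, anchor_a, anchor_b)
        helix_ca = frag["CA"][3:17]
        axis = helix_ca[-1] - helix_ca[0]
        axis = axis / np.linalg.norm(axis)
        # sheet normal of the domain: smallest principal axis of all CAs
        ca = ideal_domain.ca_coords()
        _, _, vt = np.linalg.svd(ca - ca.mean(axis=0))
        out_of_plane = np.degrees(np.arcsin(abs(float(np.dot(axis, vt[2])))))
        assert out_of_plane < 45.0

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ConnectorSpec("beta_alpha_beta", helix_length=11)
        with pytest.raises(ValueError):
            ConnectorSpec("beta_hairpin", hairpin_loop_length=6)
        with pytest.raises(ValueError):
            ConnectorSpec("beta_alpha_beta", n_strand_extension=4)


class TestFaceToFaceSampler:
    def test_zero_trials(self, ideal_domain):
        assert sample_face_to_face(ideal_domain, ideal_domain, 0, seed=1) == []

    def test_deterministic(self, ideal_domain):
        s1 = sample_face_to_face(ideal_domain, ideal_domain, 100, seed=37)
        s2 = sample_face_to_face(ideal_domain, ideal_domain, 100, seed=37)
        assert [(a.rotation, a.translation, a.tilt, a.termini_gap) for a in s1] \
            == [(b.rotation, b.translation, b.tilt, b.termini_gap) for b in s2]

    def test_parameters_within_ranges(self, ideal_domain):
        samples = sample_face_to_face(ideal_domain, ideal_domain, 2000, seed=5)
        rot = np.array([s.rotation for s in samples])
        tr = np.array([s.translation for s in samples])
        tilt = np.array([s.tilt for s in samples])
        assert rot.min() >= ROTATION_RANGE[0] and rot.max() <= ROTATION_RANGE[1]
        assert tr.min() >= TRANSLATION_RANGE[0] and tr.max() <= TRANSLATION_RANGE[1]
        assert tilt.min() >= TILT_RANGE[0] and tilt.max() <= TILT_RANGE[1]

    def test_means_converge_to_midpoints(self, ideal_domain):
        """Uniform sampling: empirical means within 3σ/√n of midpoints."""
        n = 4000
        samples = sample_face_to_face(ideal_domain, ideal_domain, n, seed=8)
        for vals, rng_ in [([s.rotation for s in samples], ROTATION_RANGE),
                           ([s.translation for s in samples], TRANSLATION_RANGE),
                           ([s.tilt for s in samples], TILT_RANGE)]:
            mid = 0.5 * (rng_[0] + rng_[1])
            sigma = (rng_[1] - rng_[0]) / np.sqrt(12.0)
            assert abs(np.mean(vals) - mid) < 3.0 * sigma / np.sqrt(n)

    def test_closable_flag_consistent(self, ideal_domain):
        samples = sample_face_to_face(ideal_domain, ideal_domain, 500, seed=3)
        for s in samples:
            assert s.closable == any(closure_feasible(s.termini_gap, nl)
                                     for nl in (2, 3))
        assert 0.0 <= closable_fraction(samples) <= 1.0


def test_merge_models_chains(ideal_domain):
    merged = merge_models(ideal_domain, ideal_domain)
    assert merged.chain_ids() == ["A", "B"]
    assert len(merged.residues()) == 2 * len(ideal_domain.residues())
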