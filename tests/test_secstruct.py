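"""Hydrogen-bond detection, strand/sheet assignment, sandwich geometry and
ABEGO classification, validated against generator ground truth."""

import numpy as np
import pytest

from igtandem.fixtures import (SandwichRecipe, make_ideal_sandwich,
                               make_ideal_sheet, make_helix, perturb_model,
                               random_sandwich_recipe, random_rigid_copy)
from igtandem.secstruct import (detect_hbonds, assign_strands_and_sheets,
                                detect_sandwich, sandwich_compatibility,
                                abego_string, abego_letter,
                                validate_connector_geometry)
from igtandem.structure import backbone_torsions, StructureModel


def bonds_set(hbonds):
    return {(b.donor, b.acceptor) for b in hbonds}


class TestHbonds:
    def test_two_strand_ladder_exact(self, two_strand_sheet):
        """The antiparallel two-strand ladder realizes exactly the planned
        bonds."""
        model, truth = two_strand_sheet
        assert bonds_set(detect_hbonds(model)) == set(truth.planned_bonds)

    def test_helix_only_i_to_i_minus_4(self):
        hb = detect_hbonds(make_helix(12))
        assert hb, "helix should have hydrogen bonds"
        assert all(b.donor - b.acceptor == 4 for b in hb)

    def test_energies_negative(self, ig_sandwich):
        model, _ = ig_sandwich
        assert all(b.energy < -0.5 for b in detect_hbonds(model))

    def test_displaced_strand_loses_ladder(self):
        """Displacing one strand 3 Å breaks its ladder bonds."""
        model, truth = make_ideal_sheet(3, 7)
        lo, hi = truth.strand_ranges[2]
        nums = (model.residues()[lo].residue_number,
                model.residues()[hi - 1].residue_number)
        moved = perturb_model(model, 0.0, seed=0)
        for r in moved.residues():
            if nums[0] <= r.residue_number <= nums[1]:
                for atom in ("n", "ca", "c", "o"):
                    setattr(r, atom, getattr(r, atom) + np.array([0, 3.0, 0]))
        got = bonds_set(detect_hbonds(moved))
        displaced = set(range(lo, hi))
        assert not any(b[0] in displaced or b[1] in displaced for b in got)
        # bonds of the intact pair survive
        intact = {b for b in truth.pairings[0].bonds}
        assert intact <= got


class TestStrandAssignment:
    def test_four_strand_sheet(self):
        model, truth = make_ideal_sheet(4, 7)
        strands, pairings = assign_strands_and_sheets(model)
        assert [(s.start, s.stop) for s in strands] == truth.strand_ranges
        assert len(pairings) == 3
        assert all(p.orientation == "antiparallel" for p in pairings)
        assert len({s.sheet_id for s in strands}) == 1

    def test_sandwich_recovery(self, ig_sandwich):
        model, truth = ig_sandwich
        strands, pairings = assign_strands_and_sheets(model)
        assert [(s.start, s.stop) for s in strands] == truth.strand_ranges
        sheet_sizes = {}
        for s in strands:
            sheet_sizes[s.sheet_id] = sheet_sizes.get(s.sheet_id, 0) + 1
        assert sorted(sheet_sizes.values()) == [6, 6]
        got = {(p.strand_a, p.strand_b): (p.orientation, p.register)
               for p in pairings}
        want = {(p.strand_a, p.strand_b): (p.orientation, p.register)
                for p in truth.pairings}
        assert got == want

    def test_mixed_parallel_pair(self):
        """A sheet with one parallel neighbour pair is labelled parallel
        with the register from generator bookkeeping."""
        model, truth = make_ideal_sheet(3, 7, directions=[1, 1, -1])
        _, pairings = assign_strands_and_sheets(model)
        by_pair = {(p.strand_a, p.strand_b): p for p in pairings}
        want = {(p.strand_a, p.strand_b): p for p in truth.pairings}
        assert by_pair[(0, 1)].orientation == "parallel"
        for key, truth_p in want.items():
            assert by_pair[key].orientation == truth_p.orientation
            assert by_pair[key].register == truth_p.register

    def test_renumbering_idempotent(self, small_sandwich):
        """Strand assignment depends on geometry, not residue numbering."""
        model, _ = small_sandwich
        strands_a, pairings_a = assign_strands_and_sheets(model)
        chains = {"A": [type(r)(r.chain_id, r.residue_number + 500,
                                r.amino_acid, r.n, r.ca, r.c, r.o,
                                r.sidechain, r.confidence, r.insertion_code)
                        for r in model.residues()]}
        renum = StructureModel(chains)
        strands_b, pairings_b = assign_strands_and_sheets(renum)
        assert [(s.start, s.stop, s.sheet_id) for s in strands_a] == \
               [(s.start, s.stop, s.sheet_id) for s in strands_b]
        assert [(p.strand_a, p.strand_b, p.orientation, p.register)
                for p in pairings_a] == \
               [(p.strand_a, p.strand_b, p.orientation, p.register)
                for p in pairings_b]


class TestSandwich:
    def test_geometry_round_trip(self):
        geomatrix = [(10.0, 30.0), (8.5, 5.0), (11.5, 42.0)]
        for d, th in geomatrix:
            model, _ = make_ideal_sandwich(SandwichRecipe(4, 7, d, th))
            geom = detect_sandwich(model)
            assert geom.separation == pytest.approx(d, abs=0.5)
            assert geom.rotation == pytest.approx(th, abs=3.0)

    def test_single_sheet_raises(self):
        model, _ = make_ideal_sheet(4, 7)
        with pytest.raises(ValueError, match="two-sheet sandwich"):
            detect_sandwich(model)

    def test_four_edge_strands(self, ig_sandwich):
        model, truth = ig_sandwich
        geom = detect_sandwich(model)
        assert len(geom.all_edge_strands) == 4
        assert sorted(geom.all_edge_strands) == truth.edge_strands

    @pytest.mark.parametrize("strands_per_sheet", [2, 3, 5])
    def test_edge_count_independent_of_sheet_size(self, strands_per_sheet):
        model, _ = make_ideal_sandwich(
            SandwichRecipe(strands_per_sheet, 7, 10.0, 20.0))
        assert len(detect_sandwich(model).all_edge_strands) == 4

    def test_randomized_recovery(self, rng):
        """Detection recovers ground truth on randomized recipes (a larger
        sweep runs in the acceptance suite)."""
        for _ in range(10):
            recipe = random_sandwich_recipe(rng)
            model, truth = make_ideal_sandwich(recipe)
            model = random_rigid_copy(model, seed=int(rng.integers(2 ** 16)))
            strands, pairings = assign_strands_and_sheets(model)
            assert [(s.start, s.stop) for s in strands] == truth.strand_ranges
            got = {(p.strand_a, p.strand_b): (p.orientation, p.register)
                   for p in pairings}
            want = {(p.strand_a, p.strand_b): (p.orientation, p.register)
                    for p in truth.pairings}
            assert got == want
            geom = detect_sandwich(model)
            assert geom.separation == pytest.approx(recipe.sheet_separation, abs=0.5)
            assert geom.rotation == pytest.approx(recipe.sheet_rotation, abs=3.0)


class TestCompatibility:
    def test_identical_pass(self, ig_sandwich):
        model, _ = ig_sandwich
        geom = detect_sandwich(model)
        res = sandwich_compatibility(geom, geom)
        assert res.compatible and res.delta_separation == 0.0

    def test_separation_mismatch_fails(self):
        a = detect_sandwich(make_ideal_sandwich(SandwichRecipe(3, 7, 9.0, 10.0))[0])
        b = detect_sandwich(make_ideal_sandwich(SandwichRecipe(3, 7, 12.0, 10.0))[0])
        assert not sandwich_compatibility(a, b, tol_separation=1.5).compatible

    def test_boundary_inclusive(self):
        a = detect_sandwich(make_ideal_sandwich(SandwichRecipe(3, 7, 10.0, 10.0))[0])
        b = detect_sandwich(make_ideal_sandwich(SandwichRecipe(3, 7, 11.0, 10.0))[0])
        delta = abs(a.separation - b.separation)
        res = sandwich_compatibility(a, b, tol_separation=delta, tol_rotation=15.0)
        assert res.compatible  # <= is inclusive


class TestAbego:
    def test_helix_all_A(self):
        torsions = backbone_torsions(make_helix(10))["A"]
        assert set(abego_string(torsions)[1:-1]) == {"A"}

    def test_strand_all_B(self, two_strand_sheet):
        model, truth = two_strand_sheet
        torsions = backbone_torsions(model)["A"]
        s = abego_string(torsions)
        lo, hi = truth.strand_ranges[0]
        assert set(s[lo + 1:hi - 1]) == {"B"}

    @pytest.mark.parametrize("phi,psi,omega,letter", [
        (60.0, 40.0, 180.0, "G"),
        (60.0, -130.0, 180.0, "E"),
        (-60.0, -40.0, 180.0, "A"),
        (-120.0, 130.0, 180.0, "B"),
        (-120.0, 130.0, 10.0, "O"),
        (None, None, None, "-"),
    ])
    def test_bins(self, phi, psi, omega, letter):
        assert abego_letter(phi, psi, omega) == letter


class TestConnectorGeometry:
    @pytest.mark.parametrize("ba,ab,helix,ok", [
        ("BAB", "GBA", 14, True),
        ("BAB", "BA", 14, True),
        ("BAB", "GG", 14, False),
        ("BAB", "AGB", 12, True),
        ("BAB", "GB", 16, True),
        ("BAB", "GBA", 11, False),
        ("BAB", "GBA", 17, False),
        ("BA", "GBA", 14, False),
    ])
    def test_admissible_connectors(self, ba, ab, helix, ok):
        assert validate_connector_geometry(ba, ab, helix) is ok
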