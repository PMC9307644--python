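"""Contact-pair, hydrogen-bond and water-bridge detection."""

import numpy as np
import pytest

from conftest import acp_oracle, dhb_oracle
from solvinterface.fixtures import ToyComplexSpec, make_toy_complex
from solvinterface.hydration import WaterSet
from solvinterface.interactions import (
    HBCriteria,
    classify_acps,
    find_acps,
    find_dhbs,
    find_wmhbs,
    summarize_interface,
    water_orientations,
)
from solvinterface.structio import (
    AtomRecord,
    StructureModel,
    annotate_atoms,
    annotate_cdrs,
    place_polar_hydrogens,
)


def _model(spec, roles=None, protonate=False):
    atoms = [AtomRecord(c, s, "", rn, an, an.strip("0123456789")[0],
                        np.array(p, dtype=float))
             for c, s, rn, an, p in spec]
    model = StructureModel(
        atoms, chain_roles=roles or {"A": "antibody-heavy", "B": "antigen"})
    annotate_atoms(model)
    if protonate:
        place_polar_hydrogens(model)
    return model


class TestFindAcps:
    def test_carbon_carbon_threshold(self):
        # vdW sum + 0.5 = 3.90 for two carbons
        near = _model([("A", 1, "ALA", "CB", (0, 0, 0)),
                       ("B", 1, "ALA", "CB", (3.80, 0, 0))])
        far = _model([("A", 1, "ALA", "CB", (0, 0, 0)),
                      ("B", 1, "ALA", "CB", (3.95, 0, 0))])
        assert len(find_acps(near)) == 1
        assert len(find_acps(far)) == 0

    def test_separated_chains_empty(self):
        model = _model([("A", 1, "ALA", "CB", (0, 0, 0)),
                        ("B", 1, "ALA", "CB", (15, 0, 0))])
        assert find_acps(model) == []

    def test_unpartitioned_raises(self):
        model = _model([("A", 1, "ALA", "CB", (0, 0, 0))], roles={})
        with pytest.raises(Exception):
            find_acps(model)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        model, _ = make_toy_complex(
            ToyComplexSpec(n_dhb=2, n_bridge=1, n_aromatic=2, n_nacc=2,
                           sigma=0.4, seed=seed))
        got = {(p.ab_atom.key, p.ag_atom.key) for p in find_acps(model)}
        assert got == acp_oracle(model)


class TestClassifyAcps:
    def test_precedence(self):
        model = _model([
            ("A", 1, "TYR", "CZ", (0, 0, 0)),      # aromatic ring carbon
            ("A", 2, "ALA", "CB", (0, 6, 0)),
            ("A", 3, "GLY", "N", (0, 12, 0)),      # donor
            ("B", 1, "LEU", "CD1", (3.0, 0, 0)),
            ("B", 2, "LEU", "CD1", (3.0, 6, 0)),
            ("B", 3, "LYS", "NZ", (3.0, 12, 0)),   # donor
        ])
        pairs, counts = classify_acps(find_acps(model))
        by_ab = {p.ab_atom.res_seq: p.acp_class for p in pairs}
        assert by_ab == {1: "aACP", 2: "naCC", 3: "donor-donor"}
        assert counts["aACP"] == counts["naCC"] == counts["donor-donor"] == 1

    def test_his_gated_by_flag(self):
        model = _model([("A", 1, "HIS", "CE1", (0, 0, 0)),
                        ("B", 1, "ALA", "CB", (3.0, 0, 0))])
        pairs, _ = classify_acps(find_acps(model))
        assert pairs[0].acp_class == "naCC"  # FWY-only aromatic class
        pairs, _ = classify_acps(find_acps(model), include_his=True)
        assert pairs[0].acp_class == "aACP"

    def test_carbon_polar(self):
        model = _model([("A", 1, "ALA", "CB", (0, 0, 0)),
                        ("B", 1, "GLY", "O", (3.0, 0, 0))])
        pairs, _ = classify_acps(find_acps(model))
        assert pairs[0].acp_class == "carbon-polar"


class TestFindDhbs:
    def test_ideal_geometry_accepted(self):
        # N(0,0,0)-H(0,0,1)...O(0,0,2.9): 180 deg
        model, _ = make_toy_complex(ToyComplexSpec(n_dhb=1))
        bonds = find_dhbs(model)
        assert len(bonds) == 1
        assert bonds[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_distance_cutoff(self):
        model, truth = make_toy_complex(ToyComplexSpec(n_dhb=1))
        acc = model.get_atom(*truth["dhb"][0][1])
        acc.pos = acc.pos + np.array([0.0, 0.7, 0.0])  # D-A to 3.6 > 3.5
        assert find_dhbs(model) == []

    def test_angle_cutoff(self):
        model, truth = make_toy_complex(ToyComplexSpec(n_dhb=1))
        donor = model.get_atom(*truth["dhb"][0][0])
        acc = model.get_atom(*truth["dhb"][0][1])
        # move acceptor to 100 deg off the N-H axis at the same distance
        acc.pos = donor.pos + 2.9 * np.array(
            [np.sin(np.radians(80.0)), np.cos(np.radians(80.0)), 0.0])
        assert find_dhbs(model) == []

    def test_flexible_donor_passes_without_fixed_h(self):
        # Ser OG donor: place the acceptor on a scanned O-H ray (tetrahedral
        # cone around CB-OG, one of the 36-degree torsion samples)
        c, s = np.cos(np.radians(70.5)), np.sin(np.radians(70.5))
        model = _model([
            ("A", 1, "SER", "CB", (0, 0, 0)),
            ("A", 1, "SER", "OG", (1.42, 0, 0)),
            ("B", 1, "GLY", "O", (1.42 + 3.0 * c, 3.0 * s, 0)),
        ], protonate=True)
        bonds = find_dhbs(model)
        assert len(bonds) == 1 and bonds[0].flexible

    def test_input_order_invariance(self):
        model, _ = make_toy_complex(
            ToyComplexSpec(n_dhb=3, n_bridge=1, sigma=0.3, seed=5))
        keys = {(b.donor.key, b.acceptor.key) for b in find_dhbs(model)}
        reversed_model = StructureModel(list(reversed(model.atoms)),
                                        dict(model.chain_roles), model.waters)
        reversed_model.annotated = True
        keys_rev = {(b.donor.key, b.acceptor.key)
                    for b in find_dhbs(reversed_model)}
        assert keys == keys_rev

    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_matches_brute_force(self, seed):
        model, _ = make_toy_complex(
            ToyComplexSpec(n_dhb=3, n_bridge=2, n_aromatic=1, n_nacc=1,
                           sigma=0.5, seed=seed))
        got = {(b.donor.key, b.acceptor.key) for b in find_dhbs(model)}
        assert got == dhb_oracle(model)


class TestWaterOrientations:
    def test_cardinality(self):
        assert len(water_orientations(36.0)) == 500
        assert water_orientations(36.0).counts == (10, 10, 5)
        assert len(water_orientations(90.0)) == 32

    def test_rotations_are_proper(self):
        grid = water_orientations(36.0)
        for rot in grid.rotations[::37]:
            np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            water_orientations(50.0)


class TestFindWmhbs:
    def test_planted_bridge_detected_at_orientation_zero(self):
        model, truth = make_toy_complex(ToyComplexSpec(n_bridge=1))
        bridges = find_wmhbs(model, WaterSet(model.waters))
        assert len(bridges) == 1
        b = bridges[0]
        widx, ab_key, ag_key = truth["wmhb"][0]
        assert (b.water_index, b.ab_atom.key, b.ag_atom.key) == \
            (widx, ab_key, ag_key)
        assert 0 in b.orientations

    def test_no_waters_no_bridges(self):
        model, _ = make_toy_complex(ToyComplexSpec(n_bridge=1))
        assert find_wmhbs(model, WaterSet(np.empty((0, 3)))) == []

    def test_remote_partner_kills_bridge(self):
        model, truth = make_toy_complex(ToyComplexSpec(n_bridge=1))
        ag = model.get_atom(*truth["wmhb"][0][2])
        w = model.waters[0]
        direction = (ag.pos - w) / np.linalg.norm(ag.pos - w)
        ag.pos = w + 4.1 * direction
        assert find_wmhbs(model, WaterSet(model.waters)) == []

    def test_symmetric_under_partition_swap(self):
        model, _ = make_toy_complex(ToyComplexSpec(n_bridge=2))
        bridges = find_wmhbs(model, WaterSet(model.waters))
        swapped = model.copy()
        swapped.set_partition({"H": "antigen", "G": "antibody-heavy"})
        bridges_sw = find_wmhbs(swapped, WaterSet(swapped.waters))
        fwd = {(b.water_index, b.ab_atom.key, b.ag_atom.key) for b in bridges}
        rev = {(b.water_index, b.ag_atom.key, b.ab_atom.key) for b in bridges_sw}
        assert fwd == rev


class TestSummarizeInterface:
    @staticmethod
    def _summary(model, cdr_config, waters=None):
        cdrs = annotate_cdrs(model, cdr_config)
        acps, _ = classify_acps(find_acps(model))
        dhbs = find_dhbs(model)
        wmhbs = find_wmhbs(model, waters) if waters is not None else []
        return summarize_interface(model, cdrs, acps, dhbs, wmhbs)

    def test_single_aromatic_contact_marks_one_position(self):
        model, truth = make_toy_complex(ToyComplexSpec(n_aromatic=1, n_nacc=1))
        phe_key = truth["aacp"][0][0][:3]
        ala_key = truth["nacc"][0][0][:3]
        cfg = {"positions": {"H109": list(phe_key), "H110": list(ala_key)},
               "cdrs": {"H3": ["H109", "H110"]}}
        s = self._summary(model, cfg)
        assert s.positions["H109"]["classes"] == {"aACP"}
        assert s.positions["H109"]["aa"] == "F"
        assert s.positions["H110"]["classes"] == {"naCC"}
        assert s.class_totals == {"aACP": 1, "naCC": 1, "DHB": 0, "WMHB": 0}

    def test_epitope_residues_from_any_acp_class(self):
        model, truth = make_toy_complex(ToyComplexSpec(n_dhb=1, n_nacc=1))
        cfg = {"positions": {"H1": ["H", 2, ""]}, "cdrs": {"H1": ["H1"]}}
        s = self._summary(model, cfg)
        # N...O other-polar contact and the CB-CB contact both mark antigen
        # residues as epitope
        assert len(s.epitope) == 2

    def test_empty_annotation_refused(self, toy_complex):
        model, _ = toy_complex
        cdrs = annotate_cdrs(model, {})
        with pytest.raises(ValueError):
            summarize_interface(model, cdrs, [], [], [])
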