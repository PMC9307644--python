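"""Water placement, interfacial space, pooling and benchmarking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import benchmark_oracle, interface_space_oracle
from solvinterface.hydration import (
    GridMap,
    InterfacialSpace,
    SolvationParams,
    WaterSet,
    benchmark_waters,
    build_pdm,
    compute_interfacial_space,
    meta_pool,
    place_waters,
    random_waters,
    score_counts,
    select_interfacial_waters,
)
from solvinterface.structio import AtomRecord, StructureModel, annotate_atoms


def _model_from_atoms(spec, roles=None):
    """spec: list of (chain, resseq, resname, atomname, xyz)."""
    atoms = [AtomRecord(c, s, "", rn, an, an[0], np.array(p, dtype=float))
             for c, s, rn, an, p in spec]
    model = StructureModel(atoms, chain_roles=roles or {})
    return annotate_atoms(model)


class TestSolvationParams:
    def test_derived_thresholds(self):
        p = SolvationParams()
        assert p.layer_probe == pytest.approx(1.9)
        assert p.match_threshold == pytest.approx(1.4)
        assert p.redundancy_threshold == pytest.approx(2 * 1.4 + 0.5)


class TestBuildPdm:
    def test_nonnegative_and_zero_inside_atoms(self):
        model = _model_from_atoms([("A", 1, "GLY", "O", (0, 0, 0))])
        pdm = build_pdm(model, spacing=0.5)
        assert (pdm.values >= 0).all()
        centers = pdm.centers()
        inside = np.linalg.norm(centers, axis=1) < 1.52
        assert pdm.values.flatten()[inside].max() == 0.0

    def test_carbonyl_peak_at_kernel_distance(self):
        # brute-force scan: the argmax voxel of an isolated O lies on the
        # 2.8 Å shell up to one voxel of quantization
        model = _model_from_atoms([("A", 1, "GLY", "O", (0, 0, 0))])
        pdm = build_pdm(model, spacing=0.5)
        peak = pdm.centers()[np.argmax(pdm.values.flatten())]
        assert abs(np.linalg.norm(peak) - 2.8) <= 0.5

    def test_bad_spacing_and_empty_model(self):
        model = _model_from_atoms([("A", 1, "GLY", "O", (0, 0, 0))])
        with pytest.raises(ValueError):
            build_pdm(model, spacing=0.0)
        with pytest.raises(ValueError):
            build_pdm(StructureModel([]), spacing=0.5)


class TestPlaceWaters:
    def test_zero_pdm_gives_no_waters(self):
        model = _model_from_atoms([("A", 1, "GLY", "O", (0, 0, 0))])
        pdm = GridMap(np.zeros(3), 0.5, np.zeros((8, 8, 8)))
        assert len(place_waters(pdm, model)) == 0

    def test_single_positive_voxel_in_open_space(self):
        model = _model_from_atoms([("A", 1, "GLY", "O", (0, 0, 0))])
        values = np.zeros((21, 21, 21))
        values[18, 10, 10] = 5.0  # 4 Å from the atom along +x
        pdm = GridMap(np.full(3, -5.0), 0.5, values)
        ws = place_waters(pdm, model)
        assert len(ws) == 1
        np.testing.assert_allclose(ws.positions[0], [4.0, 0.0, 0.0], atol=1e-9)

    def test_two_voxels_two_angstrom_apart_both_survive(self):
        # 2.0 Å exceeds the 1.4 Å voxel-removal radius: hand-traced loop
        model = _model_from_atoms([("A", 1, "GLY", "O", (0, 0, 0))])
        values = np.zeros((41, 21, 21))
        values[28, 10, 10] = 5.0   # (4.0, 0, 0)
        values[32, 10, 10] = 4.0   # (6.0, 0, 0)
        pdm = GridMap(np.array([-10.0, -5.0, -5.0]), 0.5, values)
        ws = place_waters(pdm, model)
        assert len(ws) == 2
        assert ws.scores[0] == 5.0 and ws.scores[1] == 4.0

    def test_output_is_clash_free(self):
        from solvinterface.fixtures import make_hydrated_interface

        model, _ = make_hydrated_interface(nx=3, ny=3, seed=4)
        pdm = build_pdm(model, spacing=0.5)
        ws = place_waters(pdm, model)
        assert len(ws) > 0
        pos = np.array([a.pos for a in model.atoms])
        radii = np.array([a.vdw_radius for a in model.atoms])
        for w in ws.positions:
            d = np.linalg.norm(pos - w, axis=1)
            assert (d >= radii + 1.4 - 1e-6).all()

    def test_disjoint_grid_raises(self):
        from solvinterface.hydration import GeometryError

        model = _model_from_atoms([("A", 1, "GLY", "O", (100, 100, 100))])
        pdm = GridMap(np.zeros(3), 0.5, np.ones((4, 4, 4)))
        with pytest.raises(GeometryError):
            place_waters(pdm, model)


class TestInterfacialSpace:
    def test_separated_chains_empty(self):
        model = _model_from_atoms(
            [("A", 1, "ALA", "CB", (0, 0, 0)), ("B", 1, "ALA", "CB", (30, 0, 0))],
            roles={"A": "antibody-heavy", "B": "antigen"},
        )
        assert compute_interfacial_space(model).n_flagged == 0

    def test_midpoint_of_two_carbons_flagged(self):
        # gap at the midpoint: 2.5 - 1.7 = 0.8 in (0, 1.9]
        model = _model_from_atoms(
            [("A", 1, "ALA", "CB", (0, 0, 0)), ("B", 1, "ALA", "CB", (5, 0, 0))],
            roles={"A": "antibody-heavy", "B": "antigen"},
        )
        space = compute_interfacial_space(model, spacing=0.5)
        assert space.contains(np.array([[2.5, 0.0, 0.0]]))[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        spec = [("A", i + 1, "ALA", "CB", rng.uniform(0, 6, 3))
                for i in range(4)]
        spec += [("B", i + 1, "ALA", "CB", rng.uniform(0, 6, 3) + [0, 0, 5])
                 for i in range(4)]
        model = _model_from_atoms(spec, roles={"A": "antibody-heavy",
                                               "B": "antigen"})
        space = compute_interfacial_space(model, spacing=1.0)
        expected = interface_space_oracle(model, space.origin, space.spacing,
                                          space.shape)
        np.testing.assert_array_equal(space.flagged, expected)

    def test_missing_side_raises(self):
        model = _model_from_atoms([("A", 1, "ALA", "CB", (0, 0, 0))],
                                  roles={"A": "antibody-heavy"})
        with pytest.raises(Exception):
            compute_interfacial_space(model)


class TestMetaPool:
    def test_identity_when_sparse(self):
        ws = WaterSet(np.array([[0, 0, 0], [5, 0, 0], [0, 6, 0]]), priority=0)
        pooled = meta_pool([ws])
        assert len(pooled) == 3

    def test_redundancy_threshold_boundary(self):
        a = WaterSet(np.array([[0.0, 0, 0]]), source="one", priority=0)
        b_near = WaterSet(np.array([[3.2, 0, 0]]), source="two", priority=1)
        b_far = WaterSet(np.array([[3.4, 0, 0]]), source="two", priority=1)
        assert len(meta_pool([a, b_near])) == 1
        assert len(meta_pool([a, b_far])) == 2

    def test_priority_decides_survivor(self):
        lo = WaterSet(np.array([[0.0, 0, 0]]), source="lo", priority=5)
        hi = WaterSet(np.array([[1.0, 0, 0]]), source="hi", priority=1)
        pooled = meta_pool([lo, hi])
        assert pooled.labels == ["hi"]

    def test_duplicate_priorities_rejected(self):
        a = WaterSet(np.zeros((1, 3)), priority=1)
        b = WaterSet(np.ones((1, 3)), priority=1)
        with pytest.raises(ValueError):
            meta_pool([a, b])

    def test_survivors_pairwise_separated_and_from_inputs(self):
        rng = np.random.default_rng(3)
        sets = [WaterSet(rng.uniform(0, 12, (30, 3)), source=f"s{i}", priority=i)
                for i in range(3)]
        pooled = meta_pool(sets)
        all_inputs = np.vstack([s.positions for s in sets])
        for i, p in enumerate(pooled.positions):
            d = np.linalg.norm(pooled.positions - p, axis=1)
            d[i] = np.inf
            assert d.min() > 3.3
            assert np.isclose(np.linalg.norm(all_inputs - p, axis=1), 0).any()


class TestRandomWaters:
    @staticmethod
    def _space():
        values = np.zeros((12, 12, 4))
        flagged = np.arange(values.size)[::3]
        return InterfacialSpace(np.zeros(3), 1.0, values.shape, flagged)

    def test_single_voxel_space(self):
        space = InterfacialSpace(np.zeros(3), 0.5, (1, 1, 1), np.array([0]))
        assert len(random_waters(space, seed=1)) == 1

    def test_seed_determinism_and_variation(self):
        space = self._space()
        a = random_waters(space, seed=7)
        b = random_waters(space, seed=7)
        c = random_waters(space, seed=8)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.positions.shape != c.positions.shape or \
            not np.allclose(a.positions, c.positions)

    def test_constraints_and_saturation(self):
        space = self._space()
        ws = random_waters(space, seed=5)
        assert space.contains(ws.positions).all()
        for i, p in enumerate(ws.positions):
            d = np.linalg.norm(ws.positions - p, axis=1)
            d[i] = np.inf
            assert d.min() >= 3.3
        # saturation: every flagged voxel within the exclusion distance
        centers = space.flagged_centers()
        for c in centers:
            assert np.linalg.norm(ws.positions - c, axis=1).min() <= 3.3

    def test_empty_space_gives_empty_set(self):
        space = InterfacialSpace(np.zeros(3), 0.5, (4, 4, 4), np.array([], int))
        assert len(random_waters(space, seed=0)) == 0


class TestSelectInterfacialWaters:
    def test_membership_and_subset(self):
        space = InterfacialSpace(np.zeros(3), 1.0, (5, 5, 5),
                                 np.array([0]))  # voxel at the origin
        ws = WaterSet(np.array([[0.1, 0.1, 0.1], [10.0, 0, 0], [3.0, 3, 3]]))
        sel = select_interfacial_waters(ws, space)
        assert len(sel) == 1
        np.testing.assert_allclose(sel.positions[0], [0.1, 0.1, 0.1])


class TestBenchmark:
    def test_threshold_boundary(self):
        hit = benchmark_waters(WaterSet([[0, 0, 0]]), WaterSet([[1.0, 0, 0]]))
        assert (hit.tp, hit.fn, hit.fp, hit.f1) == (1, 0, 0, 1.0)
        miss = benchmark_waters(WaterSet([[0, 0, 0]]), WaterSet([[2.0, 0, 0]]))
        assert (miss.tp, miss.fn, miss.fp, miss.f1) == (0, 1, 1, 0.0)

    def test_planted_fixture_and_oracle(self):
        from solvinterface.fixtures import make_benchmark_fixture

        pred, ref = make_benchmark_fixture(7, 3, 5, seed=2)
        res = benchmark_waters(pred, ref)
        assert (res.tp, res.fn, res.fp) == (7, 3, 5)
        assert (res.tp, res.fn, res.fp) == benchmark_oracle(pred.positions,
                                                            ref.positions)

    def test_self_benchmark_is_perfect(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 30, (20, 3))
        keep = [p for i, p in enumerate(pts)
                if not any(np.linalg.norm(p - pts[j]) < 2.9
                           for j in range(i))]
        ws = WaterSet(np.array(keep))
        res = benchmark_waters(ws, ws)
        assert res.fp == 0 and res.fn == 0 and res.f1 == 1.0

    def test_empty_sets(self):
        empty = WaterSet(np.empty((0, 3)))
        some = WaterSet([[0, 0, 0]])
        assert benchmark_waters(empty, some).fn == 1
        assert benchmark_waters(some, empty).fp == 1
        assert benchmark_waters(empty, empty).f1 == 0.0


class TestScoreCounts:
    def test_zero_tp(self):
        res = score_counts(0, 5, 7)
        assert (res.f1, res.pre, res.rec) == (0.0, 0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            score_counts(-1, 0, 0)

    @given(tp=st.integers(0, 10**6), fn=st.integers(0, 10**6),
           fp=st.integers(0, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_metric_invariants(self, tp, fn, fp):
        res = score_counts(tp, fn, fp)
        assert 0.0 <= res.pre <= 1.0 and 0.0 <= res.rec <= 1.0
        assert 0.0 <= res.f1 <= 1.0
        if res.pre + res.rec > 0:
            assert res.f1 == pytest.approx(
                2 * res.pre * res.rec / (res.pre + res.rec))
        assert res.tp + res.fn == tp + fn
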