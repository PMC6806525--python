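from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coreclust.errors import GeometryError, StructureError
from coreclust.geometry import (
    CoreTrace,
    DistanceMatrix,
    all_vs_all,
    core_rmsd,
    core_trace,
    kabsch_rmsd,
    rmsd_heavy,
    superpose,
    traces_for,
)
from coreclust.msa import conserved_core
from coreclust.structures import Residue, StructureModel

from oracles import oracle_min_rmsd


def rigid(points, seed=0, angle=None):
    rng = np.random.default_rng(seed)
    rv = rng.normal(size=3) if angle is None else angle
    R = Rotation.from_rotvec(rv).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return points @ R.T + t


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        _, _, value = superpose(pts, pts)
        assert value == pytest.approx(0.0, abs=1e-7)

    def test_rigid_motion_invariance(self):
        pts = np.random.default_rng(1).normal(size=(10, 3)) * 5
        moved = rigid(pts, angle=np.array([0, 0, np.pi / 2]))
        moved += np.array([5.0, 0.0, 0.0])
        R, t, value = superpose(moved, pts)
        assert value == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved @ R.T + t, pts, atol=1e-9)

    def test_returned_transform_achieves_returned_rmsd(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(12, 3)) * 4
        Q = rng.normal(size=(12, 3)) * 4
        R, t, value = superpose(P, Q)
        applied = P @ R.T + t
        assert np.sqrt(np.mean(np.sum((applied - Q) ** 2, axis=1))) == pytest.approx(
            value, abs=1e-10
        )

    def test_matches_numerical_minimization_oracle(self):
        rng = np.random.default_rng(3)
        for size in (3, 5, 10, 25):
            P = rng.normal(size=(size, 3)) * 6
            Q = rng.normal(size=(size, 3)) * 6
            _, _, value = superpose(P, Q)
            assert value == pytest.approx(oracle_min_rmsd(P, Q), abs=1e-6)

    def test_rotation_is_never_a_reflection(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = np.array(P)
            Q[:, 2] *= -1  # mirrored target tempts an improper solution
            R, _, _ = superpose(P, Q + rng.normal(scale=0.01, size=Q.shape))
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_and_degenerate_inputs(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(GeometryError):
            superpose(pts, pts[:4])
        with pytest.raises(GeometryError):
            superpose(pts[:2], pts[:2])
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="collinear"):
            superpose(line, pts)


def _toy_model(coords_per_res, homolog="target"):
    residues = []
    for atoms in coords_per_res:
        residues.append(
            Residue("A", {name: np.asarray(xyz, float) for name, xyz in atoms.items()})
        )
    return StructureModel("toy", homolog, 1, tuple(residues))


class TestRmsdHeavy:
    def _pair(self):
        res1 = {"C3'": (0, 0, 0), "P": (1, 0, 0), "N1": (0, 1, 0)}
        res2 = {"C3'": (3, 0, 0), "C1'": (3, 1, 0)}
        return _toy_model([res1, res2])

    def test_self_is_zero(self):
        m = self._pair()
        assert rmsd_heavy(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self):
        m = self._pair()
        moved = _toy_model(
            [
                {k: rigid(np.array([v], float), seed=9)[0] for k, v in
                 {"C3'": (0, 0, 0), "P": (1, 0, 0), "N1": (0, 1, 0)}.items()},
                {k: rigid(np.array([v], float), seed=9)[0] for k, v in
                 {"C3'": (3, 0, 0), "C1'": (3, 1, 0)}.items()},
            ]
        )
        assert rmsd_heavy(moved, m) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_oracle(self):
        # one of five paired atoms displaced by 2 Å along x; the optimal
        # superposition re-minimizes translation/rotation, so the expected
        # value comes from the independent numerical oracle
        ref_atoms = [
            {"C3'": (0, 0, 0), "P": (1, 0, 0), "N1": (0, 1, 0)},
            {"C3'": (3, 0, 0), "C1'": (3, 1, 0)},
        ]
        mod_atoms = [
            {"C3'": (0, 0, 0), "P": (1, 0, 0), "N1": (0, 1, 0)},
            {"C3'": (3, 0, 0), "C1'": (5, 1, 0)},  # displaced +2 in x
        ]
        ref = _toy_model(ref_atoms)
        mod = _toy_model(mod_atoms)
        P, Q = [], []
        for ma, ra in zip(mod_atoms, ref_atoms):
            for name in sorted(set(ma) & set(ra)):
                P.append(ma[name])
                Q.append(ra[name])
        P = np.array(P, float)
        Q = np.array(Q, float)
        expected = oracle_min_rmsd(P, Q)
        assert rmsd_heavy(mod, ref) == pytest.approx(expected, abs=1e-6)
        # and never worse than the naive no-refit value 2/sqrt(5)
        assert rmsd_heavy(mod, ref) <= 2 / np.sqrt(5) + 1e-9

    def test_hydrogens_excluded_and_names_intersected(self):
        ref = _toy_model([{"C3'": (0, 0, 0), "H1'": (0, 0, 1), "P": (1, 0, 0),
                           "N1": (0, 1, 0), "C4": (1, 1, 0)}])
        mod = _toy_model([{"C3'": (0, 0, 0), "H1'": (9, 9, 9), "P": (1, 0, 0),
                           "N1": (0, 1, 0), "O2": (2, 2, 2)}])
        # shared heavy atoms C3', P, N1 are identical; H1' ignored
        assert rmsd_heavy(mod, ref) == pytest.approx(0.0, abs=1e-9)

    def test_residue_count_mismatch_rejected(self):
        m = self._pair()
        one = _toy_model([{"C3'": (0, 0, 0), "P": (1, 0, 0), "N1": (0, 1, 0)}])
        with pytest.raises(GeometryError, match="residue count"):
            rmsd_heavy(m, one)


class TestCoreTraceAndMatrix:
    def test_trace_follows_core_columns(self, small_dataset):
        ds = small_dataset
        core = conserved_core(ds.alignment, list(ds.model_set.homologs))
        model = ds.model_set.models[0]
        trace = core_trace(model, core)
        assert trace.points.shape == (core.size, 3)
        idxs = core.per_seq[model.homolog]
        np.testing.assert_allclose(
            trace.points[3], model.residues[idxs[3]].atoms["C3'"]
        )

    def test_missing_core_residue_names_the_column(self, small_dataset):
        ds = small_dataset
        core = conserved_core(ds.alignment, list(ds.model_set.homologs))
        model = ds.model_set.models[0]
        truncated = StructureModel(
            "trunc", model.homolog, 1, model.residues[:3]
        )
        with pytest.raises(StructureError, match="core column"):
            core_trace(truncated, core)

    def test_core_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(6)
        a = CoreTrace("a", rng.normal(size=(12, 3)) * 5)
        b = CoreTrace("b", rng.normal(size=(12, 3)) * 5)
        assert core_rmsd(a, b) == core_rmsd(b, a)
        moved = CoreTrace("a2", rigid(a.points, seed=13))
        assert abs(core_rmsd(moved, b) - core_rmsd(a, b)) <= 1e-6

    def test_core_rmsd_triangle_inequality(self):
        rng = np.random.default_rng(7)
        traces = [CoreTrace(f"t{i}", rng.normal(size=(10, 3)) * 4) for i in range(8)]
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    dij = core_rmsd(traces[i], traces[j])
                    djk = core_rmsd(traces[j], traces[k])
                    dik = core_rmsd(traces[i], traces[k])
                    assert dik <= dij + djk + 1e-9

    def test_cross_homolog_traces_compare_despite_length_differences(
        self, small_dataset
    ):
        ds = small_dataset
        core = conserved_core(ds.alignment, list(ds.model_set.homologs))
        homs = ds.model_set.homologs
        a = core_trace(ds.model_set.of_homolog(homs[0])[0], core)
        b = core_trace(ds.model_set.of_homolog(homs[1])[0], core)
        assert len(ds.model_set.of_homolog(homs[0])[0]) != len(
            ds.model_set.of_homolog(homs[1])[0]
        )
        assert np.isfinite(core_rmsd(a, b))

    def test_all_vs_all_matches_pairwise_loop(self, small_dataset):
        ds = small_dataset
        core = conserved_core(ds.alignment, list(ds.model_set.homologs))
        subset = ds.model_set.models[::4]
        matrix = all_vs_all(subset, core)
        traces = [core_trace(m, core) for m in subset]
        for i in range(len(traces)):
            assert matrix.values[i, i] == 0.0
            for j in range(i + 1, len(traces)):
                expected = core_rmsd(traces[i], traces[j])
                assert matrix.values[i, j] == pytest.approx(expected, abs=1e-9)
                assert matrix.values[i, j] == matrix.values[j, i]

    def test_matrix_text_roundtrip(self, tmp_path, small_dataset):
        ds = small_dataset
        core = conserved_core(ds.alignment, list(ds.model_set.homologs))
        matrix = all_vs_all(ds.model_set.models[:6], core)
        path = tmp_path / "dm.txt"
        matrix.write_text(path)
        back = DistanceMatrix.read_text(path)
        assert back.ids == matrix.ids
        np.testing.assert_allclose(back.values, matrix.values, atol=5.1e-4)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(GeometryError):
            DistanceMatrix(ids=("a", "b"), values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(GeometryError):
            DistanceMatrix(ids=("a",), values=np.array([[np.nan]]))
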