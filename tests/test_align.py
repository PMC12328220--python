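"""Superposition, residue mapping, TM-scores, orthogroup refinement."""
import numpy as np
import pytest

from structcons.align import (align_and_map, kabsch_superpose,
                              refine_orthogroups, tm_d0, tm_score,
                              ResidueMapping)
from structcons.exceptions import InsufficientPairsError, UndefinedStatisticError
from structcons.synthetic import build_toy_fold

from conftest import make_ca_model


def rotation_about_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0],
                     [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])


def grid_min_rmsd(a, b, n=40000, seed=0):
    """Brute-force oracle: minimum RMSD over random uniform rotations
    (translation solved by centroid matching)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    moved = np.einsum("nij,kj->nki", R, bc)
    rmsd = np.sqrt(((moved - ac) ** 2).sum(axis=2).mean(axis=1))
    return float(rmsd.min())


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation_translation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        R = rotation_about_z(90)
        b = a @ R.T + np.array([1.0, 2.0, 3.0])
        # superposing b onto a must invert the applied transform
        sup = kabsch_superpose(a, b)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(sup.rotation, R.T, atol=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            sup = kabsch_superpose(a, b)
            oracle = grid_min_rmsd(a, b)
            assert sup.rmsd <= oracle + 1e-9  # Kabsch is optimal
            assert oracle - sup.rmsd < 1e-2   # coarse grid agreement

    def test_reflection_not_allowed(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored cloud
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)
        assert sup.rmsd > 0.1

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientPairsError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_but_solved(self):
        a = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        sup = kabsch_superpose(a, a)
        assert sup.degenerate
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)


class TestTMScore:
    def test_identity_full_coverage_is_one(self):
        m = build_toy_fold(seed=0)
        res = align_and_map(m, m)
        assert res.tm_ref == pytest.approx(1.0, abs=1e-9)
        assert res.tm_bidir == pytest.approx(1.0, abs=1e-9)
        assert res.superposition.rmsd == pytest.approx(0.0, abs=1e-6)
        assert len(res.mapping) == len(m)

    def test_all_distances_at_d0_gives_half(self):
        n = 30
        coords = np.c_[np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]
        ref = make_ca_model("A" * n, coords, "r")
        d0 = tm_d0(n)
        mem = make_ca_model("A" * n, coords + np.array([0, d0, 0]), "m")
        mapping = ResidueMapping([(i + 1, i + 1) for i in range(n)])
        from structcons.align import SuperpositionResult
        ident = SuperpositionResult(np.eye(3), np.zeros(3), d0, n)
        assert tm_score(mapping, ref, mem, ident) == pytest.approx(0.5, abs=1e-12)

    def test_five_residue_toy_matches_hand_formula(self):
        # distances 0, 1, 2, 3, 4 A under the identity superposition
        coords = np.c_[np.arange(5) * 3.8, np.zeros(5), np.zeros(5)]
        ref = make_ca_model("AAAAA", coords, "r")
        offsets = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        mem = make_ca_model("AAAAA", coords + np.c_[np.zeros(5), offsets,
                                                    np.zeros(5)], "m")
        mapping = ResidueMapping([(i + 1, i + 1) for i in range(5)])
        from structcons.align import SuperpositionResult
        ident = SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 5)
        d0 = 0.5  # floored for L < 21
        expected = sum(1.0 / (1.0 + (d / d0) ** 2) for d in offsets) / 5
        got = tm_score(mapping, ref, mem, ident)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_mapping_undefined(self):
        m = build_toy_fold(seed=0)
        with pytest.raises(ValueError):
            ResidueMapping([(2, 2), (1, 1)])  # not monotone
        with pytest.raises(UndefinedStatisticError):
            from structcons.align import SuperpositionResult
            tm_score(ResidueMapping([]), m, m,
                     SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0))


class TestAlignAndMap:
    def test_terminal_deletion_counts_toward_member_n(self):
        ref = build_toy_fold(seed=5)
        from structcons.io import ResidueRecord, StructureModel
        trimmed = [ResidueRecord("A", i + 1, r.aa, r.atoms, r.plddt)
                   for i, r in enumerate(ref.residues[6:])]
        mem = StructureModel("trunc", trimmed)
        res = align_and_map(ref, mem)
        assert res.mapping.ref_indices.min() == 7
        assert res.mapping.ref_indices.max() == len(ref)
        assert len(res.mapping) == len(mem)  # every member residue mapped

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_member_mostly_mapped(self, seed):
        ref = build_toy_fold(seed=17)
        rng = np.random.default_rng(seed)
        from structcons.io import ResidueRecord, StructureModel
        noisy = [ResidueRecord("A", r.seq_index, r.aa,
                               [(n, e, xyz + rng.normal(scale=0.5, size=3))
                                for n, e, xyz in r.atoms], r.plddt)
                 for r in ref.residues]
        mem = StructureModel("noisy", noisy)
        res = align_and_map(ref, mem)
        assert len(res.mapping) >= 0.95 * len(ref)

    def test_rigid_transform_invariance(self):
        ref = build_toy_fold(seed=7)
        rng = np.random.default_rng(0)
        from structcons.io import ResidueRecord, StructureModel
        R = rotation_about_z(37.0)
        t = np.array([5.0, -3.0, 12.0])
        moved = [ResidueRecord("A", r.seq_index, r.aa,
                               [(n, e, R @ xyz + t) for n, e, xyz in r.atoms],
                               r.plddt)
                 for r in ref.residues]
        mem = StructureModel("moved", moved)
        res0 = align_and_map(ref, ref)
        res1 = align_and_map(ref, mem)
        assert res1.mapping.pairs == res0.mapping.pairs
        assert res1.superposition.rmsd == pytest.approx(res0.superposition.rmsd,
                                                        abs=1e-6)

    def test_iterative_pruning_never_increases_rmsd(self, small_pool):
        from structcons.synthetic import SyntheticSpec, evolve_orthogroup
        anc = small_pool[0]
        og, _ = evolve_orthogroup(anc.model, SyntheticSpec(coord_noise=1.0),
                                  seed=5, pocket=anc.pocket, classes=anc.classes)
        ref = og.structure(og.reference_ids[0])
        for mid in og.member_ids[1:4]:
            res = align_and_map(ref, og.structure(mid))
            trace = res.rmsd_trace
            assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_tm_bidir_symmetric(self):
        a = build_toy_fold(seed=2)
        b = build_toy_fold(seed=3)
        r_ab = align_and_map(a, b)
        r_ba = align_and_map(b, a)
        assert r_ab.tm_bidir == pytest.approx(r_ba.tm_bidir, abs=5e-2)
        # within a single alignment the symmetrization is exact
        assert r_ab.tm_bidir == pytest.approx(0.5 * (r_ab.tm_ref + r_ab.tm_mem))


def brute_force_average_linkage(D, cutoff):
    """First-principles agglomerative average linkage with a distance cut."""
    clusters = [[i] for i in range(len(D))]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        if d > cutoff:
            break
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(sorted(c) for c in clusters)


class TestRefineOrthogroups:
    def test_all_identical_single_cluster(self):
        ids = list("abcd")
        tm = np.ones((4, 4))
        assert refine_orthogroups(ids, tm) == [["a", "b", "c", "d"]]

    def test_two_separated_blocks(self):
        ids = list("abcd")
        tm = np.full((4, 4), 0.4)
        tm[:2, :2] = 0.95
        tm[2:, 2:] = 0.95
        np.fill_diagonal(tm, 1.0)
        assert refine_orthogroups(ids, tm, 0.2) == [["a", "b"], ["c", "d"]]

    def test_never_splits_identical_structures(self):
        ids = list("abc")
        tm = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]])
        groups = refine_orthogroups(ids, tm, 0.2)
        joined = next(g for g in groups if "a" in g)
        assert "b" in joined

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        D = rng.uniform(0.0, 1.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        cutoff = 0.35
        ids = [f"s{i}" for i in range(n)]
        got = refine_orthogroups(ids, 1.0 - D, cutoff)
        expected = brute_force_average_linkage(D, cutoff)
        got_idx = sorted(sorted(int(s[1:]) for s in g) for g in got)
        assert got_idx == expected

    def test_asymmetric_matrix_rejected(self):
        tm = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError):
            refine_orthogroups(["a", "b"], tm)
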