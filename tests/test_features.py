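"""SASA, surface/core partition, secondary structure, binding-site flags."""
import numpy as np
import pandas as pd
import pytest

from structcons.features import (assign_secondary_structure, csb_binding_sites,
                                 relative_sasa, shrake_rupley_sasa,
                                 transfer_to_reference, upb_binding_sites)
from structcons.io import LigandRecord, ResidueRecord, StructureModel
from structcons.synthetic import build_backbone, build_toy_fold, segment_classes

from conftest import make_ca_model, straight_chain


def single_atom_model(element="C", xyz=(0.0, 0.0, 0.0)):
    return StructureModel("atom", [ResidueRecord(
        "A", 1, "A", [("CA", element, np.array(xyz, dtype=float))])])


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        m = single_atom_model()
        sasa = shrake_rupley_sasa(m)
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2  # ~120.76 A^2
        assert sasa[0] == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        res = [ResidueRecord("A", 1, "A", [("CA", "C", np.zeros(3))]),
               ResidueRecord("A", 2, "A", [("CA", "C", np.array([30.0, 0, 0]))])]
        m = StructureModel("two", res)
        sasa = shrake_rupley_sasa(m)
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert sasa[0] == pytest.approx(expected, rel=0.01)
        assert sasa[1] == pytest.approx(expected, rel=0.01)

    def test_self_convergence_against_dense_lattice(self):
        rng = np.random.default_rng(5)
        res = [ResidueRecord("A", i + 1, "A",
                             [("CA", "C", rng.uniform(0, 6, size=3))])
               for i in range(8)]
        m = StructureModel("cluster", res)
        coarse = shrake_rupley_sasa(m, n_points=960)
        dense = shrake_rupley_sasa(m, n_points=10000)
        np.testing.assert_allclose(coarse, dense, rtol=0.02, atol=0.5)

    def test_never_exceeds_isolated_sphere(self, toy_fold):
        sasa = shrake_rupley_sasa(toy_fold)
        # four backbone atoms per residue; max area if all were isolated
        per_atom = {"N": 1.55, "C": 1.7, "O": 1.52}
        cap = sum(4 * np.pi * (per_atom[e] + 1.4) ** 2
                  for e in ("N", "C", "C", "O"))
        assert (sasa <= cap + 1e-6).all()


class TestRelativeSasa:
    def test_boundaries(self):
        rsasa, exposure = relative_sasa(np.array([0.0, 129.0]), "AA")
        assert exposure[0] == "core"
        assert rsasa[1] == pytest.approx(1.0)
        assert exposure[1] == "surface"

    def test_threshold_is_configurable(self):
        sasa = np.array([0.3 * 129.0])
        _r, e20 = relative_sasa(sasa, "A", surface_threshold=0.20)
        _r, e35 = relative_sasa(sasa, "A", surface_threshold=0.35)
        assert e20[0] == "surface" and e35[0] == "core"

    def test_unknown_residue_raw_fallback(self):
        rsasa, exposure = relative_sasa(np.array([30.0, 10.0]), "XX")
        assert np.isnan(rsasa).all()
        assert list(exposure) == ["surface", "core"]

    def test_partition_is_total(self, toy_fold):
        sasa = shrake_rupley_sasa(toy_fold)
        _r, exposure = relative_sasa(sasa, toy_fold.sequence)
        assert set(exposure) <= {"surface", "core"}

    @pytest.mark.parametrize("seed", range(10))
    def test_helix_interiors_core_linkers_surface(self, seed):
        """Bundle geometry: buried residues concentrate in secondary
        segments, linker residues stay mostly exposed."""
        m = build_toy_fold(seed=seed)
        from structcons.synthetic import default_blueprint
        seg = segment_classes(default_blueprint())
        sasa = shrake_rupley_sasa(m)
        _r, exposure = relative_sasa(sasa, m.sequence)
        core_frac_ss = np.mean([e == "core" for e, s in zip(exposure, seg)
                                if s != "coil"])
        core_frac_coil = np.mean([e == "core" for e, s in zip(exposure, seg)
                                  if s == "coil"])
        assert core_frac_ss > core_frac_coil


def hbond_oracle(model):
    """Independent Kabsch-Sander style H-bond enumeration (set of (donor,
    acceptor) residue pairs) written against the same energy rule."""
    n = len(model)
    N = np.array([r.atom_xyz("N") for r in model.residues])
    C = np.array([r.atom_xyz("C") for r in model.residues])
    O = np.array([r.atom_xyz("O") for r in model.residues])
    bonds = set()
    for i in range(1, n):
        h = N[i] + (C[i - 1] - O[i - 1]) / np.linalg.norm(C[i - 1] - O[i - 1])
        for j in range(n):
            if abs(i - j) < 2:
                continue
            e = 0.084 * 332.0 * (1 / np.linalg.norm(O[j] - N[i])
                                 + 1 / np.linalg.norm(C[j] - h)
                                 - 1 / np.linalg.norm(O[j] - h)
                                 - 1 / np.linalg.norm(C[j] - N[i]))
            if e < -0.5:
                bonds.add((i, j))
    return bonds


def model_from_backbone(bb, sequence=None):
    n = len(bb["CA"])
    sequence = sequence or "A" * n
    res = []
    for i in range(n):
        atoms = [("N", "N", bb["N"][i]), ("CA", "C", bb["CA"][i]),
                 ("C", "C", bb["C"][i]), ("O", "O", bb["O"][i])]
        res.append(ResidueRecord("A", i + 1, sequence[i], atoms))
    return StructureModel("bb", res)


class TestSecondaryStructure:
    def test_ideal_helix_all_interior_helix(self):
        bb = build_backbone(np.full(20, -57.0), np.full(20, -47.0))
        m = model_from_backbone(bb)
        ss = assign_secondary_structure(m)
        assert ss.method == "hbond"
        interior = ss.classes[2:-2]
        assert all(c == "helix" for c in interior)

    def test_antiparallel_pair_extended_interiors(self):
        """Two ideal strands at the H-bond-optimal antiparallel placement;
        an independent H-bond enumeration confirms the bridge ladder."""
        from structcons.synthetic import Segment, build_toy_fold

        bp = [Segment("strand", 8), Segment("coil", 3), Segment("strand", 8)]
        m = build_toy_fold(bp, seed=1)
        ss = assign_secondary_structure(m)
        bonds = hbond_oracle(m)
        inter = [b for b in bonds if abs(b[0] - b[1]) > 4]
        assert len(inter) >= 3  # the sheet is actually hydrogen bonded
        interior = [3, 4, 5, 14, 15]  # inner strand residues (0-based)
        ext = sum(ss.classes[i] == "extended" for i in interior)
        assert ext >= 3

    def test_isolated_extended_chain_is_coil(self):
        bb = build_backbone(np.full(12, -139.0), np.full(12, 135.0))
        m = model_from_backbone(bb)
        ss = assign_secondary_structure(m)
        assert all(c == "coil" for c in ss.classes)

    def test_short_chain_all_coil(self):
        bb = build_backbone(np.full(4, -57.0), np.full(4, -47.0))
        ss = assign_secondary_structure(model_from_backbone(bb))
        assert ss.classes == ["coil"] * 4

    def test_ca_only_fallback_flags_and_detects_helix(self):
        bb = build_backbone(np.full(20, -57.0), np.full(20, -47.0))
        m = make_ca_model("A" * 20, bb["CA"], "ca_only")
        ss = assign_secondary_structure(m)
        assert ss.method == "ca_fallback"
        assert np.mean([c == "helix" for c in ss.classes]) >= 0.8

    def test_partition_total_and_exclusive(self, toy_fold):
        ss = assign_secondary_structure(toy_fold)
        assert set(ss.classes) <= {"helix", "extended", "turn", "coil"}
        assert len(ss.classes) == len(toy_fold)


class TestCsb:
    def _with_ligand(self, lig_xyz, resname="LIG"):
        chain = straight_chain("AGS")
        lig = LigandRecord(resname, [("C1", "C", np.array(lig_xyz, float))])
        return StructureModel("x", chain.residues, ligands=[lig])

    def test_below_cutoff_flagged(self):
        m = self._with_ligand([0.0, 3.0, 0.0])
        csb, _ = csb_binding_sites(m, distance_cutoff=5.0)
        assert csb[0]

    def test_above_cutoff_not_flagged(self):
        m = self._with_ligand([0.0, 7.2, 0.0])
        csb, _ = csb_binding_sites(m, distance_cutoff=5.0)
        assert not csb.any()

    def test_excluded_additive_ignored(self):
        m = self._with_ligand([0.0, 3.0, 0.0], resname="GOL")
        with pytest.warns(UserWarning):
            csb, _ = csb_binding_sites(m)
        assert not csb.any()

    def test_metal_flagged_separately(self):
        m = self._with_ligand([0.0, 3.0, 0.0], resname="ZN")
        csb, metal = csb_binding_sites(m)
        assert csb[0] and metal[0]

    def test_monotone_in_cutoff(self):
        m = self._with_ligand([0.0, 4.0, 0.0])
        c4, _ = csb_binding_sites(m, distance_cutoff=4.0)
        c6, _ = csb_binding_sites(m, distance_cutoff=6.0)
        assert (c6 | c4 == c6).all()

    def test_planted_pocket_recovered_exactly(self):
        from structcons.synthetic import build_fold_with_pocket, plant_ligand

        m, seed_pocket = build_fold_with_pocket(seed=2)
        m2, pocket = plant_ligand(m, seed_pocket)
        csb, _ = csb_binding_sites(m2, distance_cutoff=5.0)
        assert sorted(np.flatnonzero(csb) + 1) == pocket
        assert set(seed_pocket) <= set(pocket)


class TestUpb:
    def test_rows_set_flags(self):
        m = straight_chain("ACDEFGH")
        tab = pd.DataFrame({"structure_id": ["toy"] * 3,
                            "position": [2, 3, 4],
                            "site_type": ["substrate", "metal", "substrate"]})
        upb, metal, skipped = upb_binding_sites(m, tab)
        assert list(np.flatnonzero(upb) + 1) == [2, 3, 4]
        assert list(np.flatnonzero(metal) + 1) == [3]
        assert skipped == 0

    def test_empty_table_all_false(self):
        m = straight_chain("ACD")
        tab = pd.DataFrame(columns=["structure_id", "position", "site_type"])
        upb, metal, skipped = upb_binding_sites(m, tab)
        assert not upb.any()

    def test_author_numbering_offset_respected(self, missing_ca_pdb):
        """After dropping a residue the author numbering still drives joins."""
        from structcons.io import read_structure

        m = read_structure(missing_ca_pdb)  # residues with author ids 1, 3
        tab = pd.DataFrame({"structure_id": [m.structure_id] * 2,
                            "position": [3, 2], "site_type": ["substrate"] * 2})
        with pytest.warns(UserWarning):
            upb, _m, skipped = upb_binding_sites(m, tab)
        assert list(np.flatnonzero(upb) + 1) == [2]  # author 3 -> index 2
        assert skipped == 1  # author 2 was dropped at parse time


class TestTransfer:
    def test_flags_cross_mapping_with_drop_count(self):
        from structcons.align import ResidueMapping

        mapping = ResidueMapping([(1, 1), (2, 2), (4, 3)])
        member_flags = np.array([True, False, True, True])  # member idx 4 unmapped
        ref_flags, dropped = transfer_to_reference(mapping, member_flags, 5)
        assert list(np.flatnonzero(ref_flags) + 1) == [1, 4]
        assert dropped == 1
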