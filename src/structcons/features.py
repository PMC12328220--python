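"""Per-residue structural features of the reference structure.

Covers solvent accessibility (Shrake-Rupley with a fixed golden-spiral
lattice), the relative-SASA surface/core partition, a hydrogen-bond based
secondary-structure assignment (helix/extended/turn/coil) with a Calpha-only
geometric fallback, contact-site binding residues near retained ligands
(CSb), and curated per-residue annotations joined by author numbering (UPb,
metal, PPI, fold, selection labels).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .align import ResidueMapping
from .io import StructureModel
from .tables import ligand_exclusions, max_sasa_table, metal_resnames, vdw_radii

PROBE_RADIUS = 1.4  # A, water probe
SURFACE_RSASA = 0.25
SS_CLASSES = ("helix", "extended", "turn", "coil")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi),
                 np.sin(theta) * np.sin(phi),
                 np.cos(phi)]


def shrake_rupley_sasa(model: StructureModel, probe_radius: float = PROBE_RADIUS,
                       n_points: int = 960, include_ligands: bool = False) -> np.ndarray:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Each heavy atom is given a solvated sphere of radius vdW + probe sampled
    on a fixed ``n_points`` lattice; the accessible area is the unoccluded
    fraction times the sphere area, summed per residue. Deterministic.
    """
    radii = vdw_radii()
    coords, rads, owner = [], [], []
    for ridx, res in enumerate(model.residues):
        for _name, elem, xyz in res.atoms:
            coords.append(xyz)
            rads.append(radii.get(elem, 1.80) + probe_radius)
            owner.append(ridx)
    if include_ligands:
        for lig in model.ligands:
            for _name, elem, xyz in lig.atoms:
                coords.append(xyz)
                rads.append(radii.get(elem, 1.80) + probe_radius)
                owner.append(-1)
    if not coords:
        raise ValueError("structure has no atoms")
    coords = np.asarray(coords, float)
    rads = np.asarray(rads, float)
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = rads.max()
    sasa = np.zeros(len(model.residues))
    for k in range(len(coords)):
        if owner[k] < 0:
            continue
        surf = coords[k] + rads[k] * pts
        nbrs = [j for j in tree.query_ball_point(coords[k], rads[k] + rmax) if j != k]
        free = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d = np.linalg.norm(surf - coords[j], axis=1)
            free &= d >= rads[j]
            if not free.any():
                break
        sasa[owner[k]] += 4.0 * np.pi * rads[k] ** 2 * free.mean()
    return sasa


def relative_sasa(sasa: np.ndarray, sequence: str,
                  max_table: dict | None = None,
                  surface_threshold: float = SURFACE_RSASA,
                  raw_fallback: float = 25.0):
    """rSASA = SASA / max_SASA(aa), and the surface/core partition.

    Residues of unknown type ('X') get NaN rSASA; their exposure falls back
    to raw SASA >= ``raw_fallback`` A^2. The partition is total.
    """
    table = max_table or max_sasa_table()
    rsasa = np.empty(len(sequence))
    exposure = np.empty(len(sequence), dtype=object)
    for i, (s, aa) in enumerate(zip(sasa, sequence)):
        mx = table.get(aa)
        if mx is None:
            rsasa[i] = np.nan
            exposure[i] = "surface" if s >= raw_fallback else "core"
        else:
            rsasa[i] = s / mx
            exposure[i] = "surface" if rsasa[i] >= surface_threshold else "core"
    return rsasa, exposure


# ---------------------------------------------------------------------------
# Secondary structure (hydrogen-bond based, DSSP-style energy)

_Q1Q2F = 0.084 * 332.0  # kcal/mol, partial-charge electrostatic prefactor
_HB_ENERGY = -0.5


@dataclass
class SecondaryStructure:
    classes: list          # per residue, one of SS_CLASSES
    method: str            # "hbond" or "ca_fallback"


def _hbond_matrix(model: StructureModel) -> np.ndarray:
    """hb[i, j] is True when N-H of residue i donates to C=O of residue j."""
    n = len(model)
    N = np.array([r.atom_xyz("N") for r in model.residues])
    C = np.array([r.atom_xyz("C") for r in model.residues])
    O = np.array([r.atom_xyz("O") for r in model.residues])
    # amide H placed 1 A from N, antiparallel to the preceding C=O
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        d = C[i - 1] - O[i - 1]
        H[i] = N[i] + d / np.linalg.norm(d)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(1, n):  # donor (needs H)
        for j in range(n):  # acceptor
            if abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(O[j] - N[i])
            if r_on > 5.2:  # beyond plausible H-bond geometry
                continue
            r_ch = np.linalg.norm(C[j] - H[i])
            r_oh = np.linalg.norm(O[j] - H[i])
            r_cn = np.linalg.norm(C[j] - N[i])
            if min(r_oh, r_on) < 0.5:
                continue
            E = _Q1Q2F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            hb[i, j] = E < _HB_ENERGY
    return hb


def assign_secondary_structure(model: StructureModel) -> SecondaryStructure:
    """Four-class secondary structure from backbone hydrogen bonding.

    Kabsch-Sander style electrostatic H-bond energy below -0.5 kcal/mol
    defines bonds; consecutive i->i+4 (or i->i+3) turn patterns give helices,
    bridge ladders give extended strands, isolated 3/4/5-turn spans give
    turns, everything else is coil. Chains without full backbones fall back
    to Calpha distance rules (flagged in ``method``).
    """
    n = len(model)
    if n < 5:
        return SecondaryStructure(["coil"] * n, "hbond")
    if not model.has_backbone:
        return _ca_fallback(model)
    hb = _hbond_matrix(model)

    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if hb[i + k, i]:
                turn[k][i] = True

    cls = np.array(["coil"] * n, dtype=object)
    # helix: two consecutive k-turns (alpha first, then 3-10)
    for k in (4, 3):
        for i in range(1, n - k):
            if turn[k][i] and turn[k][i - 1]:
                cls[i:i + k] = "helix"
    # bridges -> extended
    ext = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[i + 1, j - 1] and hb[j + 1, i - 1])
            if para or anti:
                ext[i] = ext[j] = True
    cls[ext & (cls == "coil")] = "extended"
    # turns: within any k-turn span, not already assigned
    in_turn = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in np.flatnonzero(turn[k]):
            in_turn[i:i + k + 1] = True
    cls[in_turn & (cls == "coil")] = "turn"
    return SecondaryStructure(list(cls), "hbond")


def _ca_fallback(model: StructureModel) -> SecondaryStructure:
    """Distance-based assignment from the Calpha trace only."""
    ca = model.ca_coords
    n = len(ca)
    cls = ["coil"] * n

    def d(i, j):
        return float(np.linalg.norm(ca[i] - ca[j]))

    for i in range(n - 4):
        # ideal alpha helix: d(i,i+3) ~ 5.0, d(i,i+4) ~ 6.2
        if 4.2 <= d(i, i + 3) <= 6.5 and 4.9 <= d(i, i + 4) <= 7.2:
            for k in range(i, i + 5):
                cls[k] = "helix"
    for i in range(n - 3):
        # extended strand: near-maximal span
        if cls[i] == "coil" and d(i, i + 2) > 6.3 and d(i, i + 3) > 9.2:
            for k in range(i, i + 4):
                if cls[k] == "coil":
                    cls[k] = "extended"
    for i in range(n - 3):
        if cls[i] == "coil" and d(i, i + 3) < 7.0:
            for k in range(i, i + 4):
                if cls[k] == "coil":
                    cls[k] = "turn"
    return SecondaryStructure(cls, "ca_fallback")


# ---------------------------------------------------------------------------
# Binding sites

def csb_binding_sites(model: StructureModel, distance_cutoff: float = 5.0,
                      exclusions: frozenset | None = None):
    """Contact-site binding flags: residues with any heavy atom within
    ``distance_cutoff`` of a retained ligand heavy atom.

    Crystallographic additives (waters, buffers, simple ions) are excluded
    via the packaged list. Returns (csb flags, metal flags); metal flags mark
    residues contacting a metal ion.
    """
    excl = ligand_exclusions() if exclusions is None else exclusions
    metals = metal_resnames()
    lig_atoms, lig_is_metal = [], []
    for lig in model.ligands:
        if lig.resname in excl and lig.resname not in metals:
            continue
        for _n, _e, xyz in lig.atoms:
            lig_atoms.append(xyz)
            lig_is_metal.append(lig.resname in metals)
    n = len(model)
    csb = np.zeros(n, dtype=bool)
    metal = np.zeros(n, dtype=bool)
    if not lig_atoms:
        warnings.warn(f"{model.structure_id}: no ligands retained; CSb all false")
        return csb, metal
    lig_atoms = np.asarray(lig_atoms, float)
    lig_is_metal = np.asarray(lig_is_metal, bool)
    tree = cKDTree(lig_atoms)
    for i, res in enumerate(model.residues):
        for _n2, _e, xyz in res.atoms:
            hits = tree.query_ball_point(xyz, distance_cutoff)
            if hits:
                csb[i] = True
                if lig_is_metal[hits].any():
                    metal[i] = True
    return csb, metal


def upb_binding_sites(model: StructureModel, annotation: pd.DataFrame):
    """Curated binding-site flags joined via author numbering.

    ``annotation`` has columns structure_id, position (author numbering) and
    site_type in {substrate, cofactor, metal}. Positions not resolvable in
    the chain are skipped and counted. Returns (upb, metal, n_skipped).
    """
    n = len(model)
    upb = np.zeros(n, dtype=bool)
    metal = np.zeros(n, dtype=bool)
    by_author = {}
    for r in model.residues:
        if r.author_seq_id is not None:
            by_author.setdefault(r.author_seq_id, r.seq_index)
    rows = annotation[annotation["structure_id"] == model.structure_id]
    skipped = 0
    for _, row in rows.iterrows():
        pos = int(row["position"])
        idx = by_author.get(pos)
        if idx is None:
            skipped += 1
            continue
        upb[idx - 1] = True
        if str(row.get("site_type", "")) == "metal":
            metal[idx - 1] = True
    if skipped:
        warnings.warn(f"{model.structure_id}: {skipped} annotated positions outside chain")
    return upb, metal, skipped


def transfer_to_reference(mapping: ResidueMapping, member_flags: np.ndarray,
                          ref_length: int):
    """Move boolean per-residue flags from a member (e.g. a holo homologue)
    onto the reference through a residue mapping. Unmapped flagged residues
    are dropped and counted."""
    out = np.zeros(ref_length, dtype=bool)
    mapped_mem = {m: r for r, m in mapping.pairs}
    dropped = 0
    for m_idx in np.flatnonzero(member_flags) + 1:
        r_idx = mapped_mem.get(int(m_idx))
        if r_idx is None:
            dropped += 1
        else:
            out[r_idx - 1] = True
    return out, dropped


def annotate_reference(model: StructureModel, *, n_points: int = 960,
                       surface_threshold: float = SURFACE_RSASA,
                       csb_cutoff: float = 5.0,
                       upb_table: pd.DataFrame | None = None,
                       extra_flags: dict | None = None) -> pd.DataFrame:
    """Full per-residue feature table for a reference structure."""
    sasa = shrake_rupley_sasa(model, n_points=n_points)
    rsasa, exposure = relative_sasa(sasa, model.sequence,
                                    surface_threshold=surface_threshold)
    ss = assign_secondary_structure(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        csb, metal_c = csb_binding_sites(model, distance_cutoff=csb_cutoff)
    upb = np.zeros(len(model), dtype=bool)
    metal_u = np.zeros(len(model), dtype=bool)
    if upb_table is not None:
        upb, metal_u, _ = upb_binding_sites(model, upb_table)
    df = pd.DataFrame({
        "ref_idx": np.arange(1, len(model) + 1),
        "aa": list(model.sequence),
        "sasa": sasa, "rsasa": rsasa, "exposure": exposure,
        "ss_class": ss.classes, "ss_method": ss.method,
        "upb": upb, "csb": csb, "metal_site": metal_c | metal_u,
        "ppi": False, "fold_member": False, "selection_label": None,
    })
    for col, arr in (extra_flags or {}).items():
        df[col] = arr
    return df
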