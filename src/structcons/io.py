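"""Structure input/output and the in-memory data model.

Structures are read from PDB or mmCIF via gemmi into a light ``StructureModel``
of ordered residues (one model per chain by default). Predicted models carry
per-residue pLDDT in the B-factor column; ``plddt_from_bfactor`` lifts it onto
the residues. Heteroatoms other than water are retained separately as ligands
so that contact-site (CSb) binding residues can be detected later.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (EmptyStructureError, MissingAnnotationError,
                         StructureFormatError)
from .tables import NONSTANDARD_PARENT


@dataclass
class ResidueRecord:
    """One polymer residue: identity, coordinates and optional pLDDT.

    ``seq_index`` is the sequential 1-based position in the chain after
    flattening insertion codes; the original author numbering is kept in
    ``author_seq_id`` for joining external annotation tables.
    """

    chain_id: str
    seq_index: int
    aa: str
    atoms: list  # list of (atom_name, element, xyz ndarray) for heavy atoms
    plddt: float | None = None
    author_seq_id: int | None = None
    icode: str = ""

    def atom_xyz(self, name: str) -> np.ndarray | None:
        for n, _e, xyz in self.atoms:
            if n == name:
                return xyz
        return None

    @property
    def ca_xyz(self) -> np.ndarray:
        xyz = self.atom_xyz("CA")
        if xyz is None:
            raise ValueError(f"residue {self.seq_index} has no CA atom")
        return xyz

    @property
    def has_backbone(self) -> bool:
        return all(self.atom_xyz(n) is not None for n in ("N", "CA", "C", "O"))


@dataclass
class LigandRecord:
    """A non-polymer heteroatom group (small molecule, metal, cofactor)."""

    resname: str
    atoms: list  # list of (atom_name, element, xyz)


@dataclass
class StructureModel:
    """An ordered single-chain protein model (the unit of the corpus)."""

    structure_id: str
    residues: list
    source: str = "predicted"  # or "experimental"
    ligands: list = field(default_factory=list)
    n_dropped_no_ca: int = 0

    def __post_init__(self):
        self._check()

    def _check(self):
        prev = 0
        for r in self.residues:
            if r.seq_index != prev + 1:
                raise ValueError(
                    f"{self.structure_id}: seq_index must be sequential from 1 "
                    f"(got {r.seq_index} after {prev})")
            prev = r.seq_index
            if r.plddt is not None and not (0.0 <= r.plddt <= 100.0):
                raise ValueError(f"pLDDT out of [0,100]: {r.plddt}")

    def __len__(self):
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    @property
    def plddt(self) -> np.ndarray | None:
        vals = [r.plddt for r in self.residues]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    @property
    def has_backbone(self) -> bool:
        return all(r.has_backbone for r in self.residues)


@dataclass
class Orthogroup:
    """A set of orthologous structures anchored to one or more references."""

    og_id: str
    member_ids: list
    reference_ids: list
    structures: dict  # structure_id -> StructureModel

    def __post_init__(self):
        for rid in self.reference_ids:
            if rid not in self.member_ids:
                raise ValueError(f"reference {rid} is not a member of {self.og_id}")
        if len(self.member_ids) < 2:
            raise ValueError(f"orthogroup {self.og_id} needs >=2 members")

    def structure(self, sid: str) -> StructureModel:
        return self.structures[sid]


_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def _one_letter(resname: str) -> str:
    if resname in NONSTANDARD_PARENT:
        return NONSTANDARD_PARENT[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha() and code != " ":
            return code
    return "X"


def _is_amino(resname: str) -> bool:
    if resname in NONSTANDARD_PARENT:
        return True
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def read_structures(path, fmt: str | None = None, plddt_from_bfactor: bool = False,
                    merge_chains: bool = False, source: str = "predicted",
                    structure_id: str | None = None) -> list[StructureModel]:
    """Parse a PDB/mmCIF file into one StructureModel per chain.

    Waters are discarded, alternate conformations resolved to the first
    conformer, residues lacking a Calpha dropped (and counted), and non-polymer
    heteroatom groups kept as ligands on the chain they belong to (on the
    merged model when ``merge_chains``).
    """
    path = Path(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=_FORMATS[fmt])
    except (RuntimeError, ValueError, KeyError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]

    base_id = structure_id or path.stem
    chains: list[tuple[str, list[ResidueRecord], list[LigandRecord], int]] = []
    for chain in model:
        recs: list[ResidueRecord] = []
        ligs: list[LigandRecord] = []
        dropped = 0
        for res in chain:
            atoms = [(a.name, a.element.name.upper(), np.array(a.pos.tolist()))
                     for a in res]
            if _is_amino(res.name):
                ca = next((xyz for n, _e, xyz in atoms if n == "CA"), None)
                if ca is None:
                    dropped += 1
                    continue
                plddt = None
                if plddt_from_bfactor:
                    b = next((a.b_iso for a in res if a.name == "CA"), None)
                    if b is None or not (0.0 <= b <= 100.0):
                        raise MissingAnnotationError(
                            f"{path} {chain.name}/{res.seqid.num}: B-factor {b!r} "
                            "is not a valid pLDDT")
                    plddt = float(b)
                recs.append(ResidueRecord(
                    chain_id=chain.name, seq_index=len(recs) + 1,
                    aa=_one_letter(res.name), atoms=atoms, plddt=plddt,
                    author_seq_id=res.seqid.num, icode=res.seqid.icode.strip()))
            else:
                ligs.append(LigandRecord(res.name, atoms))
        if recs or ligs:
            chains.append((chain.name, recs, ligs, dropped))

    if not any(recs for _n, recs, _l, _d in chains):
        raise EmptyStructureError(f"{path}: zero standard residues")

    if merge_chains:
        all_recs, all_ligs, dropped = [], [], 0
        for _name, recs, ligs, d in chains:
            for r in recs:
                all_recs.append(ResidueRecord(r.chain_id, len(all_recs) + 1, r.aa,
                                              r.atoms, r.plddt, r.author_seq_id, r.icode))
            all_ligs.extend(ligs)
            dropped += d
        return [StructureModel(base_id, all_recs, source=source, ligands=all_ligs,
                               n_dropped_no_ca=dropped)]

    out = []
    polymer_chains = [c for c in chains if c[1]]
    # ligand-only chains are attached to the nearest polymer chain's model
    orphan_ligs = [l for name, recs, ligs, _d in chains if not recs for l in ligs]
    for name, recs, ligs, dropped in polymer_chains:
        sid = base_id if len(polymer_chains) == 1 else f"{base_id}_{name}"
        out.append(StructureModel(sid, recs, source=source,
                                  ligands=ligs + (orphan_ligs if len(polymer_chains) == 1 else []),
                                  n_dropped_no_ca=dropped))
    if len(polymer_chains) > 1 and orphan_ligs:
        out[0].ligands.extend(orphan_ligs)
    return out


def read_structure(path, fmt: str | None = None, plddt_from_bfactor: bool = False,
                   merge_chains: bool = False, source: str = "predicted",
                   structure_id: str | None = None) -> StructureModel:
    """As :func:`read_structures`, for files expected to hold a single chain."""
    models = read_structures(path, fmt, plddt_from_bfactor, merge_chains,
                             source, structure_id)
    if len(models) != 1:
        raise StructureFormatError(
            f"{path}: {len(models)} chains; pass merge_chains=True or use read_structures")
    return models[0]


def write_pdb(model: StructureModel, path) -> None:
    """Serialize a StructureModel to PDB (pLDDT, when present, as B-factor)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain(model.residues[0].chain_id if model.residues else "A")
    for r in model.residues:
        res = gemmi.Residue()
        res.name = _three_letter(r.aa)
        res.seqid = gemmi.SeqId(r.author_seq_id or r.seq_index, r.icode or " ")
        for name, elem, xyz in r.atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(elem)
            at.pos = gemmi.Position(*map(float, xyz))
            at.occ = 1.0
            at.b_iso = float(r.plddt) if r.plddt is not None else 0.0
            res.add_atom(at)
        chain.add_residue(res)
    gm.add_chain(chain)
    for i, lig in enumerate(model.ligands):
        lc = gemmi.Chain("Z")
        res = gemmi.Residue()
        res.name = lig.resname
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "H"
        for name, elem, xyz in lig.atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(elem)
            at.pos = gemmi.Position(*map(float, xyz))
            at.occ = 1.0
            res.add_atom(at)
        lc.add_residue(res)
        gm.add_chain(lc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def _three_letter(aa: str) -> str:
    return _THREE.get(aa, "UNK")


def plddt_summary(model: StructureModel, terminal_fraction: float = 0.10) -> dict:
    """Whole-chain and terminal-segment pLDDT summaries.

    Segment boundaries fall at ``floor(f*L)`` and ``L - floor(f*L)`` so the
    first/central/last segments partition the chain; ``cv`` is the ratio of
    the (population) standard deviation to the mean.
    """
    vals = model.plddt
    if vals is None:
        raise MissingAnnotationError(f"{model.structure_id}: pLDDT absent")
    L = len(vals)
    k = math.floor(terminal_fraction * L)
    mean_all = float(vals.mean())
    return {
        "mean_all": mean_all,
        "cv_all": float(vals.std() / mean_all) if mean_all else float("nan"),
        "mean_first": float(vals[:k].mean()) if k else float("nan"),
        "mean_central": float(vals[k:L - k].mean()) if L - 2 * k else float("nan"),
        "mean_last": float(vals[L - k:].mean()) if k else float("nan"),
    }


def write_fasta(models: list[StructureModel], path) -> None:
    """Write sequences to FASTA with the structure_id as header."""
    if not models:
        warnings.warn("writing empty FASTA: no structures given")
    records = [SeqRecord(Seq(m.sequence), id=m.structure_id, description="")
               for m in models]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_manifest(models: list[StructureModel], og_of: dict[str, str], path) -> None:
    """Write the structures manifest TSV (structure_id, og_id, length, mean pLDDT)."""
    import pandas as pd

    rows = []
    for m in models:
        p = m.plddt
        rows.append({"structure_id": m.structure_id,
                     "og_id": og_of.get(m.structure_id, ""),
                     "length": len(m),
                     "mean_plddt": float(p.mean()) if p is not None else float("nan")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
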