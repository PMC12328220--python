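"""Pairwise structural superposition, residue mapping and orthogroup refinement.

The alignment protocol mirrors the classic matchmaker strategy: a global
sequence alignment seeds Calpha pairs, a Kabsch superposition is fitted, pairs
further than ``prune_cutoff`` are iteratively pruned with re-superposition
until stable, and the final 1:1 mapping keeps aligned pairs whose superposed
Calpha distance is at most ``map_cutoff``. Similarity between two structures
is summarised by a bidirectional TM-score (mean of the two length
normalisations), and orthogroups are refined by average-linkage hierarchical
clustering on 1 - TM at a fixed cophenetic cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import (AlignmentFailureError, InsufficientPairsError,
                         UndefinedStatisticError)
from .io import StructureModel


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping the second point set onto the first."""

    rotation: np.ndarray   # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_pairs: int
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ResidueMapping:
    """Ordered, colinear 1:1 residue correspondence (1-based seq indices)."""

    pairs: list  # list of (ref_seq_index, mem_seq_index)

    def __post_init__(self):
        prev_r = prev_m = 0
        for r, m in self.pairs:
            if r <= prev_r or m <= prev_m:
                raise ValueError("mapping must be strictly increasing in both columns")
            prev_r, prev_m = r, m

    def __len__(self):
        return len(self.pairs)

    @property
    def ref_indices(self) -> np.ndarray:
        return np.array([r for r, _ in self.pairs], dtype=int)

    @property
    def mem_indices(self) -> np.ndarray:
        return np.array([m for _, m in self.pairs], dtype=int)


@dataclass
class AlignParams:
    """Parameters of the matchmaker-style alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    ss_bonus: float = 0.0      # +bonus for matching secondary-structure class
    prune_cutoff: float = 2.0  # A, iterative pruning
    map_cutoff: float = 5.0    # A, final 1:1 mapping
    max_iter: int = 20


@dataclass
class AlignmentResult:
    member_id: str
    reference_id: str
    mapping: ResidueMapping
    superposition: SuperpositionResult
    tm_ref: float
    tm_mem: float
    d0_ref: float
    d0_mem: float
    n_initial_pairs: int
    rmsd_trace: list = field(default_factory=list)

    @property
    def tm_bidir(self) -> float:
        return 0.5 * (self.tm_ref + self.tm_mem)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rotation/translation of ``coords_b`` onto ``coords_a`` (Kabsch).

    Uses SVD of the covariance with reflection correction (the sign of the
    smallest singular vector is flipped when the determinant is negative).
    Collinear/degenerate point sets are flagged but still solved.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be paired (n, 3)")
    if len(a) < 3:
        raise InsufficientPairsError(f"need >=3 pairs, got {len(a)}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN coordinates")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb).T @ (a - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    degenerate = S[1] < 1e-8 * max(S[0], 1.0)  # rank < 2: collinear points
    t = ca - R @ cb
    moved = b @ R.T + t
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(R, t, rmsd, len(a), degenerate=degenerate)


def _sequence_align(ref_seq: str, mem_seq: str, params: AlignParams,
                    ref_ss=None, mem_ss=None) -> list[tuple[int, int]]:
    """Global affine-gap sequence alignment; returns 0-based aligned index pairs."""
    if params.ss_bonus and ref_ss is not None and mem_ss is not None:
        return _gotoh_align(ref_seq, mem_seq, params, ref_ss, mem_ss)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(ref_seq, mem_seq)[0]
    pairs = []
    for (rs, re_), (ms, me) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(rs, re_), range(ms, me)))
    return pairs


def _gotoh_align(ref_seq, mem_seq, params, ref_ss, mem_ss):
    """Affine-gap Needleman-Wunsch with a per-position secondary-structure bonus."""
    mat = substitution_matrices.load(params.matrix)
    n, m = len(ref_seq), len(mem_seq)
    S = np.empty((n, m))
    for i, a in enumerate(ref_seq):
        for j, b in enumerate(mem_seq):
            s = mat[a, b] if (a in mat.alphabet and b in mat.alphabet) else mat["X", "X"]
            if ref_ss[i] == mem_ss[j]:
                s += params.ss_bonus
            S[i, j] = s
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in mem (ref advances)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Iy[0, j] = -go - (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best + S[i - 1, j - 1]
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j] - ge)
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1] - ge)
    # traceback
    pairs = []
    i, j = n, m
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            up_m = M[i - 1, j] - go
            state = 0 if up_m >= Ix[i - 1, j] - ge else 1
            i -= 1
        elif state == 2 and j > 0:
            left_m = M[i, j - 1] - go
            state = 0 if left_m >= Iy[i, j - 1] - ge else 2
            j -= 1
        else:
            state = 1 if i > 0 else 2
    pairs.reverse()
    return pairs


def align_and_map(ref: StructureModel, mem: StructureModel,
                  params: AlignParams | None = None,
                  ref_ss=None, mem_ss=None) -> AlignmentResult:
    """Matchmaker-style alignment of a member structure onto the reference.

    Steps: global sequence alignment, Kabsch superposition on aligned Calpha
    pairs, iterative pruning of pairs beyond ``prune_cutoff`` with refitting,
    and a final mapping of aligned pairs within ``map_cutoff`` after the last
    superposition. Deterministic given the parameters.
    """
    params = params or AlignParams()
    if len(ref) == 0 or len(mem) == 0:
        raise AlignmentFailureError("empty structure")
    seed = _sequence_align(ref.sequence, mem.sequence, params, ref_ss, mem_ss)
    if len(seed) < 3:
        raise AlignmentFailureError(
            f"{mem.structure_id} vs {ref.structure_id}: <3 aligned pairs")
    ref_ca, mem_ca = ref.ca_coords, mem.ca_coords

    pairs = list(seed)
    rmsd_trace = []
    sup = None
    for _ in range(params.max_iter):
        A = ref_ca[[i for i, _ in pairs]]
        B = mem_ca[[j for _, j in pairs]]
        sup = kabsch_superpose(A, B)
        rmsd_trace.append(sup.rmsd)
        d = np.linalg.norm(sup.apply(B) - A, axis=1)
        keep = d <= params.prune_cutoff
        if keep.sum() < 3 or keep.all():
            break
        pairs = [p for p, k in zip(pairs, keep) if k]

    # final mapping over ALL seed pairs under the final superposition
    A = ref_ca[[i for i, _ in seed]]
    B = mem_ca[[j for _, j in seed]]
    d = np.linalg.norm(sup.apply(B) - A, axis=1)
    mapped = [(i + 1, j + 1) for (i, j), di in zip(seed, d) if di <= params.map_cutoff]
    if len(mapped) < 3:
        raise AlignmentFailureError(
            f"{mem.structure_id} vs {ref.structure_id}: <3 mapped pairs at "
            f"{params.map_cutoff} A")
    mapping = ResidueMapping(mapped)
    tm_r = tm_score(mapping, ref, mem, sup, normalize_by="ref")
    tm_m = tm_score(mapping, ref, mem, sup, normalize_by="mem")
    return AlignmentResult(
        member_id=mem.structure_id, reference_id=ref.structure_id,
        mapping=mapping, superposition=sup, tm_ref=tm_r, tm_mem=tm_m,
        d0_ref=tm_d0(len(ref)), d0_mem=tm_d0(len(mem)),
        n_initial_pairs=len(seed), rmsd_trace=rmsd_trace)


def tm_d0(L: int) -> float:
    """TM-score distance scale; floored at 0.5 A so short chains are defined."""
    if L > 15:
        return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)
    return 0.5


def tm_score(mapping: ResidueMapping, ref: StructureModel, mem: StructureModel,
             superposition: SuperpositionResult, normalize_by: str = "ref") -> float:
    """TM-score of a mapping under a given superposition.

    TM = (1/L_norm) * sum_i 1/(1 + (d_i/d0)^2) over mapped pairs, with
    L_norm the length of the normalising structure.
    """
    if len(mapping) == 0:
        raise UndefinedStatisticError("empty mapping has no TM-score")
    L = len(ref) if normalize_by == "ref" else len(mem)
    d0 = tm_d0(L)
    A = ref.ca_coords[mapping.ref_indices - 1]
    B = mem.ca_coords[mapping.mem_indices - 1]
    d = np.linalg.norm(superposition.apply(B) - A, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)


def bidirectional_tm(res: AlignmentResult, mode: str = "mean") -> float:
    """Symmetrised TM-score (mean by default; min/max switchable)."""
    pair = (res.tm_ref, res.tm_mem)
    return {"mean": lambda p: 0.5 * sum(p), "min": min, "max": max}[mode](pair)


def tm_matrix(structures: list[StructureModel],
              params: AlignParams | None = None) -> "pd.DataFrame":
    """Symmetric bidirectional-TM matrix over a list of structures."""
    import pandas as pd

    ids = [s.structure_id for s in structures]
    n = len(ids)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = align_and_map(structures[i], structures[j], params)
                M[i, j] = M[j, i] = r.tm_bidir
            except AlignmentFailureError:
                M[i, j] = M[j, i] = 0.0
    return pd.DataFrame(M, index=ids, columns=ids)


def refine_orthogroups(structure_ids: list[str], tm: np.ndarray,
                       linkage_cutoff: float = 0.2) -> list[list[str]]:
    """Split structures into orthogroups by average-linkage clustering.

    Distance is 1 - bidirectional TM; flat clusters are cut at cophenetic
    distance <= ``linkage_cutoff``. Clusters are returned sorted by their
    lexicographically smallest member (deterministic tie-break).
    """
    tm = np.asarray(tm, dtype=float)
    if tm.shape[0] != tm.shape[1] or not np.allclose(tm, tm.T, atol=1e-9):
        raise ValueError("tm matrix must be square and symmetric")
    if len(structure_ids) != tm.shape[0]:
        raise ValueError("ids and matrix size mismatch")
    if len(structure_ids) == 1:
        return [list(structure_ids)]
    D = 1.0 - tm
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=linkage_cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(structure_ids, labels):
        groups.setdefault(lab, []).append(sid)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: g[0])
    return out
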