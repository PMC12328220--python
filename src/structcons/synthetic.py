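"""Synthetic orthogroups with planted ground truth.

Toy folds are assembled from ideal secondary-structure fragments (built from
canonical phi/psi backbone geometry) laid out as a compact bundle, with
self-avoiding random-coil linkers. A designated pocket (the planted binding
site) is chosen at the bundle centre so its residues are mutually close.
Members of an orthogroup evolve from the ancestor by class-dependent
Bernoulli substitutions (binding < core < surface rates), Gaussian
coordinate noise and terminal indels, so expected identity per class is
exactly 1 - p_class. Property tables couple abundance, flux variability and
k_cat variability to the true divergence with Gaussian noise.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Orthogroup, ResidueRecord, StructureModel
from .tables import CANONICAL_AA

# ideal backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d from three predecessors."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(torsion),
                   bond * math.sin(angle) * math.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict:
    """Build an ideal peptide backbone (N, CA, C, O arrays) from phi/psi.

    omega is fixed at 180 degrees; phi[0] is unused. The carbonyl oxygen is
    placed in the peptide plane anti to the next amide nitrogen.
    """
    n = len(phi)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = math.radians(_A_N_CA_C)
    C[0] = CA[0] + [-_B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0]
    for i in range(1, n):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    for i in range(n):
        O[i] = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


@functools.lru_cache(maxsize=32)
def _ideal_fragment(ss: str, length: int) -> tuple:
    phi0, psi0 = PHI_PSI[ss]
    bb = build_backbone(np.full(length, phi0), np.full(length, psi0))
    return tuple((k, v.copy()) for k, v in bb.items())


def _fragment(ss: str, length: int) -> dict:
    return {k: v.copy() for k, v in _ideal_fragment(ss, length)}


def _axis_align(bb: dict, direction: np.ndarray, roll_deg: float = 0.0) -> dict:
    """Rotate a fragment so its CA start->end axis matches ``direction``."""
    ca = bb["CA"]
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    v = np.cross(axis, direction)
    c = float(np.dot(axis, direction))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))
    th = math.radians(roll_deg)
    ct, st = math.cos(th), math.sin(th)
    u = direction
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    Rr = np.eye(3) + st * K + (1 - ct) * (K @ K)
    M = Rr @ R
    origin = ca[0]
    out = {k: (v - origin) @ M.T for k, v in bb.items()}
    # recentre so the segment axis (CA centroid) sits on the z-axis and the
    # chain starts at z = 0; rolling then spins the body in place
    ca_new = out["CA"]
    shift = np.array([ca_new[:, 0].mean(), ca_new[:, 1].mean(), ca_new[0, 2]])
    return {k: v - shift for k, v in out.items()}


def _hbond_count(bb1: dict, bb2: dict) -> int:
    """Inter-fragment backbone H-bond count (same energy rule as the
    feature module's assignment)."""
    from .features import _Q1Q2F, _HB_ENERGY

    def partners(don, acc):
        cnt = 0
        N, C1, O1 = don["N"], don["C"], don["O"]
        for i in range(1, len(N)):
            d = C1[i - 1] - O1[i - 1]
            H = N[i] + d / np.linalg.norm(d)
            for j in range(len(acc["N"])):
                r_on = np.linalg.norm(acc["O"][j] - N[i])
                if r_on > 5.2:
                    continue
                E = _Q1Q2F * (1 / r_on + 1 / np.linalg.norm(acc["C"][j] - H)
                              - 1 / np.linalg.norm(acc["O"][j] - H)
                              - 1 / np.linalg.norm(acc["C"][j] - N[i]))
                if E < _HB_ENERGY:
                    cnt += 1
        return cnt

    return partners(bb1, bb2) + partners(bb2, bb1)


@functools.lru_cache(maxsize=32)
def _antiparallel_placement(len_a: int, len_b: int) -> tuple:
    """Grid-search the rigid placement of an antiparallel partner strand that
    maximises backbone H-bonds with an ideal strand along +z."""
    a = _axis_align(_fragment("strand", len_a), [0, 0, 1.0])
    best, best_n = (4.8, 0.0, 0.0), -1
    top_z = a["CA"][-1][2]
    for dy in np.arange(4.2, 5.6, 0.2):
        for dz in np.arange(-2.0, 2.01, 0.5):
            for roll in range(0, 360, 30):
                b = _axis_align(_fragment("strand", len_b), [0, 0, -1.0], roll)
                b = {k: v + np.array([0.0, dy, top_z + dz]) for k, v in b.items()}
                ca_d = np.linalg.norm(a["CA"][:, None] - b["CA"][None, :], axis=-1)
                if ca_d.min() < 3.9:  # would register as a chain clash
                    continue
                nhb = _hbond_count(a, b)
                if nhb > best_n:
                    best_n, best = nhb, (float(dy), float(dz), float(roll))
    return best + (best_n,)


def _bridge_walk(start, end, n, rng, bond=3.8, n_iter=80, obstacles=None,
                 avoid=4.0):
    """Self-consistent fixed-bond walk of n points from ``start`` to ``end``
    (endpoints are virtual anchors, not part of the walk). Interior points
    are pushed away from ``obstacles`` closer than ``avoid`` A."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    t = np.linspace(0, 1, n + 2)[1:-1, None]
    pts = start + t * (end - start)
    pts = pts + rng.normal(scale=1.2, size=pts.shape)
    full = np.vstack([start, pts, end])
    for _ in range(n_iter):
        if obstacles is not None and len(obstacles):
            for i in range(1, len(full) - 1):
                diff = full[i] - obstacles
                dist = np.linalg.norm(diff, axis=1)
                close = dist < avoid
                if close.any():
                    j = int(np.argmin(dist))
                    d = dist[j]
                    push = diff[j] / d if d > 1e-9 else rng.normal(size=3)
                    full[i] += (avoid - d) * push
        for i in range(1, len(full)):
            d = full[i] - full[i - 1]
            L = np.linalg.norm(d)
            if L < 1e-9:
                continue
            corr = (L - bond) * d / L
            if i < len(full) - 1:
                full[i] -= 0.5 * corr
                full[i - 1] += 0.5 * corr if i - 1 > 0 else 0.0
            else:
                full[i - 1] += corr if i - 1 > 0 else 0.0
    return full[1:-1]


def _backbone_from_ca(ca: np.ndarray) -> dict:
    """Approximate backbone for coil traces (plausible bond lengths only)."""
    n = len(ca)
    N = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    for i in range(n):
        prev_dir = ca[i - 1] - ca[i] if i > 0 else np.array([-1.0, 0, 0])
        next_dir = ca[i + 1] - ca[i] if i < n - 1 else -prev_dir
        prev_dir = prev_dir / (np.linalg.norm(prev_dir) or 1.0)
        next_dir = next_dir / (np.linalg.norm(next_dir) or 1.0)
        N[i] = ca[i] + 1.46 * prev_dir
        C[i] = ca[i] + 1.52 * next_dir
        perp = np.cross(next_dir, prev_dir)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(next_dir, [0.0, 0.0, 1.0])
        perp = perp / np.linalg.norm(perp)
        O[i] = C[i] + 1.23 * perp
    return {"N": N, "CA": ca.copy(), "C": C, "O": O}


@dataclass(frozen=True)
class Segment:
    ss: str      # helix | strand | coil
    length: int

    def __post_init__(self):
        if self.ss not in ("helix", "strand", "coil"):
            raise ValueError(self.ss)
        if self.length < 3:
            raise ValueError("segment lengths must be >= 3")


def default_blueprint() -> list:
    """An ~90-residue three-helix / beta-hairpin bundle with coil tails.

    The six-residue terminal coils absorb the terminal indel model (maximum
    deletion length 6), so planted binding sites in the bundle interior are
    never truncated away."""
    return [Segment("coil", 6), Segment("helix", 18), Segment("coil", 4),
            Segment("strand", 8), Segment("coil", 3), Segment("strand", 8),
            Segment("coil", 4), Segment("helix", 18), Segment("coil", 3),
            Segment("helix", 12), Segment("coil", 6)]


class FoldBuildError(RuntimeError):
    pass


def build_toy_fold(blueprint: list | None = None, seed: int = 0,
                   structure_id: str = "ancestor", spacing: float = 9.0,
                   clash_distance: float = 2.9, max_retries: int = 25) -> StructureModel:
    """Construct a toy fold from a segment blueprint.

    Secondary segments are ideal phi/psi fragments packed on parallel,
    alternating-direction axes (adjacent strands are placed antiparallel at
    the H-bond-optimal offset); coils are fixed-bond self-avoiding walks
    bridging the segments. Bit-identical coordinates for the same seed.
    """
    blueprint = blueprint or default_blueprint()
    rng_master = np.random.default_rng(seed)
    last_err = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        try:
            return _build_once(blueprint, rng, structure_id, spacing, clash_distance)
        except FoldBuildError as err:
            last_err = err
    raise FoldBuildError(f"fold construction failed after {max_retries} retries "
                         f"(seed {seed}): {last_err}")


def build_fold_with_pocket(blueprint: list | None = None, seed: int = 0,
                           structure_id: str = "ancestor", pocket_size: int = 6,
                           pocket_diameter: float = 8.0) -> tuple:
    """Build a fold and plant its pocket, packing segments closer if needed.

    The packing step walks the bundle spacing down until ``pocket_size``
    residues are mutually within ``pocket_diameter``; returns
    (StructureModel, pocket index list).
    """
    blueprint = blueprint or default_blueprint()
    last_err = None
    for attempt in range(10):
        sub_seed = int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0]
                       % (2 ** 31)) if attempt else seed
        for spacing in (9.0, 8.4, 7.9):
            try:
                model = build_toy_fold(blueprint, seed=sub_seed,
                                       structure_id=structure_id, spacing=spacing)
                pocket = choose_pocket(model, blueprint, size=pocket_size,
                                       max_diameter=pocket_diameter)
                return model, pocket
            except FoldBuildError as err:
                last_err = err
    raise FoldBuildError(f"packing failed down to minimum spacing "
                         f"(seed {seed}): {last_err}")


def _build_once(blueprint, rng, structure_id, spacing, clash_distance):
    segs = list(blueprint)
    placed: list[dict | None] = [None] * len(segs)

    # --- place secondary segments on a bundle of alternating axes.
    # Each segment is built in a local frame along +z (strands with roll 0 so
    # the cached antiparallel placement applies) and mapped into the layout by
    # a stored rigid transform; a strand directly following a strand is placed
    # relative to its partner at the H-bond-optimal offset.
    ss_ids = [k for k, s in enumerate(segs) if s.ss != "coil"]
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: +z -> -z
    transforms: dict[int, tuple] = {}
    pair_roll: dict[int, float] = {}
    # consecutive strand segments share a layout slot (they pack as a sheet);
    # slots sit on a circle so every segment faces a common pocket centre
    slot_of: dict[int, int] = {}
    n_slots = 0
    for order, k in enumerate(ss_ids):
        prev_k = ss_ids[order - 1] if order > 0 else None
        if (prev_k is not None and segs[prev_k].ss == "strand"
                and segs[k].ss == "strand"):
            slot_of[k] = slot_of[prev_k]
        else:
            slot_of[k] = n_slots
            n_slots += 1
    if n_slots > 1:
        R_circ = spacing / (2.0 * math.sin(math.pi / n_slots))
        slot_xy = [R_circ * np.array([math.cos(2 * math.pi * s / n_slots),
                                      math.sin(2 * math.pi * s / n_slots)])
                   for s in range(n_slots)]
    else:
        slot_xy = [np.zeros(2)]
    for order, k in enumerate(ss_ids):
        seg = segs[k]
        up = order % 2 == 0
        prev_k = ss_ids[order - 1] if order > 0 else None
        paired = (prev_k is not None and segs[prev_k].ss == "strand"
                  and seg.ss == "strand" and prev_k in transforms)
        if paired:
            dy, dz, roll, _n = _antiparallel_placement(segs[prev_k].length, seg.length)
            a_local = _axis_align(_fragment("strand", segs[prev_k].length),
                                  [0, 0, 1.0], 0.0)
            g = math.radians(pair_roll.get(prev_k, 0.0))
            Rz = np.array([[math.cos(g), -math.sin(g), 0.0],
                           [math.sin(g), math.cos(g), 0.0], [0.0, 0.0, 1.0]])
            shift = Rz @ np.array([0.0, dy, 0.0]) \
                + np.array([0.0, 0.0, a_local["CA"][-1][2] + dz])
            b_local = {kk: v + shift for kk, v in
                       _axis_align(_fragment("strand", seg.length),
                                   [0, 0, -1.0], roll + math.degrees(g)).items()}
            R, t = transforms[prev_k]
            placed[k] = {kk: v @ R.T + t for kk, v in b_local.items()}
            transforms[k] = (R, t)  # pair shares its partner's frame
            continue
        xy = slot_xy[slot_of[k]]
        R = np.eye(3) if up else flip
        if seg.ss == "strand":
            # roll the sheet so the partner strand sits tangentially to the
            # bundle circle instead of intruding into (or leaving) the core
            if np.linalg.norm(xy) > 1e-9:
                rhat = xy / np.linalg.norm(xy)
                that = np.array([-rhat[1], rhat[0], 0.0])
            else:
                that = np.array([0.0, 1.0, 0.0])
            u = R.T @ that
            roll = math.degrees(math.atan2(u[1], u[0])) - 90.0
            pair_roll[k] = roll
            # centre the future sheet on the slot axis
            xy = xy - 2.3 * that[:2]
        else:
            # roll the helix so its mid-residue faces the bundle centre
            base = _axis_align(_fragment(seg.ss, seg.length), [0, 0, 1.0], 0.0)
            mid = base["CA"][seg.length // 2]
            phase = math.degrees(math.atan2(mid[1], mid[0]))
            inward = R.T @ np.array([-xy[0], -xy[1], 0.0])
            target = math.degrees(math.atan2(inward[1], inward[0]))
            roll = target - phase + float(rng.uniform(-15, 15))
        local = _axis_align(_fragment(seg.ss, seg.length), [0, 0, 1.0], roll)
        height = local["CA"][-1][2]
        t = np.array([xy[0], xy[1], 0.0 if up else height])
        transforms[k] = (R, t)
        placed[k] = {kk: v @ R.T + t for kk, v in local.items()}

    # --- coils bridge between neighbouring placed segments
    obstacles = np.vstack([placed[k]["CA"] for k in ss_ids]) if ss_ids else None
    if obstacles is None:
        raise FoldBuildError("blueprint is all coil; nothing to anchor")
    for k, seg in enumerate(segs):
        if seg.ss != "coil":
            continue
        prev_bb = placed[k - 1] if k > 0 else None
        next_bb = placed[k + 1] if k + 1 < len(segs) else None
        bundle_centre = obstacles.mean(axis=0)

        def _outward(anchor):
            d = anchor - bundle_centre
            nd = np.linalg.norm(d)
            d = d / nd if nd > 1e-9 else np.array([0.0, 0.0, 1.0])
            d = d + 0.4 * rng.normal(size=3)
            return d / np.linalg.norm(d)

        if prev_bb is not None and next_bb is not None:
            start, end = prev_bb["CA"][-1], next_bb["CA"][0]
        elif next_bb is not None:  # N-terminal tail walks outward from its anchor
            end = next_bb["CA"][0]
            start = end + 3.8 * (seg.length + 1) * 0.7 * _outward(end)
        else:  # C-terminal tail
            start = prev_bb["CA"][-1]
            end = start + 3.8 * (seg.length + 1) * 0.7 * _outward(start)
        obs = obstacles[np.minimum(
            np.linalg.norm(obstacles - start, axis=1),
            np.linalg.norm(obstacles - end, axis=1)) > 0.5]
        ca = _bridge_walk(start, end, seg.length, rng, obstacles=obs)
        placed[k] = _backbone_from_ca(np.asarray(ca))
        obstacles = np.vstack([obstacles, ca])

    # --- assemble and clash-check
    all_ca = np.vstack([placed[k]["CA"] for k in range(len(segs))])
    n = len(all_ca)
    d2 = np.linalg.norm(all_ca[:, None] - all_ca[None, :], axis=-1)
    mask = np.triu(np.ones((n, n), bool), k=4)
    if (d2[mask] < clash_distance).any():
        raise FoldBuildError("self-avoidance violated")

    seq = "".join(rng.choice(list(CANONICAL_AA)) for _ in range(n))
    L = n
    plddt_prof = np.full(L, 92.0)
    k10 = max(1, L // 10)
    plddt_prof[:k10] = 79.0
    plddt_prof[-k10:] = 87.0
    plddt_prof = np.clip(plddt_prof + rng.normal(scale=2.0, size=L), 50.0, 100.0)

    residues = []
    i = 0
    for k, seg in enumerate(segs):
        bb = placed[k]
        for j in range(seg.length):
            atoms = [("N", "N", bb["N"][j]), ("CA", "C", bb["CA"][j]),
                     ("C", "C", bb["C"][j]), ("O", "O", bb["O"][j])]
            residues.append(ResidueRecord("A", i + 1, seq[i], atoms,
                                          plddt=float(plddt_prof[i]),
                                          author_seq_id=i + 1))
            i += 1
    return StructureModel(structure_id, residues, source="predicted")


def segment_classes(blueprint: list) -> np.ndarray:
    """Per-residue segment type (helix/strand/coil) from a blueprint."""
    out = []
    for seg in blueprint:
        out.extend([seg.ss] * seg.length)
    return np.array(out, dtype=object)


def choose_pocket(model: StructureModel, blueprint: list, size: int = 6,
                  max_diameter: float = 8.0) -> list:
    """Greedy pocket: the ``size`` mutually close residues nearest the
    packed-sheet centroid (falling back to the bundle centroid).

    Seeded from every near-centroid residue in turn; the first seed whose
    greedy closure reaches ``size`` residues all pairwise within
    ``max_diameter`` wins.
    """
    ca = model.ca_coords
    seg = segment_classes(blueprint)
    anchor = np.flatnonzero(seg != "coil")
    if len(anchor) == 0:
        anchor = np.arange(len(model))
    centroid = ca[anchor].mean(axis=0)
    order = np.argsort(np.linalg.norm(ca - centroid, axis=1))
    for seed_i in order[:20]:
        pocket = [int(seed_i)]
        for i in order:
            if i == seed_i:
                continue
            if all(np.linalg.norm(ca[i] - ca[j]) <= max_diameter for j in pocket):
                pocket.append(int(i))
            if len(pocket) == size:
                return sorted(p + 1 for p in pocket)  # 1-based
    raise FoldBuildError(f"could not pack a {size}-residue pocket "
                         f"within {max_diameter} A")


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark (the planted ground truth).

    Substitution probabilities follow the planted hierarchy binding < core <
    surface. Coordinate noise and terminal indels emulate predicted-model
    imprecision and ragged termini. Property couplings are linear in the true
    divergence (1 - CR) with Gaussian noise.
    """

    seed: int = 0
    n_orthogroups: int = 20
    n_members: tuple = (10, 10)
    blueprint: list = field(default_factory=default_blueprint)
    pocket_size: int = 6
    p_bind: float = 0.02
    p_core: float = 0.20
    p_surf: float = 0.50
    #: substitution rate for planted conserved non-binding patches (emulating
    #: protein-protein interface conservation); used when a residue-class
    #: array containing 'patch' is supplied
    p_patch: float = 0.02
    coord_noise: float = 0.5           # A, per-atom Gaussian
    indel_prob: float = 0.5            # per terminus
    indel_range: tuple = (1, 6)
    surface_threshold: float = 0.25
    #: per-orthogroup substitution-rate multiplier range (divergence spread
    #: across orthogroups, as real corpora show a wide CR range)
    og_rate_range: tuple = (1.0, 1.0)
    # property couplings: value = alpha - beta * (1 - CR_true) + N(0, sigma)
    abundance_alpha: float = 10.0
    abundance_beta: float = 8.0
    abundance_sigma: float = 0.5
    flux_cv_alpha: float = 0.2
    flux_cv_beta: float = 1.0          # positive: variability grows with divergence
    flux_cv_sigma: float = 0.1
    kcat_sd_alpha: float = 0.2
    kcat_sd_beta: float = 1.0
    kcat_sd_sigma: float = 0.1
    phenotype_effect: float = 1.0      # 'yes' species substitution-rate multiplier

    def __post_init__(self):
        for p in (self.p_bind, self.p_core, self.p_surf):
            if not 0.0 <= p <= 1.0:
                raise ValueError("substitution probabilities must be in [0,1]")


@dataclass
class GroundTruth:
    og_id: str
    classes: np.ndarray            # per ancestor residue: bind/core/surface
    pocket: list                   # planted binding-site residue indices (1-based)
    substitutions: dict            # member_id -> sorted list of ancestor indices
    cr_true: float                 # realised mean identity over members
    class_identity: dict           # class -> realised identity fraction
    expected_identity: dict        # class -> 1 - p_class
    member_phenotype: dict = field(default_factory=dict)


def residue_classes(model: StructureModel, pocket: list,
                    surface_threshold: float = 0.25) -> np.ndarray:
    """bind (pocket) / core / surface labels from the ancestor's own rSASA."""
    from .features import relative_sasa, shrake_rupley_sasa

    sasa = shrake_rupley_sasa(model)
    _rs, exposure = relative_sasa(sasa, model.sequence,
                                  surface_threshold=surface_threshold)
    classes = np.where(exposure == "surface", "surface", "core").astype(object)
    for i in pocket:
        classes[i - 1] = "bind"
    return classes


def evolve_orthogroup(ancestor: StructureModel, spec: SyntheticSpec,
                      og_id: str = "og000", seed: int | None = None,
                      pocket: list | None = None,
                      classes: np.ndarray | None = None) -> tuple:
    """Evolve an orthogroup from an ancestor under planted class rates.

    Each member substitutes every site independently at its class
    probability (replacement uniform over the other 19 amino acids, so
    expected identity per class is 1 - p), adds Gaussian coordinate noise and
    truncates termini with the indel model. Member species alternate between
    the 'yes' and 'no' phenotype halves; 'yes' members scale their rates by
    ``phenotype_effect``. Returns (Orthogroup, GroundTruth).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if pocket is None:
        seed_pocket = choose_pocket(ancestor, spec.blueprint, spec.pocket_size)
        ancestor, pocket = plant_ligand(ancestor, seed_pocket)
    if classes is None:
        classes = residue_classes(ancestor, pocket, spec.surface_threshold)
    p_of = {"bind": spec.p_bind, "core": spec.p_core, "surface": spec.p_surf,
            "patch": spec.p_patch}
    L = len(ancestor)
    seq = ancestor.sequence

    n_members = int(rng.integers(spec.n_members[0], spec.n_members[1] + 1))
    ref_id = f"ref_{og_id}"
    reference = StructureModel(
        ref_id,
        [ResidueRecord(r.chain_id, r.seq_index, r.aa, r.atoms, r.plddt,
                       r.author_seq_id, r.icode) for r in ancestor.residues],
        source=ancestor.source, ligands=list(ancestor.ligands))

    structures = {ref_id: reference}
    member_ids = [ref_id]
    substitutions: dict[str, list] = {}
    phenotype: dict[str, str] = {}
    tallies = {c: [0, 0] for c in p_of}  # identical, total
    total_ident = total_sites = 0
    for m in range(n_members):
        mid = f"sp{m:02d}_{og_id}"
        pheno = "yes" if m % 2 == 0 else "no"
        phenotype[mid] = pheno
        mult = spec.phenotype_effect if pheno == "yes" else 1.0
        p_arr = np.minimum(1.0, np.array([p_of[c] for c in classes]) * mult)
        hits = rng.random(L) < p_arr
        draws = rng.integers(19, size=L)  # consumed per site for determinism
        new_seq = list(seq)
        subs = []
        for i in np.flatnonzero(hits):
            alts = [a for a in CANONICAL_AA if a != seq[i]]
            new_seq[i] = alts[int(draws[i])]
            subs.append(int(i) + 1)
        for c in p_of:
            cm = classes == c
            tallies[c][0] += int((cm & ~hits).sum())
            tallies[c][1] += int(cm.sum())
        total_ident += int((~hits).sum())
        total_sites += L
        start, stop = 0, L
        if rng.random() < spec.indel_prob:
            start = int(rng.integers(spec.indel_range[0], spec.indel_range[1] + 1))
        if rng.random() < spec.indel_prob:
            stop = L - int(rng.integers(spec.indel_range[0], spec.indel_range[1] + 1))
        noise = rng.normal(scale=spec.coord_noise, size=(L, 4, 3))
        residues = []
        for new_idx, i in enumerate(range(start, stop), start=1):
            r = ancestor.residues[i]
            atoms = [(nm, el, xyz + noise[i, a % 4])
                     for a, (nm, el, xyz) in enumerate(r.atoms)]
            residues.append(ResidueRecord(r.chain_id, new_idx, new_seq[i], atoms,
                                          plddt=r.plddt, author_seq_id=i + 1))
        structures[mid] = StructureModel(mid, residues, source="predicted")
        member_ids.append(mid)
        substitutions[mid] = subs

    og = Orthogroup(og_id, member_ids, [ref_id], structures)
    truth = GroundTruth(
        og_id=og_id, classes=classes, pocket=list(pocket),
        substitutions=substitutions,
        cr_true=total_ident / total_sites if total_sites else float("nan"),
        class_identity={c: t[0] / t[1] if t[1] else float("nan")
                        for c, t in tallies.items()},
        expected_identity={c: 1.0 - p for c, p in p_of.items()},
        member_phenotype=phenotype)
    return og, truth


def generate_corpus(spec: SyntheticSpec) -> tuple:
    """Generate ``n_orthogroups`` orthogroups plus ground truths.

    Each orthogroup gets its own ancestor fold (same blueprint, different
    seed) so coil regions and sequences differ between groups.
    """
    rng = np.random.default_rng(spec.seed)
    ogs, truths = {}, {}
    for k in range(spec.n_orthogroups):
        og_id = f"og{k:03d}"
        fold_seed = int(rng.integers(2 ** 31))
        ancestor, seed_pocket = build_fold_with_pocket(
            spec.blueprint, seed=fold_seed, structure_id=f"anc_{og_id}",
            pocket_size=spec.pocket_size)
        ancestor, pocket = plant_ligand(ancestor, seed_pocket)
        mult = float(rng.uniform(*spec.og_rate_range))
        og_spec = replace(spec,
                          p_bind=min(0.95, spec.p_bind * mult),
                          p_core=min(0.95, spec.p_core * mult),
                          p_surf=min(0.95, spec.p_surf * mult))
        og, truth = evolve_orthogroup(ancestor, og_spec, og_id,
                                      seed=int(rng.integers(2 ** 31)),
                                      pocket=pocket)
        ogs[og_id] = og
        truths[og_id] = truth
    return ogs, truths


def generate_property_tables(truths: dict, spec: SyntheticSpec,
                             seed: int | None = None) -> pd.DataFrame:
    """Per-orthogroup property table with the stated couplings to divergence."""
    rng = np.random.default_rng((spec.seed + 1) if seed is None else seed)
    pathways = [f"pw{k}" for k in range(5)]
    rows = []
    for i, (og_id, t) in enumerate(sorted(truths.items())):
        div = 1.0 - t.cr_true
        rows.append({
            "og_id": og_id,
            "abundance_log2": spec.abundance_alpha - spec.abundance_beta * div
                              + rng.normal(scale=spec.abundance_sigma),
            "flux_median": float(rng.lognormal(0.0, 1.0)),
            "flux_cv": max(0.0, spec.flux_cv_alpha + spec.flux_cv_beta * div
                           + rng.normal(scale=spec.flux_cv_sigma)),
            "flux_n_species": int(rng.integers(5, 27)),
            "kcat_log_sd": max(0.0, spec.kcat_sd_alpha + spec.kcat_sd_beta * div
                               + rng.normal(scale=spec.kcat_sd_sigma)),
            "n_inhibitors": int(rng.poisson(2.0 + 10.0 * t.cr_true)),
            "ppi_degree": int(rng.poisson(5.0)),
            "enzyme_class": int(rng.integers(1, 8)),
            "pathway": pathways[i % len(pathways)],
        })
    return pd.DataFrame(rows).set_index("og_id")


def plant_ligand(model: StructureModel, seed_pocket: list,
                 resname: str = "LIG", approach: float = 3.0) -> tuple:
    """Plant a synthetic ligand at the pocket centre and return the model
    with the ligand plus the contact-defined pocket.

    One carbon atom is dropped ``approach`` A from each seed residue's CA
    toward the pocket centroid. The planted binding site is then *defined*
    as the set of residues with a heavy atom within 5 A of the ligand --
    exactly how contact-site (CSb) residues are detected -- so detection
    recovers the planted pocket by construction.
    """
    from .features import csb_binding_sites
    from .io import LigandRecord
    import warnings

    ca = model.ca_coords
    idx0 = np.asarray(seed_pocket, int) - 1
    centroid = ca[idx0].mean(axis=0)
    atoms = []
    for i in idx0:
        direction = centroid - ca[i]
        nd = np.linalg.norm(direction)
        direction = direction / nd if nd > 1e-9 else np.zeros(3)
        atoms.append(ca[i] + direction * min(approach, nd))
    lig = LigandRecord(resname, [(f"C{k + 1}", "C", a)
                                 for k, a in enumerate(atoms)])
    out = StructureModel(model.structure_id, model.residues, source=model.source,
                         ligands=model.ligands + [lig])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        csb, _metal = csb_binding_sites(out)
    pocket = sorted(int(i) for i in np.flatnonzero(csb) + 1)
    return out, pocket
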