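"""Mapping-ratio and conservation-ratio metrics over orthogroups.

For each member aligned to the reference, M counts its 1:1-mapped residues,
N the unmapped ones (so M + N is the member length), and C the mapped
residues identical to the reference residue. The mapping ratio MR = M/(M+N)
and conservation ratio CR = C/M are computed per member and averaged
unweighted over non-reference members. Per-reference-residue tallies support
the fully-conserved-residue network downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyProfileError, UndefinedStatisticError
from .io import Orthogroup
from .tables import aa_class_table, logp_table


@dataclass
class MemberConservation:
    """Per-member mapping/conservation bookkeeping against one reference."""

    member_id: str
    M: int
    N: int
    C: int
    #: mapped pairs as (ref_idx, mem_idx, ref_aa, mem_aa)
    pairs: list = field(default_factory=list, repr=False)

    @property
    def mr(self) -> float:
        return self.M / (self.M + self.N)

    @property
    def cr(self) -> float:
        return self.C / self.M if self.M else float("nan")


@dataclass
class ConservationProfile:
    og_id: str
    reference_id: str
    ref_sequence: str
    members: dict               # member_id -> MemberConservation
    n_mapped: np.ndarray        # per reference residue
    n_identical: np.ndarray
    quorum: float = 1.0

    @property
    def n_members_aligned(self) -> int:
        return len(self.members)

    @property
    def fully_conserved(self) -> np.ndarray:
        """Reference positions mapped in (>= quorum of) all aligned members and
        identical in all of them."""
        n = self.n_members_aligned
        need = n * self.quorum
        return (self.n_mapped >= need) & (self.n_identical >= need) \
            & (self.n_identical == self.n_mapped)

    @property
    def og_mr(self) -> float:
        return float(np.mean([m.mr for m in self.members.values()]))

    @property
    def og_cr(self) -> float:
        return float(np.mean([m.cr for m in self.members.values()]))


def conservation_profile(og: Orthogroup, alignments: dict, reference_id: str | None = None,
                         quorum: float = 1.0, dedupe_species: bool = False,
                         species_of: dict | None = None) -> ConservationProfile:
    """Build the conservation profile of an orthogroup against one reference.

    Parameters
    ----------
    alignments : dict
        ``member_id -> AlignmentResult`` (or ResidueMapping) against the
        reference; failed members are simply absent. The reference itself is
        excluded from averaging.
    dedupe_species : bool
        Collapse paralogues to the best-mapping member per species before
        averaging (species taken from ``species_of`` or the structure-id
        prefix before the first underscore).
    """
    reference_id = reference_id or og.reference_ids[0]
    ref = og.structure(reference_id)
    ref_seq = ref.sequence
    L = len(ref_seq)

    items = {mid: a for mid, a in alignments.items() if mid != reference_id}
    if not items:
        raise EmptyProfileError(f"{og.og_id}: no aligned members besides the reference")

    def _mapping(a):
        return a.mapping if hasattr(a, "mapping") else a

    if dedupe_species:
        best: dict[str, tuple[float, str]] = {}
        for mid, a in items.items():
            sp = (species_of or {}).get(mid, mid.split("_", 1)[0])
            mr = len(_mapping(a)) / len(og.structure(mid))
            if sp not in best or mr > best[sp][0]:
                best[sp] = (mr, mid)
        items = {mid: items[mid] for _mr, mid in best.values()}

    n_mapped = np.zeros(L, dtype=int)
    n_identical = np.zeros(L, dtype=int)
    members: dict[str, MemberConservation] = {}
    for mid, a in sorted(items.items()):
        mapping = _mapping(a)
        mem_seq = og.structure(mid).sequence
        pairs = []
        C = 0
        for r_idx, m_idx in mapping.pairs:
            ra, ma = ref_seq[r_idx - 1], mem_seq[m_idx - 1]
            ident = ra == ma and ra != "X"  # 'X' never counts as identical
            n_mapped[r_idx - 1] += 1
            if ident:
                n_identical[r_idx - 1] += 1
                C += 1
            pairs.append((r_idx, m_idx, ra, ma))
        M = len(mapping)
        members[mid] = MemberConservation(mid, M=M, N=len(mem_seq) - M, C=C, pairs=pairs)

    return ConservationProfile(og.og_id, reference_id, ref_seq, members,
                               n_mapped, n_identical, quorum=quorum)


def cr_by_class(profile: ConservationProfile, class_map: dict | None = None) -> float:
    """CR counting a mapped pair as conserved when both residues share a
    physicochemical class. Always >= the identity-based CR ('X' excluded from
    the denominator)."""
    cmap = class_map or aa_class_table()
    vals = []
    for m in profile.members.values():
        denom = hits = 0
        for _r, _m, ra, ma in m.pairs:
            if ra == "X" or ma == "X":
                continue
            denom += 1
            if cmap[ra] == cmap[ma]:
                hits += 1
        if denom:
            vals.append(hits / denom)
    if not vals:
        raise UndefinedStatisticError("no classifiable mapped pairs")
    return float(np.mean(vals))


def mean_hydrophobicity_change(profile: ConservationProfile,
                               table: dict | None = None,
                               substituted_only: bool = False) -> float:
    """Mean |delta logP| over mapped pairs, averaged over members.

    Uses the side-chain octanol-water partition scale. Identical pairs
    contribute 0, so the statistic grows with divergence (and is 0 for an
    identical member). ``substituted_only`` restricts the average to
    substituted pairs (the per-substitution chemical step size instead of a
    divergence measure).
    """
    logp = table or logp_table()
    vals = []
    for m in profile.members.values():
        if not m.pairs:
            continue
        deltas = [abs(logp[ra] - logp[ma]) for _r, _mi, ra, ma in m.pairs
                  if ra in logp and ma in logp
                  and (ra != ma or not substituted_only)]
        if substituted_only:
            vals.append(float(np.mean(deltas)) if deltas else 0.0)
        elif deltas:
            vals.append(float(np.mean(deltas)))
    if not vals:
        raise UndefinedStatisticError("no mapped pairs")
    return float(np.mean(vals))


def cr_by_feature(profile: ConservationProfile, selector) -> float | None:
    """CR restricted to reference residues passing ``selector``.

    ``selector`` is a boolean array over reference positions (0-based) or a
    callable ``ref_idx (1-based) -> bool``. Per member, identical/mapped
    counts are taken within the subset; the unweighted mean over members with
    at least one mapped residue in the subset is returned, or None if the
    subset is empty/unmapped everywhere (reported as missing).
    """
    if callable(selector):
        sel = np.array([bool(selector(i + 1)) for i in range(len(profile.ref_sequence))])
    else:
        sel = np.asarray(selector, dtype=bool)
    vals = []
    for m in profile.members.values():
        denom = hits = 0
        for r_idx, _mi, ra, ma in m.pairs:
            if sel[r_idx - 1]:
                denom += 1
                if ra == ma and ra != "X":
                    hits += 1
        if denom:
            vals.append(hits / denom)
    return float(np.mean(vals)) if vals else None


def profile_tables(profile: ConservationProfile):
    """Per-orthogroup summary row and per-residue table as DataFrames."""
    import pandas as pd

    summary = pd.DataFrame([{
        "og_id": profile.og_id, "reference_id": profile.reference_id,
        "og_mr": profile.og_mr, "og_cr": profile.og_cr,
        "n_members": profile.n_members_aligned,
    }])
    fc = profile.fully_conserved
    residues = pd.DataFrame({
        "og_id": profile.og_id,
        "ref_idx": np.arange(1, len(profile.ref_sequence) + 1),
        "aa": list(profile.ref_sequence),
        "n_mapped": profile.n_mapped,
        "n_identical": profile.n_identical,
        "fully_conserved": fc,
    })
    return summary, residues
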