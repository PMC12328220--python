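"""Amino-acid cost and composition profiling of proteins and structural elements.

Costs come from packaged per-residue metrics (ATP-equivalent biosynthetic
cost, opportunity cost, molecular weight), median-normalised so metrics are
comparable. Element-level reports join composition and cost with element CRs
for the downstream association tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .conservation import ConservationProfile, cr_by_feature
from .exceptions import UndefinedStatisticError
from .tables import CANONICAL_AA, CostTable, cost_tables

ELEMENTS = ("all_mapped", "core", "surface", "binding_upb", "binding_csb",
            "helix", "extended", "coil", "turn")


def average_cost(residues: str, table: CostTable) -> float:
    """Mean per-residue cost of an amino-acid string ('X' skipped)."""
    vals = [table.values[a] for a in residues if a in table.values]
    if not vals:
        raise UndefinedStatisticError("empty residue subset")
    return float(np.mean(vals))


def composition(residues: str) -> pd.Series:
    """Relative frequencies over the 20 canonical amino acids ('X' excluded)."""
    counts = pd.Series(0.0, index=list(CANONICAL_AA))
    n = 0
    for a in residues:
        if a in counts.index:
            counts[a] += 1
            n += 1
    if n == 0:
        raise UndefinedStatisticError("subset contains no canonical residues")
    return counts / n


def _element_masks(features: pd.DataFrame, n_mapped: np.ndarray) -> dict[str, np.ndarray]:
    masks = {
        "all_mapped": n_mapped > 0,
        "core": (features["exposure"] == "core").to_numpy(),
        "surface": (features["exposure"] == "surface").to_numpy(),
        "binding_upb": features["upb"].to_numpy(dtype=bool),
        "binding_csb": features["csb"].to_numpy(dtype=bool),
    }
    for ss in ("helix", "extended", "coil", "turn"):
        masks[ss] = (features["ss_class"] == ss).to_numpy()
    return masks


def orthogroup_element_costs(profile: ConservationProfile, features: pd.DataFrame,
                             tables: tuple[CostTable, ...] | None = None) -> pd.DataFrame:
    """Per-element cost, composition and CR for one orthogroup.

    Cost is the mean per-residue cost of each member's residues mapped to the
    element's reference positions, averaged unweighted over members (the same
    averaging convention as the CR). Missing elements stay missing rather
    than being imputed as zero.
    """
    tables = tables or cost_tables()
    masks = _element_masks(features, profile.n_mapped)
    rows = []
    for element, mask in masks.items():
        sel = set(np.flatnonzero(mask) + 1)
        member_res = []
        for m in profile.members.values():
            aa = "".join(ma for r_idx, _mi, _ra, ma in m.pairs if r_idx in sel)
            if aa:
                member_res.append(aa)
        row = {"og_id": profile.og_id, "element": element,
               "n_residues": int(mask.sum()),
               "cr": cr_by_feature(profile, mask) if mask.any() else None}
        for t in tables:
            if member_res:
                row[f"cost_{t.metric_name}"] = float(np.mean(
                    [average_cost(aa, t) for aa in member_res]))
            else:
                row[f"cost_{t.metric_name}"] = np.nan
        if member_res:
            comp = sum((composition(aa) for aa in member_res),
                       pd.Series(0.0, index=list(CANONICAL_AA))) / len(member_res)
            for a in CANONICAL_AA:
                row[f"freq_{a}"] = float(comp[a])
        else:
            for a in CANONICAL_AA:
                row[f"freq_{a}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def element_cost_report(profiles: dict, features_by_og: dict,
                        tables: tuple[CostTable, ...] | None = None) -> pd.DataFrame:
    """Concatenated per-orthogroup, per-element cost/composition/CR report."""
    tables = tables or cost_tables()
    frames = [orthogroup_element_costs(profiles[og], features_by_og[og], tables)
              for og in sorted(profiles)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
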