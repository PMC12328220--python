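"""Packaged lookup tables (SASA maxima, hydrophobicity, costs, classes, radii).

All tables ship as TSV under ``structcons/data`` and can be overridden by
user-supplied files in the same format.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: parent amino acid for common non-standard residue names; anything not
#: resolvable here or via the chemical-component dictionary becomes 'X'.
NONSTANDARD_PARENT = {
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S", "TPO": "T",
    "PTR": "Y", "CSO": "C", "CSD": "C", "OCS": "C", "CME": "C", "MLY": "K",
    "M3L": "K", "KCX": "K", "FME": "M", "LLP": "K", "PCA": "E", "SAR": "G",
}


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("structcons.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@functools.lru_cache(maxsize=None)
def max_sasa_table(path: str | None = None) -> dict[str, float]:
    """Per-amino-acid maximum SASA (theoretical, Gly-X-Gly context), in A^2."""
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("max_sasa_tien.tsv")
    return dict(zip(df["aa"], df["max_sasa"].astype(float)))


@functools.lru_cache(maxsize=None)
def logp_table(path: str | None = None) -> dict[str, float]:
    """Side-chain octanol-water partition coefficients (Fauchere-Pliska pi scale)."""
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("logp_fauchere.tsv")
    return dict(zip(df["aa"], df["logp"].astype(float)))


@functools.lru_cache(maxsize=None)
def aa_class_table(path: str | None = None) -> dict[str, str]:
    """Default physicochemical class per amino acid."""
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("aa_classes.tsv")
    return dict(zip(df["aa"], df["aa_class"]))


@functools.lru_cache(maxsize=None)
def vdw_radii(path: str | None = None) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("vdw_radii.tsv")
    return {str(e).upper(): float(r) for e, r in zip(df["element"], df["radius"])}


@functools.lru_cache(maxsize=None)
def ligand_exclusions(path: str | None = None) -> frozenset[str]:
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("ligand_exclusions.tsv")
    return frozenset(df["resname"].astype(str))


@functools.lru_cache(maxsize=None)
def metal_resnames(path: str | None = None) -> frozenset[str]:
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("metal_resnames.tsv")
    return frozenset(df["resname"].astype(str))


@dataclass(frozen=True)
class CostTable:
    """A per-residue cost metric.

    Parameters
    ----------
    metric_name : str
        Short identifier of the metric (``atp``, ``opportunity``, ``mw`` ...).
    values : dict
        Cost per canonical amino acid. Finite and positive.
    provenance : str
        Free-text note on where the numbers come from.
    """

    metric_name: str
    values: dict
    provenance: str = ""

    def __post_init__(self):
        missing = [a for a in CANONICAL_AA if a not in self.values]
        if missing:
            raise ValueError(f"cost table {self.metric_name!r} missing amino acids: {missing}")
        for aa, v in self.values.items():
            if not (v > 0 and v < float("inf")):
                raise ValueError(f"cost for {aa} must be finite and positive, got {v}")

    def normalized(self) -> "CostTable":
        """Return the table rescaled so the median cost is 1 (relative cost)."""
        med = float(pd.Series(self.values).median())
        return CostTable(self.metric_name, {a: v / med for a, v in self.values.items()},
                         self.provenance + " (median-normalised)")


@functools.lru_cache(maxsize=None)
def cost_tables(path: str | None = None, normalize: bool = True) -> tuple[CostTable, ...]:
    """Load the packaged cost metrics (ATP-equivalent, opportunity, weight)."""
    df = pd.read_csv(path, sep="\t", comment="#") if path else _read_packaged("cost_tables.tsv")
    df = df.set_index("aa")
    out = []
    for col in df.columns:
        t = CostTable(col, df[col].astype(float).to_dict(), provenance="packaged")
        out.append(t.normalized() if normalize else t)
    return tuple(out)


def cost_table(metric: str = "atp", **kw) -> CostTable:
    for t in cost_tables(**kw):
        if t.metric_name == metric:
            return t
    raise KeyError(metric)
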