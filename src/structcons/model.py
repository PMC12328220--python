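"""Model/Results facade over the conservation pipeline.

``ConservationAnalysis`` is constructed from orthogroups (plus optional
annotation and property tables); ``fit()`` runs alignment, conservation
profiling, reference-residue feature annotation, conserved-cluster detection
and cost/composition profiling, and returns a ``ConservationResults`` object
carrying the per-orthogroup estimates, the residue-level tables and
association-test helpers, with a ``summary()`` in the spirit of statistical
modelling packages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st
from .align import AlignmentFailureError, AlignParams, align_and_map
from .clusters import (ConservedClusterSet, cluster_features,
                       cluster_site_overlap, cluster_summary, conserved_network,
                       find_clusters)
from .conservation import (ConservationProfile, conservation_profile,
                           cr_by_class, cr_by_feature, mean_hydrophobicity_change,
                           profile_tables)
from .cost import element_cost_report
from .exceptions import EmptyProfileError
from .features import annotate_reference
from .io import Orthogroup
from .tables import cost_tables


@dataclass
class FitParams:
    align: AlignParams = field(default_factory=AlignParams)
    quorum: float = 1.0
    dedupe_species: bool = False
    surface_threshold: float = 0.25
    csb_cutoff: float = 5.0
    contact_cutoff: float = 10.0
    min_cluster_size: int = 3
    sasa_points: int = 960


class ConservationAnalysis:
    """Structure-aware conservation analysis of enzyme orthogroups.

    Parameters
    ----------
    orthogroups : list of Orthogroup
        Each with resolvable member structures and designated reference(s).
    annotations : DataFrame, optional
        Curated per-residue binding-site rows (structure_id, position,
        site_type) joined onto references by author numbering.
    properties : DataFrame, optional
        Per-orthogroup property table (abundance, flux statistics, ...)
        indexed by og_id; used by ``ConservationResults.associate``.
    """

    def __init__(self, orthogroups: list, annotations: pd.DataFrame | None = None,
                 properties: pd.DataFrame | None = None,
                 params: FitParams | None = None):
        self.orthogroups = {og.og_id: og for og in orthogroups}
        self.annotations = annotations
        self.properties = properties
        self.params = params or FitParams()

    @classmethod
    def from_directory(cls, structures_dir, manifest, references=None, **kw):
        """Build from a directory of PDB files plus a manifest TSV
        (structure_id, og_id); references default to the first member
        (ids starting with ``ref`` win)."""
        from pathlib import Path

        from .io import read_structure

        man = pd.read_csv(manifest, sep="\t")
        structures = {}
        for sid in man["structure_id"]:
            path = Path(structures_dir) / f"{sid}.pdb"
            structures[sid] = read_structure(path, plddt_from_bfactor=True,
                                             structure_id=sid)
        ogs = []
        for og_id, sub in man.groupby("og_id"):
            mids = sorted(sub["structure_id"])
            if references and og_id in references:
                refs = [references[og_id]]
            else:
                pref = [m for m in mids if m.startswith("ref")]
                refs = [pref[0] if pref else mids[0]]
            ogs.append(Orthogroup(og_id, mids, refs,
                                  {m: structures[m] for m in mids}))
        return cls(ogs, **kw)

    def fit(self) -> "ConservationResults":
        p = self.params
        profiles: dict[str, ConservationProfile] = {}
        features: dict[str, pd.DataFrame] = {}
        clusters: dict[str, ConservedClusterSet] = {}
        alignments: dict[str, dict] = {}
        failures: dict[str, list] = {}
        for og_id, og in sorted(self.orthogroups.items()):
            ref_id = og.reference_ids[0]
            ref = og.structure(ref_id)
            al, failed = {}, []
            for mid in og.member_ids:
                if mid == ref_id:
                    continue
                try:
                    al[mid] = align_and_map(ref, og.structure(mid), p.align)
                except AlignmentFailureError:
                    failed.append(mid)
            if not al:
                failures[og_id] = failed
                continue
            profiles[og_id] = conservation_profile(
                og, al, reference_id=ref_id, quorum=p.quorum,
                dedupe_species=p.dedupe_species)
            alignments[og_id] = al
            failures[og_id] = failed
            features[og_id] = annotate_reference(
                ref, n_points=p.sasa_points,
                surface_threshold=p.surface_threshold,
                csb_cutoff=p.csb_cutoff, upb_table=self.annotations)
            nodes, edges = conserved_network(profiles[og_id], ref,
                                             p.contact_cutoff)
            clusters[og_id] = find_clusters(nodes, edges, og_id,
                                            p.min_cluster_size, p.contact_cutoff)
        if not profiles:
            raise EmptyProfileError("no orthogroup produced a profile")
        return ConservationResults(self, profiles, features, clusters,
                                   alignments, failures)


class ConservationResults:
    """Fitted conservation estimates and downstream statistics."""

    def __init__(self, model, profiles, features, clusters, alignments, failures):
        self.model = model
        self.profiles = profiles
        self.features = features
        self.cluster_sets = clusters
        self.alignments = alignments
        self.failures = failures
        self._og_table = None

    # ------------------------------------------------------------------ tables
    @property
    def orthogroup_table(self) -> pd.DataFrame:
        """Per-orthogroup MR/CR and structural-element CRs."""
        if self._og_table is not None:
            return self._og_table
        rows = []
        for og_id, prof in sorted(self.profiles.items()):
            feat = self.features[og_id]
            og = self.model.orthogroups[og_id]
            ref = og.structure(prof.reference_id)
            row = {
                "og_id": og_id, "reference_id": prof.reference_id,
                "n_members": prof.n_members_aligned,
                "n_failed": len(self.failures.get(og_id, [])),
                "length": len(ref),
                "og_mr": prof.og_mr, "og_cr": prof.og_cr,
                "cr_class_based": cr_by_class(prof),
                "dlogp": mean_hydrophobicity_change(prof),
            }
            for name, mask in (
                    ("core", (feat["exposure"] == "core").to_numpy()),
                    ("surface", (feat["exposure"] == "surface").to_numpy()),
                    ("helix", (feat["ss_class"] == "helix").to_numpy()),
                    ("extended", (feat["ss_class"] == "extended").to_numpy()),
                    ("coil", (feat["ss_class"] == "coil").to_numpy()),
                    ("turn", (feat["ss_class"] == "turn").to_numpy()),
                    ("csb", feat["csb"].to_numpy(bool)),
                    ("upb", feat["upb"].to_numpy(bool))):
                row[f"cr_{name}"] = cr_by_feature(prof, mask) if mask.any() else np.nan
            cs = self.cluster_sets[og_id]
            row["n_clusters"] = len(cs.clusters)
            row["mean_cluster_size"] = float(np.mean(cs.sizes)) if cs.sizes else np.nan
            rows.append(row)
        self._og_table = pd.DataFrame(rows)
        return self._og_table

    @property
    def residue_table(self) -> pd.DataFrame:
        frames = []
        for og_id, prof in sorted(self.profiles.items()):
            _s, res = profile_tables(prof)
            frames.append(res.merge(self.features[og_id], on="ref_idx",
                                    suffixes=("", "_feat")))
        return pd.concat(frames, ignore_index=True)

    def element_costs(self) -> pd.DataFrame:
        return element_cost_report(self.profiles, self.features, cost_tables())

    def cluster_table(self) -> pd.DataFrame:
        frames = []
        for og_id, cs in sorted(self.cluster_sets.items()):
            og = self.model.orthogroups[og_id]
            ref = og.structure(self.profiles[og_id].reference_id)
            df = cluster_features(cs, ref, self.features[og_id])
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def cluster_overlap(self, flag_column: str = "csb") -> pd.DataFrame:
        rows = []
        for og_id, cs in sorted(self.cluster_sets.items()):
            og = self.model.orthogroups[og_id]
            prof = self.profiles[og_id]
            ref = og.structure(prof.reference_id)
            flags = self.features[og_id][flag_column].to_numpy(bool)
            rows.append({"og_id": og_id, "flag": flag_column,
                         **cluster_site_overlap(cs, flags, ref, prof)})
        return pd.DataFrame(rows)

    def cluster_stats(self) -> pd.DataFrame:
        return cluster_summary(self.cluster_sets)

    # ------------------------------------------------------------ associations
    def associate(self, columns=None, method_by_column: dict | None = None,
                  properties: pd.DataFrame | None = None) -> pd.DataFrame:
        """Correlate per-orthogroup CR with property columns (BH-adjusted).

        Spearman by default; integer-count columns (e.g. species counts,
        inhibitor counts) use Kendall's tau.
        """
        props = properties if properties is not None else self.model.properties
        if props is None:
            raise ValueError("no property table supplied")
        tab = self.orthogroup_table.set_index("og_id")
        joined = tab.join(props, how="inner")
        columns = columns or [c for c in props.columns
                              if pd.api.types.is_numeric_dtype(props[c])]
        kendall_default = {"flux_n_species", "n_inhibitors", "ppi_degree"}
        results = []
        for col in columns:
            method = (method_by_column or {}).get(
                col, "kendall" if col in kendall_default else "spearman")
            r = st.correlate(joined["og_cr"], joined[col], method)
            r.meta["variable"] = col
            results.append(r)
        return st.association_report(results)

    def summary(self) -> str:
        tab = self.orthogroup_table
        lines = [
            "Structure-aware conservation analysis",
            "=" * 54,
            f"Orthogroups fitted:        {len(tab)}",
            f"Members aligned (total):   {int(tab['n_members'].sum())}"
            f"   (failures: {int(tab['n_failed'].sum())})",
            f"Median MR:                 {tab['og_mr'].median():.3f}"
            f"   (IQR {tab['og_mr'].quantile(0.25):.3f}-{tab['og_mr'].quantile(0.75):.3f})",
            f"Median CR:                 {tab['og_cr'].median():.3f}"
            f"   (IQR {tab['og_cr'].quantile(0.25):.3f}-{tab['og_cr'].quantile(0.75):.3f})",
            "Element CR medians:",
        ]
        for el in ("core", "surface", "helix", "extended", "turn", "coil",
                   "csb", "upb"):
            col = tab[f"cr_{el}"]
            if col.notna().any():
                lines.append(f"  {el:<10} {col.median():.3f}")
        cstats = self.cluster_stats()
        if len(cstats):
            lines += [
                f"Conserved clusters/OG:     median "
                f"{cstats['n_clusters'].median():.2f}",
                f"Cluster size:              median "
                f"{cstats['median_size'].median():.2f} residues",
            ]
        return "\n".join(lines)

    # ----------------------------------------------------------------- plotting
    def plot_mr_cr(self, ax=None):
        """MR-vs-CR scatter over orthogroups (one point per orthogroup)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(4, 4))
        tab = self.orthogroup_table
        ax.scatter(tab["og_mr"], tab["og_cr"], s=12, alpha=0.7)
        ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
        ax.axhline(tab["og_cr"].median(), ls="--", c="grey", lw=1)
        ax.set_xlabel("mapping ratio  M/(M+N)")
        ax.set_ylabel("conservation ratio  C/M")
        return ax
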