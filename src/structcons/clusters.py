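"""Conserved-residue contact networks, clusters and the cluster classifier.

Fully conserved reference residues become nodes of a contact graph (edges:
Calpha pairs within 10 A); connected components of at least
``min_cluster_size`` residues are the conserved clusters. Overlap statistics
quantify how well clusters capture annotated binding sites, and a
histogram-based gradient-boosting classifier (with two null baselines)
checks whether cluster physicochemistry predicts binding-site content.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .conservation import ConservationProfile
from .exceptions import UndefinedStatisticError
from .io import StructureModel
from .tables import CostTable, cost_table

CONTACT_CUTOFF = 10.0  # A, Calpha-Calpha
MIN_CLUSTER_SIZE = 3


@dataclass
class ConservedClusterSet:
    og_id: str
    nodes: np.ndarray          # retained fully conserved residue indices (1-based)
    edges: list                # (i, j) with i < j, both retained
    clusters: list             # list of sorted node lists
    n_discarded_components: int = 0
    contact_cutoff: float = CONTACT_CUTOFF
    min_cluster_size: int = MIN_CLUSTER_SIZE

    @property
    def sizes(self) -> list:
        return [len(c) for c in self.clusters]

    def membership(self) -> dict:
        return {i: k for k, c in enumerate(self.clusters) for i in c}


def contact_edges(coords: np.ndarray, indices: np.ndarray,
                  cutoff: float = CONTACT_CUTOFF) -> list:
    """All pairs of ``indices`` whose Calpha distance is <= cutoff."""
    if len(indices) < 2:
        return []
    pts = coords[indices - 1]
    pairs = cKDTree(pts).query_pairs(cutoff)
    return sorted((int(min(indices[i], indices[j])), int(max(indices[i], indices[j])))
                  for i, j in pairs)


def conserved_network(profile: ConservationProfile, ref: StructureModel,
                      contact_cutoff: float = CONTACT_CUTOFF):
    """Nodes (fully conserved residues) and contact edges on the reference."""
    nodes = np.flatnonzero(profile.fully_conserved) + 1
    edges = contact_edges(ref.ca_coords, nodes, contact_cutoff)
    return nodes, edges


def find_clusters(nodes: np.ndarray, edges: list, og_id: str = "",
                  min_cluster_size: int = MIN_CLUSTER_SIZE,
                  contact_cutoff: float = CONTACT_CUTOFF) -> ConservedClusterSet:
    """Connected components of the conserved network, small ones discarded."""
    G = nx.Graph()
    G.add_nodes_from(int(i) for i in nodes)
    G.add_edges_from(edges)
    clusters, discarded = [], 0
    for comp in nx.connected_components(G):
        if len(comp) >= min_cluster_size:
            clusters.append(sorted(comp))
        else:
            discarded += 1
    clusters.sort(key=lambda c: c[0])
    kept = sorted(i for c in clusters for i in c)
    kept_set = set(kept)
    edges_kept = [(i, j) for i, j in edges if i in kept_set and j in kept_set]
    return ConservedClusterSet(og_id, np.array(kept, dtype=int), edges_kept, clusters,
                               n_discarded_components=discarded,
                               contact_cutoff=contact_cutoff,
                               min_cluster_size=min_cluster_size)


def _flag_sites(flags: np.ndarray, coords: np.ndarray, cutoff: float) -> list:
    """Sites = connected components of flagged residues on the contact graph."""
    idx = np.flatnonzero(np.asarray(flags, bool)) + 1
    if len(idx) == 0:
        return []
    edges = contact_edges(coords, idx, cutoff)
    G = nx.Graph()
    G.add_nodes_from(int(i) for i in idx)
    G.add_edges_from(edges)
    return [sorted(c) for c in nx.connected_components(G)]


def cluster_site_overlap(cluster_set: ConservedClusterSet, site_flags: np.ndarray,
                         ref: StructureModel, profile: ConservationProfile) -> dict:
    """Coverage and enrichment of annotated sites by conserved clusters.

    A site (spatially connected component of flagged residues) is covered
    when at least one of its residues lies in a cluster. The enrichment
    ratio compares the binding fraction among fully conserved residues with
    the binding fraction among all residues.
    """
    flags = np.asarray(site_flags, bool)
    if not flags.any():
        return {"pct_sites_covered": None, "pct_clusters_without_site": None,
                "enrichment_ratio": None, "n_sites": 0}
    sites = _flag_sites(flags, ref.ca_coords, cluster_set.contact_cutoff)
    in_cluster = set(int(i) for i in cluster_set.nodes)
    covered = sum(1 for s in sites if any(i in in_cluster for i in s))
    clusters_with = sum(1 for c in cluster_set.clusters
                        if any(flags[i - 1] for i in c))
    nc = len(cluster_set.clusters)
    fc = profile.fully_conserved
    frac_all = flags.mean()
    frac_cons = flags[fc].mean() if fc.any() else np.nan
    return {
        "pct_sites_covered": 100.0 * covered / len(sites),
        "pct_clusters_without_site": 100.0 * (nc - clusters_with) / nc if nc else None,
        "enrichment_ratio": float(frac_cons / frac_all) if frac_all else None,
        "n_sites": len(sites),
    }


def cluster_features(cluster_set: ConservedClusterSet, ref: StructureModel,
                     features: pd.DataFrame,
                     cost: CostTable | None = None) -> pd.DataFrame:
    """Physicochemical feature vector per cluster.

    Mean rSASA, secondary-structure composition, mean relative cost,
    amino-acid class content, mean pLDDT, size and contact density.
    """
    cost = cost or cost_table("atp")
    from .tables import aa_class_table
    classes = aa_class_table()
    class_names = sorted(set(classes.values()))
    plddt = ref.plddt
    rows = []
    edge_by_cluster: dict[int, int] = {}
    member = cluster_set.membership()
    for i, j in cluster_set.edges:
        k = member.get(i)
        if k is not None and member.get(j) == k:
            edge_by_cluster[k] = edge_by_cluster.get(k, 0) + 1
    for k, c in enumerate(cluster_set.clusters):
        idx = np.array(c) - 1
        sub = features.iloc[idx]
        aa = [ref.sequence[i] for i in idx]
        n = len(c)
        row = {
            "og_id": cluster_set.og_id, "cluster_id": k, "size": n,
            "mean_rsasa": float(np.nanmean(sub["rsasa"])),
            "mean_cost": float(np.mean([cost.values.get(a, np.nan) for a in aa])),
            "mean_plddt": float(plddt[idx].mean()) if plddt is not None else np.nan,
            "contact_density": 2.0 * edge_by_cluster.get(k, 0) / (n * (n - 1)) if n > 1 else 0.0,
        }
        for ss in ("helix", "extended", "turn", "coil"):
            row[f"frac_{ss}"] = float((sub["ss_class"] == ss).mean())
        for cl in class_names:
            row[f"frac_{cl}"] = float(np.mean([classes.get(a) == cl for a in aa]))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClassifierReport:
    balanced_accuracy: float
    auc: float
    per_repeat: pd.DataFrame
    baseline_random_site: dict = field(default_factory=dict)
    baseline_permuted: dict = field(default_factory=dict)


_NON_FEATURES = {"og_id", "cluster_id"}


def _cv_metrics(X, y, seed, n_repeats, n_folds):
    bas, aucs = [], []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        fold_ba, fold_auc = [], []
        for tr, te in skf.split(X, y):
            clf = HistGradientBoostingClassifier(
                min_samples_leaf=4, random_state=seed + rep)
            clf.fit(X[tr], y[tr])
            prob = clf.predict_proba(X[te])[:, 1]
            fold_ba.append(balanced_accuracy_score(y[te], prob >= 0.5))
            if len(np.unique(y[te])) == 2:
                fold_auc.append(roc_auc_score(y[te], prob))
        bas.append(float(np.mean(fold_ba)))
        aucs.append(float(np.mean(fold_auc)) if fold_auc else np.nan)
    return np.array(bas), np.array(aucs)


def _matched_size_shuffle(sizes: np.ndarray, labels: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Reassign positive labels to random clusters with a matched size
    distribution: labels are permuted within size-quartile strata."""
    out = labels.copy()
    qs = np.quantile(sizes, [0.25, 0.5, 0.75])
    strata = np.digitize(sizes, qs)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = out[rng.permutation(idx)]
    return out


def classify_clusters(features: pd.DataFrame, labels, seed: int = 0,
                      n_repeats: int = 10, n_folds: int = 5) -> ClassifierReport:
    """Ten repeats of stratified fivefold CV of a histogram-based gradient
    boosting classifier, against two null baselines.

    Baseline 1 reassigns site labels to random clusters with a matched size
    distribution; baseline 2 permutes the labels. All three use the same
    folds and seed. Requires >= 20 clusters with both classes present.
    """
    y = np.asarray(labels).astype(int)
    if len(y) < 20:
        raise UndefinedStatisticError("need >=20 clusters")
    if len(np.unique(y)) < 2:
        raise UndefinedStatisticError("labels contain a single class")
    cols = [c for c in features.columns if c not in _NON_FEATURES
            and pd.api.types.is_numeric_dtype(features[c])]
    X = features[cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    ba, auc = _cv_metrics(X, y, seed, n_repeats, n_folds)
    y_rs = _matched_size_shuffle(features["size"].to_numpy(), y, rng)
    if len(np.unique(y_rs)) < 2:
        y_rs = y[rng.permutation(len(y))]
    ba_rs, auc_rs = _cv_metrics(X, y_rs, seed, n_repeats, n_folds)
    y_perm = y[rng.permutation(len(y))]
    ba_p, auc_p = _cv_metrics(X, y_perm, seed, n_repeats, n_folds)

    per_repeat = pd.DataFrame({
        "repeat": np.arange(n_repeats),
        "balanced_accuracy": ba, "auc": auc,
        "ba_random_site": ba_rs, "auc_random_site": auc_rs,
        "ba_permuted": ba_p, "auc_permuted": auc_p,
    })
    return ClassifierReport(
        balanced_accuracy=float(np.nanmean(ba)), auc=float(np.nanmean(auc)),
        per_repeat=per_repeat,
        baseline_random_site={"balanced_accuracy": float(np.nanmean(ba_rs)),
                              "auc": float(np.nanmean(auc_rs))},
        baseline_permuted={"balanced_accuracy": float(np.nanmean(ba_p)),
                           "auc": float(np.nanmean(auc_p))})


def cluster_summary(cluster_sets: dict) -> pd.DataFrame:
    """Per-orthogroup cluster count and size summaries."""
    rows = []
    for og, cs in sorted(cluster_sets.items()):
        sizes = cs.sizes
        rows.append({"og_id": og, "n_clusters": len(sizes),
                     "mean_size": float(np.mean(sizes)) if sizes else np.nan,
                     "median_size": float(np.median(sizes)) if sizes else np.nan,
                     "n_conserved_retained": int(len(cs.nodes)),
                     "n_discarded_components": cs.n_discarded_components})
    return pd.DataFrame(rows)
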