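"""Association statistics: correlations, nonparametric group tests with
Cliff's delta, quartile Fisher enrichment, ROC/AUC enrichment, BH adjustment
and phenotype subgrouping.

Everything returns :class:`AssociationResult` records so reports carry the
estimate, effect size, p-value, adjusted p-value and n together.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedStatisticError

EXACT_N = 8  # full permutation enumeration for rank-correlation p below this


@dataclass
class AssociationResult:
    test_name: str
    estimate: float
    p_value: float
    n: int
    effect_size: float | None = None  # Cliff's delta where applicable
    p_adjusted: float | None = None
    meta: dict = field(default_factory=dict)


def _drop_missing(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok], int((~ok).sum())


def correlate(x, y, method: str = "spearman") -> AssociationResult:
    """Rank or linear correlation with midrank ties and small-n exact p.

    Missing pairs are dropped (count recorded in ``meta``). For n <= 8 the
    p-value of the rank correlations is computed by full permutation
    enumeration; otherwise the usual large-sample approximation is used.
    """
    x, y, n_miss = _drop_missing(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"need >=3 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult(method, float("nan"), float("nan"), n,
                                 meta={"constant_input": True, "n_missing": n_miss})
    if method == "spearman":
        est, p = sps.spearmanr(x, y)
        stat = lambda xv, yv: sps.spearmanr(xv, yv).statistic
    elif method == "kendall":
        est, p = sps.kendalltau(x, y)
        stat = lambda xv, yv: sps.kendalltau(xv, yv).statistic
    elif method == "pearson":
        est, p = sps.pearsonr(x, y)
        stat = None
    else:
        raise ValueError(method)
    if stat is not None and n <= EXACT_N:
        obs = abs(stat(x, y))
        count = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(stat(x, np.array(perm))) >= obs - 1e-12:
                count += 1
        p = count / total
    return AssociationResult(method, float(est), float(p), n,
                             meta={"n_missing": n_miss})


def cliffs_delta(a, b) -> float:
    """Cliff's delta = (#(a>b) - #(a<b)) / (n_a * n_b) over all cross pairs."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float(((a > b).sum() - (a < b).sum()) / (a.size * b.size))


def group_compare(a, b, test: str = "mann_whitney", paired: bool = False) -> AssociationResult:
    """Two-sided Mann-Whitney U or Wilcoxon signed-rank with Cliff's delta.

    The effect size is always the unpaired cross-pair Cliff's delta; the
    signed-rank test additionally requires equal lengths and at least one
    nonzero difference (otherwise flagged undefined).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedStatisticError("empty group")
    delta = cliffs_delta(a, b)
    if test == "wilcoxon_signed_rank" or paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        diff = a - b
        if np.all(diff == 0):
            return AssociationResult("wilcoxon_signed_rank", float("nan"), float("nan"),
                                     len(a), effect_size=delta,
                                     meta={"all_zero_differences": True})
        res = sps.wilcoxon(a, b, alternative="two-sided")
        return AssociationResult("wilcoxon_signed_rank", float(res.statistic),
                                 float(res.pvalue), len(a), effect_size=delta)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return AssociationResult("mann_whitney", float(res.statistic), float(res.pvalue),
                             len(a) + len(b), effect_size=delta,
                             meta={"n_a": len(a), "n_b": len(b)})


def quartile_enrichment(values: pd.Series, membership: dict, tail: str = "top25",
                        min_in_universe: int = 2) -> list[AssociationResult]:
    """Fisher's exact enrichment of annotation sets in a CR quartile.

    ``values`` maps orthogroup -> score; the tail is the top or bottom 25%
    with boundary ties included. Each set with >= ``min_in_universe`` members
    in the universe gets a two-sided Fisher test on the 2x2 (in-tail x
    in-set) table; p-values are BH-adjusted across the sets tested together.
    """
    values = values.dropna()
    if len(values) < 8:
        raise UndefinedStatisticError("need >=8 orthogroups for quartile enrichment")
    if tail == "top25":
        thr = values.quantile(0.75)
        in_tail = values >= thr
    elif tail == "bottom25":
        thr = values.quantile(0.25)
        in_tail = values <= thr
    else:
        raise ValueError(tail)
    universe = set(values.index)
    results = []
    for name, members in sorted(membership.items()):
        members = set(members) & universe
        if len(members) < min_in_universe:
            continue
        a = sum(1 for og in members if in_tail[og])
        b = int(in_tail.sum()) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(AssociationResult(
            "fisher_exact", float(odds) if math.isfinite(odds) else float("inf"),
            float(p), len(universe),
            meta={"set": name, "table": [[a, b], [c, d]], "tail": tail}))
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def roc_enrichment(scores, labels):
    """ROC curve and AUC of a ranking against binary labels.

    AUC is computed through the Mann-Whitney identity U/(n1*n0) with midrank
    ties; the curve sweeps all score thresholds.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("ROC needs both label classes")
    ranks = sps.rankdata(scores)
    U = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = float(U / (n1 * n0))
    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    return fpr, tpr, auc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def phenotype_split(cr: pd.DataFrame, phenotype: dict,
                    min_species: int = 2) -> tuple[pd.DataFrame, AssociationResult]:
    """Subdivide orthogroups by a species phenotype and compare mean CRs.

    ``cr`` is a long table with columns og_id, species, cr; ``phenotype``
    maps species -> {'yes','no','variable'} ('variable' excluded). Returns a
    per-orthogroup table of subgroup means and their difference, plus the
    paired two-sided Wilcoxon signed-rank result across orthogroups.
    Orthogroups missing one subgroup are excluded and counted.
    """
    keep = cr[cr["species"].map(lambda s: phenotype.get(s) in ("yes", "no"))].copy()
    keep["pheno"] = keep["species"].map(phenotype)
    for lab in ("yes", "no"):
        if keep.loc[keep["pheno"] == lab, "species"].nunique() < min_species:
            raise UndefinedStatisticError(f"fewer than {min_species} '{lab}' species")
    rows, excluded = [], 0
    for og, sub in keep.groupby("og_id"):
        means = sub.groupby("pheno")["cr"].mean()
        if "yes" not in means or "no" not in means:
            excluded += 1
            continue
        rows.append({"og_id": og, "cr_yes": means["yes"], "cr_no": means["no"],
                     "delta_cr": means["yes"] - means["no"]})
    table = pd.DataFrame(rows).sort_values("delta_cr", ascending=False).reset_index(drop=True)
    res = group_compare(table["cr_yes"], table["cr_no"],
                        test="wilcoxon_signed_rank", paired=True)
    res.meta["n_excluded_orthogroups"] = excluded
    return table, res


def association_report(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten AssociationResults into the report TSV layout, with a BH pass
    over the family if any adjusted values are missing."""
    if any(r.p_adjusted is None for r in results):
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            if r.p_adjusted is None:
                r.p_adjusted = float(q)
    return pd.DataFrame([{
        "test": r.test_name, "estimate": r.estimate, "effect_size": r.effect_size,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted, "n": r.n,
        **{f"meta_{k}": v for k, v in r.meta.items() if not isinstance(v, (list, dict))},
    } for r in results])
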