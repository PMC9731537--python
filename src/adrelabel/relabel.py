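"""Cluster-based diagnostic re-labelling and its statistical validation.

One cluster is expected to be dominated by clinically diagnosed AD
cases.  The re-labelling rule promotes every CN and MCI case inside
that cluster to AD; AD cases outside the cluster are deliberately left
untouched (label revision is one-directional).  Agreement between the
original and revised labels is quantified with unweighted Cohen's
kappa, and the revised groups are validated post hoc by comparing
held-out biomarkers (tau-region uptake, memory composites, CSF
amyloid-beta) across the groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ClusterAssignment, FeatureTable, LabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "identify_ad_cluster",
    "relabel_ad_cluster",
    "cohen_kappa",
    "posthoc_group_summary",
    "relabel_groups",
    "welch_t_test",
]


def identify_ad_cluster(clusters: ClusterAssignment, labels: LabelSet) -> int:
    """Index of the cluster with the highest within-cluster AD proportion.

    The proportion criterion (rather than an absolute majority) also
    covers settings where no cluster exceeds 50% AD.  Ties resolve to
    the lowest index.
    """
    if labels.provenance != "original":
        raise ValueError("AD-cluster identification expects original labels")
    is_ad = labels.labels == "AD"
    if not is_ad.any():
        raise ValueError("no AD-enriched cluster: no AD cases in the labels")
    props = {c: float(is_ad.loc[clusters.members(c)].mean())
             for c in range(clusters.k)}
    best = max(props.values())
    winners = [c for c in sorted(props) if props[c] == best]
    if len(winners) > 1:
        logger.info("AD-proportion tie between clusters %s; taking %d",
                    winners, winners[0])
    return winners[0]


def relabel_ad_cluster(labels: LabelSet, clusters: ClusterAssignment,
                       ad_cluster: int) -> LabelSet:
    """Promote every CN/MCI case inside ``ad_cluster`` to AD.

    AD-labelled cases are never changed, anywhere.  The result carries
    provenance ``relabelled`` and a mask of the changed samples.
    """
    if labels.provenance != "original":
        raise ValueError("re-labelling expects original labels")
    if not 0 <= ad_cluster < clusters.k:
        raise IndexError(f"cluster index {ad_cluster} out of range 0..{clusters.k - 1}")
    new = labels.labels.copy()
    members = clusters.members(ad_cluster)
    mask = pd.Series(False, index=new.index)
    to_change = members[new.loc[members] != "AD"]
    new.loc[to_change] = "AD"
    mask.loc[to_change] = True
    return LabelSet(new, provenance="relabelled", relabel_mask=mask)


def cohen_kappa(a: LabelSet | pd.Series, b: LabelSet | pd.Series) -> float:
    """Unweighted Cohen's kappa between two categorical labelings.

    kappa = (p_o - p_e) / (1 - p_e) with the expected agreement p_e taken
    from the product of the two marginal distributions.  When both sides
    are the same constant labeling (p_e = 1), returns 1 by convention.
    """
    sa = a.labels if isinstance(a, LabelSet) else pd.Series(a)
    sb = b.labels if isinstance(b, LabelSet) else pd.Series(b)
    if len(sa) != len(sb):
        raise ValueError("label vectors must have equal length")
    if len(sa) == 0:
        raise ValueError("empty label vectors")
    av, bv = np.asarray(sa), np.asarray(sb)
    cats = np.unique(np.concatenate([av, bv]))
    n = len(av)
    p_o = float((av == bv).mean())
    pa = np.array([(av == c).sum() for c in cats]) / n
    pb = np.array([(bv == c).sum() for c in cats]) / n
    p_e = float((pa * pb).sum())
    if p_e == 1.0:
        logger.info("both labelings constant and equal; kappa = 1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def relabel_groups(labels_original: LabelSet, labels_relabelled: LabelSet,
                   clusters: ClusterAssignment, ad_cluster: int) -> dict[str, pd.Index]:
    """The four validation groups used in the post-hoc biomarker check.

    ``non_ad``: not AD under either labeling; ``cn_mci_to_ad``: the
    re-labelled cases; ``remained_ad``: originally AD (unchanged by the
    rule); ``ad_outside_ad_cluster``: the subset of remained-AD falling
    outside the AD cluster.
    """
    orig = labels_original.labels
    mask = labels_relabelled.relabel_mask
    members = clusters.members(ad_cluster)
    return {
        "non_ad": orig.index[(orig != "AD") & ~mask],
        "cn_mci_to_ad": orig.index[mask],
        "remained_ad": orig.index[orig == "AD"],
        "ad_outside_ad_cluster": orig.index[
            (orig == "AD") & ~orig.index.isin(members)],
    }


def posthoc_group_summary(table: FeatureTable | pd.DataFrame,
                          groups: dict[str, pd.Index],
                          features: list[str]) -> pd.DataFrame:
    """Per-group n, mean, and SD (n-1 denominator) of selected features.

    Missing entries are dropped per feature; an SD over fewer than two
    observed values is reported as NaN.
    """
    df = table.df if isinstance(table, FeatureTable) else table
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise KeyError(f"unknown features: {missing}")
    rows = []
    for gname, idx in groups.items():
        sub = df.loc[idx, features]
        for f in features:
            vals = sub[f].dropna()
            rows.append({
                "group": gname,
                "feature": f,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan,
            })
    return pd.DataFrame(rows)


def welch_t_test(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Degenerate case: both samples with zero variance and equal means
    gives t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            logger.info("both samples constant and equal; t = 0, p = 1")
            return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
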