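"""Manifold embedding, cluster discovery, and cluster characterization.

The preprocessed table is embedded with UMAP (30 neighbours, minimum
distance 0, 5 output dimensions by default: a large neighbourhood to
avoid overly local structure, zero minimum distance to densify
clusters), discrete clusters are found with k-means (k = 5 by default),
and the features most associated with cluster membership are ranked by
information gain.  Clusters are then given human-readable names from
their dominant characteristics (single-gender, youngest with family
history, AD-enriched, catchall).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .tables import ClusterAssignment, Embedding, FeatureTable, LabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRanking",
    "embed_umap",
    "kmeans_cluster",
    "information_gain",
    "rank_features_infogain",
    "name_clusters",
    "plot_embedding",
]


def embed_umap(table: FeatureTable, neighbours: int = 30, min_dist: float = 0.0,
               dims: int = 5, seed: int = 0) -> Embedding:
    """Embed the table into a low-dimensional UMAP manifold.

    Runs single-threaded with a fixed random state so identical inputs
    give identical coordinates.
    """
    n = table.n_samples
    if dims >= n or neighbours >= n:
        raise ValueError(
            f"dims ({dims}) and neighbours ({neighbours}) must be < n_samples ({n})")
    if not table.is_complete():
        raise ValueError("embedding requires a fully imputed table")
    import umap  # deferred: numba JIT import is slow

    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # trade is deliberate here
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=neighbours,
            min_dist=min_dist,
            n_components=dims,
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(table.values())
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        sample_ids=table.sample_ids,
        params={"neighbours": neighbours, "min_dist": min_dist,
                "dims": dims, "seed": seed},
    )


def kmeans_cluster(embedding: Embedding, k: int = 5, seed: int = 0,
                   n_init: int = 10) -> ClusterAssignment:
    """Hard k-means assignment in embedding space (greedy ++ seeding,
    ``n_init`` restarts, best inertia kept)."""
    n = embedding.coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k ({k}) exceeds the number of samples ({n})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(embedding.coords)
    # relabel so cluster indices are contiguous 0..k-1 even if a centroid
    # ended up empty (possible for degenerate inputs)
    uniq = np.unique(assignment)
    remap = {c: i for i, c in enumerate(uniq)}
    assignment = np.array([remap[c] for c in assignment])
    return ClusterAssignment(
        pd.Series(assignment, index=embedding.sample_ids), k=len(uniq))


# ---------------------------------------------------------------------------
# information gain
# ---------------------------------------------------------------------------

def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(values: pd.Series, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; features with few distinct values are
    treated as already discrete."""
    if values.nunique() <= n_bins:
        codes, _ = pd.factorize(values)
        return codes
    binned = pd.qcut(values, q=n_bins, duplicates="drop", labels=False)
    return np.asarray(binned)


def information_gain(feature: pd.Series, clusters: np.ndarray,
                     n_bins: int = 5) -> float:
    """IG = H(cluster) - H(cluster | discretized feature), in bits."""
    x = _discretize(feature, n_bins)
    h = _entropy_bits(clusters)
    cond = 0.0
    n = len(clusters)
    for v in np.unique(x):
        mask = x == v
        cond += mask.sum() / n * _entropy_bits(clusters[mask])
    # plug-in estimate; clip tiny negative rounding
    return max(h - cond, 0.0)


@dataclass
class FeatureRanking:
    """Features ordered by information gain against cluster membership."""

    scores: list[tuple[str, float]]  # (feature, bits), non-increasing

    def __post_init__(self) -> None:
        vals = [s for _, s in self.scores]
        if any(v < 0 for v in vals):
            raise ValueError("information gain scores must be non-negative")
        if any(a < b - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("ranking must be non-increasing")

    def features(self) -> list[str]:
        return [f for f, _ in self.scores]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": range(1, len(self.scores) + 1),
             "feature": [f for f, _ in self.scores],
             "infogain_bits": [s for _, s in self.scores]}
        )


def rank_features_infogain(table: FeatureTable, clusters: ClusterAssignment,
                           top_n: int = 10, n_bins: int = 5) -> FeatureRanking:
    """Top ``top_n`` features by information gain w.r.t. cluster labels."""
    if top_n > len(table.feature_names):
        raise ValueError("top_n exceeds the number of features")
    if not table.is_complete():
        raise ValueError("information gain requires a complete table")
    y = clusters.assignment.loc[table.sample_ids].to_numpy()
    if len(np.unique(y)) == 1:
        logger.warning("single-cluster assignment: all information gains are 0")
    scores = {
        col: information_gain(table.df[col], y, n_bins=n_bins)
        for col in table.feature_names
    }
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return FeatureRanking(ordered)


# ---------------------------------------------------------------------------
# cluster naming
# ---------------------------------------------------------------------------

def name_clusters(clusters: ClusterAssignment, table: FeatureTable,
                  labels: LabelSet, gender_col: str = "gender",
                  age_col: str = "age",
                  fh_col: str = "mother_ad_history") -> ClusterAssignment:
    """Name clusters from their dominant characteristics.

    Rules, applied in order: a single-gender cluster is "Male"/"Female";
    the highest-AD-proportion remaining cluster is "AD"; the
    youngest-mean-age remaining cluster with elevated family history is
    "Young-FH"; everything left is "Catchall-NRF".  Duplicate names get
    the cluster index as a suffix.
    """
    df = table.df
    names: dict[int, str] = {}
    remaining = set(range(clusters.k))

    for c in sorted(remaining):
        members = clusters.members(c)
        g = df.loc[members, gender_col]
        if g.nunique() == 1:  # gender encoded 1 = male, 0 = female
            names[c] = "Male" if g.iloc[0] == 1 else "Female"
    remaining -= set(names)

    if remaining:
        ad_prop = {
            c: (labels.labels.loc[clusters.members(c)] == "AD").mean()
            for c in remaining
        }
        best = max(sorted(remaining), key=lambda c: ad_prop[c])
        if ad_prop[best] > 0:
            names[best] = "AD"
            remaining.discard(best)

    if remaining:
        overall_fh = df[fh_col].mean()
        ages = {c: df.loc[clusters.members(c), age_col].mean() for c in remaining}
        youngest = min(sorted(remaining), key=lambda c: ages[c])
        fh = df.loc[clusters.members(youngest), fh_col].mean()
        if fh > overall_fh:
            names[youngest] = "Young-FH"
            remaining.discard(youngest)

    for c in sorted(remaining):
        names[c] = "Catchall-NRF"

    # de-duplicate
    seen: dict[str, list[int]] = {}
    for c, nm in names.items():
        seen.setdefault(nm, []).append(c)
    for nm, cs in seen.items():
        if len(cs) > 1:
            logger.warning("duplicate cluster name %r; suffixing indices", nm)
            for c in cs:
                names[c] = f"{nm}-{c}"

    return ClusterAssignment(clusters.assignment.copy(), k=clusters.k, names=names)


def plot_embedding(embedding: Embedding, clusters: ClusterAssignment,
                   path: str, dims: tuple[int, int] = (0, 1)) -> None:
    """Basic 2-D scatter of two embedding axes coloured by cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = dims
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in range(clusters.k):
        mask = (clusters.assignment == c).to_numpy()
        ax.scatter(embedding.coords[mask, i], embedding.coords[mask, j],
                   s=8, label=clusters.name_of(c))
    ax.set_xlabel(f"UMAP {i + 1}")
    ax.set_ylabel(f"UMAP {j + 1}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
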