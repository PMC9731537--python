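"""Model/results objects for the cluster-based re-labelling analysis.

``ClusterRelabelModel`` binds a raw feature table and original
diagnoses; ``fit`` runs preprocessing, manifold embedding, cluster
discovery, feature ranking, cluster naming and the re-labelling rule,
returning a ``ClusterRelabelResults`` with the revised labels, the
agreement statistic and post-hoc validation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import manifold, preprocess, relabel as relabel_mod
from .tables import ClusterAssignment, Embedding, FeatureTable, LabelSet


class ClusterRelabelModel:
    """Unsupervised re-labelling model over a heterogeneous feature table.

    Parameters
    ----------
    table : FeatureTable
        Raw (possibly incomplete) merged table.
    labels : LabelSet
        Original clinician diagnoses (provenance ``original``).
    neighbours, min_dist, dims : UMAP parameters.
    k : number of discrete clusters.
    top_n, n_bins : information-gain ranking parameters.
    """

    def __init__(self, table: FeatureTable, labels: LabelSet, *,
                 neighbours: int = 30, min_dist: float = 0.0, dims: int = 5,
                 k: int = 5, top_n: int = 10, n_bins: int = 5,
                 preprocessed: bool = False):
        if len(labels) != table.n_samples:
            raise ValueError("labels must cover exactly the table's samples")
        self.table = table
        self.labels = labels
        self.neighbours = neighbours
        self.min_dist = min_dist
        self.dims = dims
        self.k = k
        self.top_n = top_n
        self.n_bins = n_bins
        self.preprocessed = preprocessed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "diagnosis",
                       blocks: dict | None = None, kinds: dict | None = None,
                       **kwargs) -> "ClusterRelabelModel":
        labels = LabelSet(df[label_column])
        feats = df.drop(columns=[label_column])
        table = FeatureTable(
            feats,
            blocks or {c: "imaging" for c in feats.columns},
            kinds or {c: "numeric" for c in feats.columns},
        )
        return cls(table, labels, **kwargs)

    def fit(self, seed: int = 0) -> "ClusterRelabelResults":
        processed = (self.table if self.preprocessed
                     else preprocess.run_preprocess(self.table))
        embedding = manifold.embed_umap(
            processed, neighbours=self.neighbours, min_dist=self.min_dist,
            dims=self.dims, seed=seed)
        clusters = manifold.kmeans_cluster(embedding, k=self.k, seed=seed)
        ranking = manifold.rank_features_infogain(
            processed, clusters, top_n=self.top_n, n_bins=self.n_bins)
        named = manifold.name_clusters(clusters, self.table, self.labels) \
            if "gender" in self.table.df.columns else clusters
        ad_cluster = relabel_mod.identify_ad_cluster(named, self.labels)
        relabelled = relabel_mod.relabel_ad_cluster(self.labels, named, ad_cluster)
        kappa = relabel_mod.cohen_kappa(self.labels, relabelled)
        return ClusterRelabelResults(
            model=self, processed=processed, embedding=embedding,
            clusters=named, ranking=ranking, ad_cluster=ad_cluster,
            labels_relabelled=relabelled, kappa=kappa, seed=seed)


@dataclass
class ClusterRelabelResults:
    """Fitted re-labelling analysis."""

    model: ClusterRelabelModel
    processed: FeatureTable
    embedding: Embedding
    clusters: ClusterAssignment
    ranking: manifold.FeatureRanking
    ad_cluster: int
    labels_relabelled: LabelSet
    kappa: float
    seed: int
    _groups: dict | None = field(default=None, repr=False)

    @property
    def n_relabelled(self) -> int:
        return int(self.labels_relabelled.relabel_mask.sum())

    def groups(self) -> dict[str, pd.Index]:
        if self._groups is None:
            self._groups = relabel_mod.relabel_groups(
                self.model.labels, self.labels_relabelled,
                self.clusters, self.ad_cluster)
        return self._groups

    def group_summary(self, features: list[str],
                      table: FeatureTable | pd.DataFrame | None = None
                      ) -> pd.DataFrame:
        """Post-hoc biomarker summary over the four validation groups.

        ``table`` defaults to the raw input table (biomarkers in their
        original units); pass any frame indexed by sample id to compare
        held-out variables such as CSF amyloid-beta.
        """
        return relabel_mod.posthoc_group_summary(
            table if table is not None else self.model.table,
            self.groups(), features)

    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster size and diagnosis composition (original labels)."""
        rows = []
        for c in range(self.clusters.k):
            members = self.clusters.members(c)
            diag = self.model.labels.labels.loc[members]
            rows.append({
                "cluster": c,
                "name": self.clusters.name_of(c),
                "n": len(members),
                "CN": int((diag == "CN").sum()),
                "MCI": int((diag == "MCI").sum()),
                "AD": int((diag == "AD").sum()),
                "AD_pct": round(100 * (diag == "AD").mean(), 1),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        orig = self.model.labels.counts()
        new = self.labels_relabelled.counts()
        lines = [
            "Cluster-based re-labelling results",
            "=" * 50,
            f"samples                  {self.model.table.n_samples:>6d}",
            f"embedding                UMAP {self.embedding.n_dims}-d, "
            f"{self.model.neighbours} neighbours, min_dist {self.model.min_dist}",
            f"clusters (k-means)       {self.clusters.k:>6d}",
            f"AD-enriched cluster      {self.clusters.name_of(self.ad_cluster)!r} "
            f"(index {self.ad_cluster})",
            f"re-labelled CN/MCI->AD   {self.n_relabelled:>6d}",
            f"AD count                 {orig['AD']} -> {new['AD']}",
            f"Cohen's kappa            {self.kappa:>9.3f}",
            "-" * 50,
            "top features by information gain (bits):",
        ]
        for feat, bits in self.ranking.scores:
            lines.append(f"  {feat:<28} {bits:.3f}")
        return "\n".join(lines)
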