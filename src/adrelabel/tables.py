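"""Core data containers shared across the pipeline.

The pipeline moves four kinds of objects between stages: a feature table
(samples x named features, each feature tagged with a block and a kind),
a diagnostic label set, a hard cluster assignment, and a low-dimensional
embedding.  All four are thin wrappers around pandas/numpy structures so
that every stage can read and write plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BLOCKS = ("sociodemographic", "cfa", "imaging")
KINDS = ("numeric", "categorical")
DIAGNOSES = ("CN", "MCI", "AD")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class FeatureTable:
    """Sample-by-feature table with per-column block and kind tags.

    Parameters
    ----------
    df : DataFrame
        Indexed by unique sample id; one column per feature.  Missing
        entries are NaN (allowed before imputation only).
    blocks : dict
        feature name -> one of ``sociodemographic``, ``cfa``, ``imaging``.
    kinds : dict
        feature name -> ``numeric`` or ``categorical``.
    """

    df: pd.DataFrame
    blocks: dict[str, str]
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.df.index.is_unique:
            raise ValidationError("sample ids must be unique")
        cols = list(self.df.columns)
        for name, tagmap, allowed in (
            ("block", self.blocks, BLOCKS),
            ("kind", self.kinds, KINDS),
        ):
            missing = [c for c in cols if c not in tagmap]
            if missing:
                raise ValidationError(f"columns without a {name} tag: {missing[:5]}")
            bad = {c: tagmap[c] for c in cols if tagmap[c] not in allowed}
            if bad:
                raise ValidationError(f"invalid {name} tags: {bad}")

    # -- accessors --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def columns_in_block(self, block: str) -> list[str]:
        return [c for c in self.df.columns if self.blocks[c] == block]

    def numeric_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.kinds[c] == "numeric"]

    def categorical_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.kinds[c] == "categorical"]

    def is_complete(self) -> bool:
        return not self.df.isna().any().any()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), dict(self.blocks), dict(self.kinds))

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write data CSV (empty cells for missing) plus a column-tag sidecar."""
        path = Path(path)
        self.df.to_csv(path, index_label="sample_id")
        meta = pd.DataFrame(
            {
                "feature": self.feature_names,
                "block": [self.blocks[c] for c in self.feature_names],
                "kind": [self.kinds[c] for c in self.feature_names],
            }
        )
        meta.to_csv(path.with_suffix(path.suffix + ".columns"), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="sample_id")
        meta_path = path.with_suffix(path.suffix + ".columns")
        if meta_path.exists():
            meta = pd.read_csv(meta_path)
            blocks = dict(zip(meta["feature"], meta["block"]))
            kinds = dict(zip(meta["feature"], meta["kind"]))
        else:  # untagged external table: treat everything as numeric imaging
            blocks = {c: "imaging" for c in df.columns}
            kinds = {c: "numeric" for c in df.columns}
        return cls(df, blocks, kinds)


@dataclass
class LabelSet:
    """Per-sample diagnosis in {CN, MCI, AD} with relabelling provenance."""

    labels: pd.Series
    provenance: str = "original"
    relabel_mask: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.relabel_mask is None:
            self.relabel_mask = pd.Series(False, index=self.labels.index)
        bad = set(self.labels.dropna().unique()) - set(DIAGNOSES)
        if bad:
            raise ValidationError(f"unknown diagnosis values: {sorted(bad)}")
        if self.provenance not in ("original", "relabelled"):
            raise ValidationError(f"bad provenance {self.provenance!r}")
        if self.provenance == "original" and bool(self.relabel_mask.any()):
            raise ValidationError("original labels cannot carry a relabel mask")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {d: int(vc.get(d, 0)) for d in DIAGNOSES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"diagnosis": self.labels, "relabelled": self.relabel_mask}
        )


@dataclass
class ClusterAssignment:
    """Hard assignment of each sample to one of k clusters."""

    assignment: pd.Series
    k: int
    names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.assignment = pd.Series(self.assignment).astype(int)
        vals = set(self.assignment.unique())
        if not vals <= set(range(self.k)):
            raise ValidationError(f"cluster indices outside 0..{self.k - 1}: {vals}")
        if vals != set(range(self.k)):
            raise ValidationError("every cluster index must appear at least once")

    def __len__(self) -> int:
        return len(self.assignment)

    def members(self, cluster: int) -> pd.Index:
        return self.assignment.index[self.assignment == cluster]

    def sizes(self) -> dict[int, int]:
        return {c: int((self.assignment == c).sum()) for c in range(self.k)}

    def name_of(self, cluster: int) -> str:
        if self.names and cluster in self.names:
            return self.names[cluster]
        return str(cluster)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.assignment,
                "cluster_name": [self.name_of(c) for c in self.assignment],
            }
        )


@dataclass
class Embedding:
    """Manifold coordinates for each sample plus the parameters that made them."""

    coords: np.ndarray
    sample_ids: pd.Index
    params: dict

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValidationError("coords must be 2-D")
        if len(self.sample_ids) != self.coords.shape[0]:
            raise ValidationError("one coordinate row per sample id required")
        if "dims" in self.params and self.coords.shape[1] != self.params["dims"]:
            raise ValidationError("coordinate dimension disagrees with params")
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding contains non-finite coordinates")

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"umap_{i + 1}": self.coords[:, i] for i in range(self.n_dims)}
        return pd.DataFrame(cols, index=self.sample_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")
        Path(str(path) + ".params").write_text(json.dumps(self.params, indent=2))
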