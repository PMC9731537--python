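"""Data-preparation chain for the merged clinical/neuroimaging table.

Order of operations: similarity-based imputation of the sociodemographic
block, then column-wise mean/mode imputation of everything still
missing, one-hot expansion of the APoE4 allele count, shifting of
negative columns to zero minimum, and finally min-max normalization.
After the full chain the table is complete and every value lies in
[0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationError",
    "impute_simple",
    "impute_similarity",
    "shift_nonnegative",
    "minmax_normalize",
    "onehot_apoe4",
    "run_preprocess",
]


class ImputationError(ValueError):
    pass


def impute_simple(table: FeatureTable) -> FeatureTable:
    """Column mean for numeric cells, column mode for categorical cells.

    Observed cells are never altered.  A column with no observed value at
    all cannot be imputed and raises, naming the column.
    """
    out = table.copy()
    for col in out.df.columns:
        s = out.df[col]
        if not s.isna().any():
            continue
        observed = s.dropna()
        if observed.empty:
            raise ImputationError(f"column {col!r} has no observed values")
        if out.kinds[col] == "numeric":
            fill = observed.mean()
        else:
            # mode; ties broken by smallest value for determinism
            fill = observed.mode().min()
        out.df[col] = s.fillna(fill)
    return out


def _gower_similarity(row: pd.Series, others: pd.DataFrame,
                      kinds: dict[str, str], ranges: pd.Series) -> pd.Series:
    """Mean per-feature similarity of one row to each complete row.

    Numeric features contribute 1 - |difference|/range, categorical ones
    an equality indicator; features missing in the target row are skipped.
    """
    sims = []
    for col in others.columns:
        v = row[col]
        if pd.isna(v):
            continue
        if kinds[col] == "numeric":
            rng = ranges[col]
            if rng == 0:
                sims.append(pd.Series(1.0, index=others.index))
            else:
                sims.append(1.0 - (others[col] - v).abs() / rng)
        else:
            sims.append((others[col] == v).astype(float))
    if not sims:
        return pd.Series(np.nan, index=others.index)
    return pd.concat(sims, axis=1).mean(axis=1)


def impute_similarity(table: FeatureTable, target_block: str = "sociodemographic",
                      n_neighbours: int = 10) -> FeatureTable:
    """Fill missing cells of one block from the most similar complete row.

    For each row with a missing target-block cell, similarity to every
    row complete in that block is computed over all shared observed
    features (Gower-style), the ``n_neighbours`` most similar rows are
    retained, and the value is copied from the single most similar
    reference.  Ties break on the lowest sample id.  If no complete
    reference row exists the block falls back to modal/mean imputation
    with a warning.
    """
    out = table.copy()
    block_cols = out.columns_in_block(target_block)
    if not block_cols:
        return out
    block = out.df[block_cols]
    incomplete = block.index[block.isna().any(axis=1)]
    if len(incomplete) == 0:
        return out
    complete = block.index[block.notna().all(axis=1)]
    if len(complete) == 0:
        logger.warning(
            "no complete reference rows in block %r; falling back to "
            "mean/mode imputation", target_block)
        sub = FeatureTable(out.df[block_cols],
                           {c: out.blocks[c] for c in block_cols},
                           {c: out.kinds[c] for c in block_cols})
        out.df[block_cols] = impute_simple(sub).df
        return out

    ranges = out.df.max(numeric_only=False) - out.df.min()
    refs = out.df.loc[complete]
    for rid in incomplete:
        sim = _gower_similarity(out.df.loc[rid], refs.drop(index=rid, errors="ignore"),
                                out.kinds, ranges)
        # ~n_neighbours most similar candidates, then the single best;
        # ties resolved by lowest sample id (stable sort on id order)
        sim = sim.sort_index()
        top = sim.sort_values(ascending=False, kind="stable").head(n_neighbours)
        best = top.index[0]
        for col in block_cols:
            if pd.isna(out.df.at[rid, col]):
                out.df.at[rid, col] = out.df.at[best, col]
    return out


def shift_nonnegative(table: FeatureTable) -> FeatureTable:
    """Add |column minimum| to every numeric column containing a negative."""
    out = table.copy()
    for col in out.numeric_columns():
        m = out.df[col].min()
        if m < 0:
            out.df[col] = out.df[col] + abs(m)
    return out


def minmax_normalize(table: FeatureTable) -> FeatureTable:
    """Map every column to (x - min)/(max - min); constant columns to 0."""
    out = table.copy()
    for col in out.df.columns:
        s = out.df[col].astype(float)
        lo, hi = s.min(), s.max()
        if hi == lo:
            logger.warning("constant column %r normalized to all zeros", col)
            out.df[col] = 0.0
        else:
            out.df[col] = (s - lo) / (hi - lo)
    return out


def onehot_apoe4(table: FeatureTable, column: str = "apoe4") -> FeatureTable:
    """Expand the APoE4 allele count (0/1/2) into three indicator columns.

    A no-op when the column is absent (e.g. on already-encoded tables).
    """
    out = table.copy()
    if column not in out.df.columns:
        return out
    values = out.df[column]
    bad = values.dropna()[~values.dropna().isin([0, 1, 2])]
    if len(bad):
        raise ValueError(
            f"{column} values outside {{0,1,2}}: {sorted(bad.unique())[:5]}")
    if values.isna().any():
        raise ValueError(f"{column} must be imputed before one-hot encoding")
    pos = out.df.columns.get_loc(column)
    block = out.blocks.pop(column)
    out.kinds.pop(column)
    df = out.df.drop(columns=[column])
    for offset, level in enumerate((0, 1, 2)):
        name = f"{column}_{level}"
        df.insert(pos + offset, name, (values == level).astype(float))
        out.blocks[name] = block
        out.kinds[name] = "categorical"
    out.df = df
    return out


def run_preprocess(table: FeatureTable) -> FeatureTable:
    """Full preparation chain; output is complete with values in [0, 1]."""
    stages = [
        ("similarity_imputation", lambda t: impute_similarity(t, "sociodemographic")),
        ("simple_imputation", impute_simple),
        ("onehot_apoe4", onehot_apoe4),
        ("shift_nonnegative", shift_nonnegative),
        ("minmax_normalize", minmax_normalize),
    ]
    out = table
    for name, stage in stages:
        before = out.df.copy()
        try:
            out = stage(out)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        changed = _count_changed(before, out.df)
        logger.info("stage %s: %d cells changed", name, changed)
    if len(out.df) and (out.df.isna().any().any()
                        or (out.df.to_numpy() < -1e-12).any()
                        or (out.df.to_numpy() > 1 + 1e-12).any()):
        raise AssertionError("preprocessing postcondition violated")
    return out


def _count_changed(before: pd.DataFrame, after: pd.DataFrame) -> int:
    shared = before.columns.intersection(after.columns)
    b, a = before[shared], after[shared]
    diff = (b != a) & ~(b.isna() & a.isna())
    return int(diff.to_numpy().sum()) + abs(len(after.columns) - len(before.columns)) * len(after)
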