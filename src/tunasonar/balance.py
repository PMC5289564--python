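"""Class-imbalance handling for the blob training table.

The reference imagery yields far more clutter blobs than tuna blobs
(positives:negatives of 1:14 in the original training table), because
images containing tuna also contain many non-tuna blobs.  Two standard
remedies are provided: SMOTE oversampling of the minority class and
spread subsampling of the majority class.

Canonical class labels are ``"tuna"`` (positive/minority) and
``"no-tuna"`` (negative/majority).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphfeatures import FEATURE_COLUMNS

log = logging.getLogger(__name__)

POSITIVE_CLASS = "tuna"
NEGATIVE_CLASS = "no-tuna"
TABLE_COLUMNS = ["Blob_ID"] + FEATURE_COLUMNS + ["Class"]


@dataclass
class TrainingTable:
    """A labelled collection of blob feature rows (S1 schema).

    Wraps a DataFrame with columns ``Blob_ID``, the 20 numeric descriptors,
    and ``Class`` in {"tuna", "no-tuna"}.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing column {missing[0]}")
        self.df = self.df[TABLE_COLUMNS].reset_index(drop=True)

    @property
    def n_pos(self) -> int:
        return int((self.df["Class"] == POSITIVE_CLASS).sum())

    @property
    def n_neg(self) -> int:
        return int((self.df["Class"] == NEGATIVE_CLASS).sum())

    def __len__(self) -> int:
        return len(self.df)

    def ratio(self) -> float:
        """Majority-to-minority ratio n_neg / n_pos."""
        if self.n_pos == 0:
            raise ValueError("ratio undefined: no positive rows")
        return self.n_neg / self.n_pos

    def features(self) -> np.ndarray:
        """(N, 20) float matrix of the numeric descriptors."""
        return self.df[FEATURE_COLUMNS].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        """Binary label vector: 1 = tuna, 0 = no-tuna."""
        return (self.df["Class"] == POSITIVE_CLASS).to_numpy().astype(int)

    def subset(self, idx) -> "TrainingTable":
        return TrainingTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


def smote(table: TrainingTable, percent: float = 100.0, k_neighbors: int = 5,
          seed: int | None = None) -> TrainingTable:
    """Synthetic Minority Oversampling.

    Each synthetic row is drawn by picking a minority row, one of its
    ``k_neighbors`` nearest minority neighbours (Euclidean distance on
    z-scored features), and interpolating uniformly along the segment
    between them in the original feature space.  ``percent=100`` spawns one
    synthetic row per minority row, so n_pos doubles; other multiples of
    100 spawn ``percent/100`` per row, and fractional parts are covered by
    a random minority subset.  Majority rows are never touched.
    """
    if percent < 0:
        raise ValueError("percent must be >= 0")
    n_pos = table.n_pos
    if n_pos == 0:
        raise ValueError("no minority instances")
    rng = np.random.default_rng(seed)

    k = k_neighbors
    if n_pos <= k:
        k = max(n_pos - 1, 0)
        warnings.warn(
            f"k_neighbors reduced from {k_neighbors} to {k}: only {n_pos} "
            "minority instances")

    pos_mask = (table.df["Class"] == POSITIVE_CLASS).to_numpy()
    pos_idx = np.flatnonzero(pos_mask)
    X = table.features()[pos_idx]

    n_syn = int(round(n_pos * percent / 100.0))
    whole, extra = divmod(n_syn, n_pos)
    donors = np.repeat(np.arange(n_pos), whole)
    if extra:
        donors = np.concatenate(
            [donors, rng.choice(n_pos, size=extra, replace=False)])

    if k > 0:
        from sklearn.neighbors import NearestNeighbors

        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Z).kneighbors(
            Z, return_distance=False)[:, 1:]

    syn_rows = []
    base = table.df.iloc[pos_idx].reset_index(drop=True)
    for i, d in enumerate(donors):
        if k > 0:
            nb = int(nn[d, rng.integers(k)])
            u = rng.random()
            vec = X[d] + u * (X[nb] - X[d])
        else:
            vec = X[d].copy()
        row = base.iloc[int(d)].copy()
        row[FEATURE_COLUMNS] = vec
        row["Blob_ID"] = f"{row['Blob_ID']}_syn{i}"
        syn_rows.append(row)

    out = pd.concat([table.df, pd.DataFrame(syn_rows)], ignore_index=True)
    return TrainingTable(out)


def spread_subsample(table: TrainingTable, majority_factor: float = 0.5,
                     max_ratio: float | None = None,
                     seed: int | None = None) -> TrainingTable:
    """Uniform random subsampling of the majority class.

    All minority rows are kept; ``floor(n_neg * majority_factor)`` majority
    rows are kept, sampled uniformly without replacement (original row
    order preserved).  Alternatively ``max_ratio`` caps the resulting
    majority:minority ratio, overriding ``majority_factor``.
    """
    if max_ratio is not None:
        if max_ratio <= 0:
            raise ValueError("max_ratio must be > 0")
        target = min(table.n_neg, int(max_ratio * table.n_pos))
    else:
        if not 0 < majority_factor <= 1:
            raise ValueError("majority_factor must be in (0, 1]")
        target = int(table.n_neg * majority_factor)

    rng = np.random.default_rng(seed)
    neg_idx = np.flatnonzero((table.df["Class"] == NEGATIVE_CLASS).to_numpy())
    keep_neg = np.sort(rng.choice(neg_idx, size=target, replace=False))
    pos_idx = np.flatnonzero((table.df["Class"] == POSITIVE_CLASS).to_numpy())
    keep = np.sort(np.concatenate([pos_idx, keep_neg]))
    return table.subset(keep)
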