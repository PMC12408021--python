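"""Core in-memory containers: feature tables and distance matrices.

A :class:`FeatureTable` is a features x samples matrix (taxa or pathways).
Internally all relative tables live on the proportion scale (0-1); percentage
conversion happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio


class FeatureTable:
    """Features x samples matrix of non-negative values.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index and sample ids as columns.
    kind:
        ``"counts"`` or ``"relative"``. Relative tables must sum to ~1
        per sample.
    level:
        Optional taxonomy level tag (e.g. ``"species"``, ``"genus"``,
        ``"pathway"``).
    taxonomy:
        Optional mapping feature id -> full pipe-delimited clade string.
    """

    def __init__(self, data: pd.DataFrame, kind: str = "relative",
                 level: str | None = None,
                 taxonomy: dict[str, str] | None = None,
                 check_closure: bool = True):
        if kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {kind!r}")
        data = data.astype(float)
        if (data.values < 0).any():
            raise ValueError("feature table contains negative entries")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup}")
        if kind == "relative" and check_closure:
            sums = data.sum(axis=0).values
            nonzero = sums > 0
            if nonzero.any() and not np.allclose(sums[nonzero], 1.0, atol=1e-6):
                raise ValueError("relative table columns must sum to 1 (+-1e-6)")
        self.data = data
        self.kind = kind
        self.level = level
        self.taxonomy = taxonomy or {}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_relative(self) -> "FeatureTable":
        """Closure: rescale each sample to sum to 1 (no-op if already relative)."""
        if self.kind == "relative":
            return self
        sums = self.data.sum(axis=0)
        sums = sums.replace(0, np.nan)
        rel = self.data.div(sums, axis=1).fillna(0.0)
        return FeatureTable(rel, kind="relative", level=self.level,
                            taxonomy=self.taxonomy)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return FeatureTable(self.data[list(sample_ids)], kind=self.kind,
                            level=self.level, taxonomy=self.taxonomy,
                            check_closure=False)

    def subset_features(self, feature_ids) -> "FeatureTable":
        """Row subset. Closure is intentionally not re-imposed: values stay
        proportions of the original whole."""
        sub = self.data.loc[list(feature_ids)]
        return FeatureTable(sub, kind=self.kind, level=self.level,
                            taxonomy={f: self.taxonomy[f] for f in feature_ids
                                      if f in self.taxonomy},
                            check_closure=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"FeatureTable({self.shape[0]} features x {self.shape[1]} "
                f"samples, kind={self.kind!r}, level={self.level!r})")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with named samples."""

    ids: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
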