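"""Symmetric dyadic matrices (genetic, geographic and resistance distances).

The diagonal is undefined by convention (self-pairs carry no information in
pairwise landscape-genetic models) and stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METRICS = frozenset({
    "relatedness_r", "rousset_ar", "dps", "commute", "euclidean", "resistance",
})


@dataclass
class PairwiseMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        off = ~np.eye(n, dtype=bool)
        a, b = self.values, self.values.T
        both = off & np.isfinite(a) & np.isfinite(b)
        if not np.allclose(a[both], b[both]):
            raise ValueError("matrix is not symmetric")
        if (np.isfinite(a) != np.isfinite(b))[off].any():
            raise ValueError("matrix is not symmetric (mismatched missing entries)")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric tag {self.metric!r}")
        np.fill_diagonal(self.values, np.nan)

    @property
    def n(self) -> int:
        return len(self.ids)

    def dyads(self) -> Iterable[tuple[int, int]]:
        """Unordered dyads (i < j) in id order."""
        n = self.n
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values as a vector, scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return PairwiseMatrix([self.ids[k] for k in idx],
                              self.values[np.ix_(idx, idx)].copy(), self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path: str | Path, metric: str) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), metric)

    @classmethod
    def from_condensed(cls, ids: Sequence[str], condensed: np.ndarray,
                       metric: str) -> "PairwiseMatrix":
        n = len(ids)
        vals = np.full((n, n), np.nan)
        iu = np.triu_indices(n, k=1)
        vals[iu] = condensed
        vals[(iu[1], iu[0])] = condensed
        return cls(list(ids), vals, metric)


def euclidean_matrix(ids: Sequence[str], xy: np.ndarray) -> PairwiseMatrix:
    """Pairwise Euclidean distances between projected coordinates."""
    xy = np.asarray(xy, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    return PairwiseMatrix(list(ids), d, "euclidean")
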