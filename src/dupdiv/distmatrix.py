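"""Labeled symmetric distance matrices with an optional mask for undefined pairs.

This is the common currency of the pipeline: genetic distances, expression
distances and Dn/Ds ratios all travel as :class:`DistanceMatrix`.  The mask
marks pairs whose value is undefined (saturated ML distance, invalid omega);
masked entries are excluded pairwise from every downstream statistic rather
than dropping whole genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IdError, IncompleteMatrixError, ParseError

_SYM_TOL = 1e-12


class DistanceMatrix:
    def __init__(self, labels, values, mask=None):
        self.labels = tuple(str(l) for l in labels)
        if len(self.labels) != len(set(self.labels)):
            raise IdError("distance matrix labels must be unique")
        v = np.asarray(values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} labels")
        if mask is None:
            m = np.zeros((n, n), dtype=bool)
        else:
            m = np.asarray(mask, dtype=bool).copy()
        # undefined entries are ignored in the symmetry/negativity checks
        vis = ~m
        if np.any(np.abs(np.where(vis & vis.T, v - v.T, 0.0)) > _SYM_TOL):
            raise ValueError("distance matrix is not symmetric")
        if np.any(m != m.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v[vis] < 0):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(m, False)
        self.values = 0.5 * (v + v.T)
        np.fill_diagonal(self.values, 0.0)
        self.mask = m

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise IdError(f"label {label!r} not in distance matrix") from None

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self.index(a), self.index(b)]

    def reorder(self, labels) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = np.array([self.index(l) for l in labels])
        return DistanceMatrix(
            labels, self.values[np.ix_(idx, idx)], self.mask[np.ix_(idx, idx)]
        )

    def condensed(self, with_mask: bool = False):
        """Upper-triangle (i<j) vector of values; optionally the mask too."""
        iu = np.triu_indices(self.n, k=1)
        if with_mask:
            return self.values[iu], self.mask[iu]
        return self.values[iu]

    def pair_iter(self):
        """Yield (label_i, label_j, value, masked) for i < j."""
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield self.labels[i], self.labels[j], self.values[i, j], bool(
                    self.mask[i, j]
                )

    def require_complete(self, what: str):
        if not self.is_complete:
            bad = int(self.mask.sum() // 2)
            raise IncompleteMatrixError(
                f"{what} requires a complete matrix; {bad} pair(s) masked"
            )

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return df.mask(pd.DataFrame(self.mask, index=self.labels, columns=self.labels))

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ParseError("distance matrix TSV must have identical row/column labels")
        mask = df.isna().to_numpy()
        values = df.fillna(0.0).to_numpy(dtype=float)
        return cls(df.index, values, mask)

    @classmethod
    def from_condensed(cls, labels, condensed, mask=None):
        n = len(labels)
        v = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        v[iu] = condensed
        v += v.T
        m = None
        if mask is not None:
            m = np.zeros((n, n), dtype=bool)
            m[iu] = mask
            m |= m.T
        return cls(labels, v, m)
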