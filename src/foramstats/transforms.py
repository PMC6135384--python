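"""Community-matrix transformations and inter-sample distances.

The Hellinger transformation, y'_ij = sqrt(y_ij / y_i+), maps each sample
to the unit sphere so that plain Euclidean distances between transformed
rows equal Hellinger distances; it removes the double-zero problem that
makes raw Euclidean distance ecologically misleading.  Chord distance is
Euclidean distance between unit-norm-scaled rows (bounded by sqrt(2));
chi-square distance is the inter-row metric preserved by correspondence
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AssemblageMatrix, ValidationError

__all__ = [
    "DistanceMatrix",
    "hellinger",
    "chord_distance",
    "chi_square_distance",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample x sample distance table."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValidationError("negative distances")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.17g")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))

    def __getitem__(self, pair):
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, AssemblageMatrix):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr)


def hellinger(matrix, sqrt: bool = True):
    """Hellinger-transform a samples x taxa table.

    Each value is divided by its row sum and (by default) square-rooted, so
    every output row has unit sum of squares.  ``sqrt=False`` gives the plain
    relative-abundance profile instead (row sums 1), for comparison with the
    transform's occasionally-printed no-radical form.  Returns the same kind
    of object it is given (AssemblageMatrix in, AssemblageMatrix out).
    """
    df = _as_frame(matrix)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("hellinger requires nonnegative abundances")
    sums = values.sum(axis=1)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ValidationError(f"zero-abundance sample {df.index[zero[0]]!r}")
    out = values / sums[:, None]
    if sqrt:
        out = np.sqrt(out)
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, AssemblageMatrix):
        return AssemblageMatrix(res, mode="counts")
    if isinstance(matrix, pd.DataFrame):
        return res
    return res.to_numpy()


def chord_distance(matrix) -> DistanceMatrix:
    """Chord distance: Euclidean distance between unit-norm-scaled rows.

    For rows that are already unit-norm (e.g. Hellinger-transformed data) this
    is plain Euclidean distance; for nonnegative data every entry lies in
    [0, sqrt(2)].
    """
    df = _as_frame(matrix)
    values = df.to_numpy(dtype=float)
    norms = np.linalg.norm(values, axis=1)
    zero = np.nonzero(norms <= 0)[0]
    if zero.size:
        raise ValidationError(f"zero-norm sample {df.index[zero[0]]!r}")
    unit = values / norms[:, None]
    gram = unit @ unit.T
    sq = np.maximum(0.0, 2.0 - 2.0 * gram)
    d = np.sqrt(sq)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(df.index), d)


def chi_square_distance(matrix) -> DistanceMatrix:
    """Chi-square distance between sample rows (the CA/CCA site metric).

    D(i,k)^2 = sum_j (1/c_j) * (p_ij/r_i - p_kj/r_k)^2 with p the matrix
    scaled to unit grand total and r, c the row/column masses.  Columns with
    zero total have no defined weight and are dropped with a warning.
    """
    df = _as_frame(matrix)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("chi-square distance requires nonnegative abundances")
    total = values.sum()
    if total <= 0:
        raise ValidationError("zero grand total")
    col_sums = values.sum(axis=0)
    dead = np.nonzero(col_sums <= 0)[0]
    if dead.size:
        warnings.warn(
            f"dropping {dead.size} all-zero taxon column(s): "
            f"{[df.columns[j] for j in dead]}",
            stacklevel=2,
        )
        keep = col_sums > 0
        values = values[:, keep]
        col_sums = col_sums[keep]
    row_sums = values.sum(axis=1)
    zero = np.nonzero(row_sums <= 0)[0]
    if zero.size:
        raise ValidationError(f"zero-abundance sample {df.index[zero[0]]!r}")
    profiles = values / row_sums[:, None]
    c = col_sums / total
    scaled = profiles / np.sqrt(c)[None, :]
    sq = (
        (scaled ** 2).sum(axis=1)[:, None]
        + (scaled ** 2).sum(axis=1)[None, :]
        - 2.0 * scaled @ scaled.T
    )
    d = np.sqrt(np.maximum(0.0, sq))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(df.index), d)
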