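"""Expression-matrix container, TSV I/O and preprocessing.

The container holds a feature x sample matrix for one cohort (tumor or
control) together with a scale tag.  Raw values are normalized expression
units (RPKM/RPM); the analysis operates on log2(x + pseudocount).
Preprocessing follows the standard miRNA-seq recipe: log2 transform and
exclusion of very lowly expressed features.  ``bootstrap_match`` resamples
a cohort to a target size so tumor and control cohorts of unequal size can
be compared on equal footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionParseError",
    "read_expression_tsv",
    "log2_transform",
    "filter_low_expressed",
    "bootstrap_match",
]


class ExpressionParseError(ValueError):
    """Raised when an expression TSV is malformed (names the offending cell)."""


_COHORTS = ("tumor", "control")
_SCALES = ("raw", "log2")


@dataclass
class ExpressionMatrix:
    """Feature x sample numeric matrix with cohort and scale tags.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples. Values must be numeric and
        finite; non-negative when ``scale == "raw"``.
    cohort : {"tumor", "control"}
    scale : {"raw", "log2"}
    """

    data: pd.DataFrame
    cohort: str = "tumor"
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.cohort not in _COHORTS:
            raise ValueError(f"cohort must be one of {_COHORTS}, got {self.cohort!r}")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionParseError(f"duplicate feature id(s): {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ExpressionParseError("non-numeric values in expression matrix")
        if values.size and not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionParseError(
                f"non-finite value at feature {idx[r]!r}, sample {self.data.columns[c]!r}"
            )
        if self.scale == "raw" and values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ExpressionParseError(
                f"negative raw value at feature {idx[r]!r}, sample {self.data.columns[c]!r}"
            )

    # -- accessors -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def feature(self, feature_id: str) -> np.ndarray:
        """Observation vector for one feature across samples."""
        return self.data.loc[feature_id].to_numpy(dtype=float)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", lineterminator="\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_features} features x {self.n_samples} samples, "
            f"cohort={self.cohort}, scale={self.scale})"
        )


def read_expression_tsv(path, cohort: str = "tumor", scale: str = "raw") -> ExpressionMatrix:
    """Read a rectangular TSV (first column feature ids, header sample ids).

    Parsing is locale-independent (C float grammar).  Ragged rows, duplicate
    feature ids, missing or non-numeric cells raise
    :class:`ExpressionParseError` naming the offending feature/sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ExpressionParseError(f"{path}: duplicate feature id(s): {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (raw == "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[r, c]
        what = "missing cell" if cell == "" else f"non-numeric cell {cell!r}"
        raise ExpressionParseError(
            f"{path}: {what} at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), cohort=cohort, scale=scale)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply x -> log2(x + pseudocount) to a raw-scale matrix.

    The default pseudocount of 1 maps zero counts to exactly 0 and makes the
    transform invertible (x = 2**y - 1).  Double transformation is refused.
    """
    if m.scale != "raw":
        raise ValueError("matrix is already log2-scaled; refusing double transform")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    data = np.log2(m.data + pseudocount)
    return ExpressionMatrix(data, cohort=m.cohort, scale="log2")


def inverse_log2(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Invert :func:`log2_transform` (y -> 2**y - pseudocount, clipped at 0)."""
    if m.scale != "log2":
        raise ValueError("matrix is not log2-scaled")
    data = (2.0 ** m.data - pseudocount).clip(lower=0.0)
    return ExpressionMatrix(data, cohort=m.cohort, scale="raw")


def filter_low_expressed(
    m: ExpressionMatrix,
    min_nonzero_frac: float = 0.1,
    min_mean_raw: float = 1.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop very lowly expressed features from a raw-scale matrix.

    A feature is removed when EITHER its fraction of non-zero samples is
    below ``min_nonzero_frac`` or its mean raw expression is below
    ``min_mean_raw``.  Returns the filtered matrix (feature order preserved)
    and the list of removed feature ids.
    """
    if m.scale != "raw":
        raise ValueError("low-expression filter operates on raw-scale values")
    if not (0.0 <= min_nonzero_frac <= 1.0):
        raise ValueError("min_nonzero_frac must lie in [0, 1]")
    if min_mean_raw < 0:
        raise ValueError("min_mean_raw must be non-negative")
    values = m.values
    if m.n_features == 0:
        return m, []
    nonzero_frac = (values > 0).mean(axis=1)
    mean_raw = values.mean(axis=1)
    keep = (nonzero_frac >= min_nonzero_frac) & (mean_raw >= min_mean_raw)
    removed = [fid for fid, k in zip(m.feature_ids, keep) if not k]
    kept = ExpressionMatrix(m.data.loc[keep], cohort=m.cohort, scale=m.scale)
    return kept, removed


def bootstrap_match(
    m: ExpressionMatrix,
    target_n: int,
    seed: int,
    replace: bool = True,
) -> ExpressionMatrix:
    """Resample columns (samples) to exactly ``target_n``.

    Samples are drawn with replacement by default ("bootstrapped samples of
    the same size as the control cohort"); ``replace=False`` gives a plain
    subsample and requires ``target_n <= n_samples``.  Resampled sample ids
    are suffixed with the draw index to stay unique.
    """
    if m.n_samples == 0:
        raise ValueError("cannot resample an empty matrix")
    if target_n < 2:
        raise ValueError("target_n must be at least 2")
    if not replace and target_n > m.n_samples:
        raise ValueError("target_n exceeds sample count for without-replacement mode")
    rng = np.random.default_rng(seed)
    cols = rng.choice(m.n_samples, size=target_n, replace=replace)
    data = m.data.iloc[:, cols].copy()
    data.columns = [f"{m.data.columns[c]}.b{i}" for i, c in enumerate(cols)]
    return ExpressionMatrix(data, cohort=m.cohort, scale=m.scale)
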