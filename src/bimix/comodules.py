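"""Concurrent-expression modules among bimodal features.

A module is a group of at least ``min_size`` features whose pairwise
Pearson correlations all exceed ``r_threshold`` (strictly).  This is
formalized as maximal-clique enumeration on the graph whose edges connect
feature pairs with r above the threshold; maximal cliques may overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix

__all__ = ["CoexpressionModule", "pairwise_correlations", "find_modules"]

DEFAULT_R_THRESHOLD = 0.5
DEFAULT_MIN_SIZE = 3


@dataclass(frozen=True)
class CoexpressionModule:
    """Set of >= min_size features, all pairwise correlations > threshold."""

    feature_ids: tuple[str, ...]
    min_pairwise_r: float

    @property
    def size(self) -> int:
        return len(self.feature_ids)


def pairwise_correlations(m, feature_subset=None) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over samples.

    ``m`` is an :class:`ExpressionMatrix` or feature x sample DataFrame;
    ``feature_subset`` restricts to the given features (typically those
    with final BI above the detection threshold).  Zero-variance features
    are excluded with a warning since their correlation is undefined.
    """
    data = m.data if isinstance(m, ExpressionMatrix) else pd.DataFrame(m)
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        data = data.loc[list(feature_subset)]
    variances = data.var(axis=1, ddof=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        warnings.warn(f"excluding zero-variance feature(s): {flat}", stacklevel=2)
        data = data.drop(index=flat)
    corr = data.T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def find_modules(
    corr: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
    disjoint: bool = False,
) -> list[CoexpressionModule]:
    """Enumerate co-expression modules from a correlation matrix.

    Modules are maximal cliques of size >= ``min_size`` in the graph with
    an edge wherever r > ``r_threshold`` (strict).  Output order is
    deterministic: by size descending, then lexicographic member tuple.
    With ``disjoint=True`` a greedy pass keeps only cliques sharing no
    feature with a previously accepted (larger or lexicographically
    earlier) module.
    """
    corr = pd.DataFrame(corr)
    if not np.allclose(corr.values, corr.values.T, atol=1e-8, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(corr.index)
    ids = list(corr.index)
    vals = corr.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] > r_threshold:
                g.add_edge(ids[i], ids[j])
    modules = []
    for clique in nx.find_cliques(g):
        if len(clique) < min_size:
            continue
        members = tuple(sorted(str(f) for f in clique))
        sub = corr.loc[list(members), list(members)].to_numpy()
        off_diag = sub[~np.eye(len(members), dtype=bool)]
        modules.append(CoexpressionModule(members, float(off_diag.min())))
    modules.sort(key=lambda mod: (-mod.size, mod.feature_ids))
    if disjoint:
        seen: set[str] = set()
        kept = []
        for mod in modules:
            if seen.isdisjoint(mod.feature_ids):
                kept.append(mod)
                seen.update(mod.feature_ids)
        modules = kept
    return modules


def modules_to_frame(modules: list[CoexpressionModule]) -> pd.DataFrame:
    """Tabular view: module_id, size, members (comma-joined), min pairwise r."""
    return pd.DataFrame(
        {
            "module_id": [f"M{i + 1}" for i in range(len(modules))],
            "size": [m.size for m in modules],
            "members": [",".join(m.feature_ids) for m in modules],
            "min_pairwise_r": [m.min_pairwise_r for m in modules],
        }
    )
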