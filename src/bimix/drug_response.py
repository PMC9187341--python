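"""Correlation of miRNA expression with drug potency across cell lines.

For each drug, the Pearson correlation between per-cell-line miRNA
expression and log(IC50) is computed over the cell lines with both values
present.  Negative correlations mark drugs that are more potent (lower
IC50) in high-expressing lines, i.e. candidate treatments for the
high-expression patient subgroup; positive correlations mark drugs those
lines resist.  Pearson r is invariant to the log base; the natural log is
used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DrugCorrelation", "correlate_drugs", "rank_drugs", "module_score"]

MIN_CELL_LINES = 3


@dataclass(frozen=True)
class DrugCorrelation:
    drug_id: str
    n_cell_lines_used: int
    r: float  # NaN when undefined (constant expression or IC50)

    @property
    def direction(self) -> str:
        if np.isnan(self.r):
            return "undefined"
        return "effective_in_high" if self.r < 0 else "ineffective_in_high"


def correlate_drugs(mirna_expr: pd.Series, ic50_table: pd.DataFrame) -> list[DrugCorrelation]:
    """Per-drug Pearson r between expression and log(IC50).

    ``mirna_expr`` is indexed by cell line; ``ic50_table`` is cell line x
    drug with IC50 in concentration units (must be positive; blanks/NaN =
    missing).  Cell lines missing a drug's IC50 are dropped per drug
    (pairwise-complete); drugs with fewer than 3 usable cell lines are
    excluded with a warning, and constant columns yield r = NaN.
    """
    expr = pd.Series(mirna_expr).astype(float)
    ic50 = pd.DataFrame(ic50_table).astype(float)
    finite = ic50.to_numpy()
    if np.any(finite[np.isfinite(finite)] <= 0):
        raise ValueError("IC50 values must be positive")
    common = expr.index.intersection(ic50.index)
    if len(common) < MIN_CELL_LINES:
        raise ValueError(
            f"need >= {MIN_CELL_LINES} cell lines with expression and IC50, got {len(common)}"
        )
    expr = expr.loc[common]
    ic50 = ic50.loc[common]
    out = []
    for drug in ic50.columns:
        y = np.log(ic50[drug])
        mask = y.notna() & expr.notna()
        n = int(mask.sum())
        if n < MIN_CELL_LINES:
            warnings.warn(
                f"drug {drug!r}: only {n} usable cell lines; excluded", stacklevel=2
            )
            continue
        xv = expr[mask].to_numpy()
        yv = y[mask].to_numpy()
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            out.append(DrugCorrelation(str(drug), n, float("nan")))
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        out.append(DrugCorrelation(str(drug), n, r))
    return out


def rank_drugs(
    correlations: list[DrugCorrelation], k: int = 15
) -> tuple[list[DrugCorrelation], list[DrugCorrelation]]:
    """Top-k candidate lists from per-drug correlations.

    Returns ``(top_effective, top_ineffective)``: the k most negative and
    the k most positive correlations (ties broken by drug id); drugs with
    undefined r are excluded.  When fewer than k drugs have negative r the
    effective list is padded with the least-positive remainder, with a
    warning.
    """
    usable = [c for c in correlations if not np.isnan(c.r)]
    asc = sorted(usable, key=lambda c: (c.r, c.drug_id))
    effective = asc[:k]
    if effective and all(c.r >= 0 for c in usable):
        warnings.warn("no negatively correlated drugs; effective list is all r >= 0",
                      stacklevel=2)
    ineffective = sorted(usable, key=lambda c: (-c.r, c.drug_id))[:k]
    return effective, ineffective


def module_score(expr: pd.DataFrame) -> pd.Series:
    """Combined per-cell-line score for a multi-miRNA module.

    Mean of member z-scores across cell lines (rows = miRNA, columns =
    cell lines); robust to members on different expression scales.
    """
    expr = pd.DataFrame(expr).astype(float)
    sd = expr.std(axis=1, ddof=0).replace(0, np.nan)
    z = expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def correlations_to_frame(correlations: list[DrugCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_id": [c.drug_id for c in correlations],
            "n_cell_lines": [c.n_cell_lines_used for c in correlations],
            "r": [c.r for c in correlations],
            "direction": [c.direction for c in correlations],
        }
    ).sort_values(["r", "drug_id"]).reset_index(drop=True)
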