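"""Module-based patient stratification and survival analysis.

Patients are split into two groups by agglomerative clustering of their
module-restricted expression profiles (Manhattan distance, complete
linkage, tree cut at k=2).  Group survival is compared with a Cox
proportional-hazards fit on the binary group indicator: the hazard ratio,
its Wald test, and per-group Kaplan-Meier median survival are reported.
A chi-square test of independence checks whether the split is confounded
with TNM stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency

from .io_preprocess import ExpressionMatrix

__all__ = [
    "StratificationResult",
    "stratify_hierarchical",
    "stratify_mixture_membership",
    "fit_cox",
    "stage_association",
    "ModuleSurvivalModel",
]


@dataclass
class StratificationResult:
    """Two-group survival comparison.

    ``hr`` is the hazard of the second (or "high") group relative to the
    first, with 95% CI and Wald-test p-value; ``median_survival`` maps each
    group label to (median_days, ci_low, ci_high) from the Kaplan-Meier
    estimator (NaN when the curve never crosses 0.5).
    """

    group_labels: pd.Series
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    median_survival: dict
    n_per_group: dict
    reference: str
    comparison: str

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards: {self.comparison} vs {self.reference}",
            f"  HR = {self.hr:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), "
            f"Wald p = {self.wald_p:.3g}",
            f"  group sizes: "
            + ", ".join(f"{g}: {n}" for g, n in self.n_per_group.items()),
        ]
        for g, (med, lo, hi) in self.median_survival.items():
            lines.append(
                f"  median survival [{g}]: {med:.0f} days (95% CI {lo:.0f}-{hi:.0f})"
            )
        return "\n".join(lines)


def _module_matrix(m, module_features) -> pd.DataFrame:
    data = m.data if isinstance(m, ExpressionMatrix) else pd.DataFrame(m)
    missing = [f for f in module_features if f not in data.index]
    if missing:
        raise KeyError(f"module features not in matrix: {missing}")
    return data.loc[list(module_features)]


def stratify_hierarchical(m, module_features, label_high_low: bool = True) -> pd.Series:
    """Cut a Manhattan / complete-linkage dendrogram of samples into 2 groups.

    Clustering acts on samples restricted to the module's features.
    Samples are canonically sorted by id before linkage so the partition
    is invariant to input column order.  With ``label_high_low`` the group
    with the larger mean module expression is labeled "high", the other
    "low"; otherwise labels are "group1"/"group2" in dendrogram order.
    """
    data = _module_matrix(m, module_features)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples to stratify")
    order = np.argsort(data.columns.astype(str), kind="stable")
    x = data.iloc[:, order].T.to_numpy(dtype=float)  # samples x features
    z = linkage(x, method="complete", metric="cityblock")
    groups = fcluster(z, t=2, criterion="maxclust")
    labels = pd.Series(groups, index=data.columns[order].astype(str))
    labels = labels.reindex([str(c) for c in data.columns])
    if label_high_low:
        means = {g: data.T.to_numpy()[labels.to_numpy() == g].mean()
                 for g in (1, 2)}
        high = max(means, key=means.get)
        labels = labels.map(lambda g: "high" if g == high else "low")
    else:
        labels = labels.map(lambda g: f"group{g}")
    labels.name = "group"
    return labels


def stratify_mixture_membership(calls: dict, sample_ids) -> pd.Series:
    """Alternative split: majority high-component membership across a module.

    ``calls`` maps feature id -> per-sample 0/1 component labels (0 = lower
    component) for the module's features, in sample order.  A sample is
    "high" when it sits in the upper component for a majority of the
    module's features.
    """
    mat = np.vstack([np.asarray(v) for v in calls.values()])
    high = mat.mean(axis=0) > 0.5
    return pd.Series(np.where(high, "high", "low"), index=list(sample_ids), name="group")


def fit_cox(group_labels: pd.Series, clinical: pd.DataFrame) -> StratificationResult:
    """Cox PH fit of survival on the binary group indicator.

    ``clinical`` needs columns sample_id, time_days, event (1 = death).
    The reported HR is for the second group ("high" or "group2",
    alphabetically the later label) versus the first.  Raises when a group
    has no events (the partial likelihood is unbounded).
    """
    labels = pd.Series(group_labels)
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    missing = [s for s in labels.index if s not in clin.index]
    if missing:
        raise KeyError(f"samples missing from clinical table: {missing[:5]}")
    clin = clin.loc[labels.index]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    ref, comp = uniq  # e.g. ("group1", "group2") or ("high", "low")
    if uniq == ["high", "low"]:
        ref, comp = "low", "high"  # HR of high vs low
    df = pd.DataFrame(
        {
            "time": clin["time_days"].astype(float),
            "event": clin["event"].astype(int),
            "group": (labels == comp).astype(int).to_numpy(),
        }
    )
    if df["event"].sum() == 0:
        raise ValueError("all samples censored; cannot fit proportional hazards")
    for g, sub in df.groupby("group"):
        if sub["event"].sum() == 0:
            name = comp if g == 1 else ref
            raise ValueError(f"group {name!r} has zero events; fit would not converge")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["group"]
    medians = {}
    for g, name in ((0, ref), (1, comp)):
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        med = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        medians[name] = (med, lo, hi)
    return StratificationResult(
        group_labels=labels,
        hr=float(np.exp(row["coef"])),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        wald_p=float(row["p"]),
        median_survival=medians,
        n_per_group={ref: int((df["group"] == 0).sum()),
                     comp: int((df["group"] == 1).sum())},
        reference=ref,
        comparison=comp,
    )


def stage_association(group_labels: pd.Series, stages: pd.Series):
    """Chi-square independence test of group membership vs TNM stage.

    Stage categories with zero total count are dropped with a warning;
    cells with expected count < 5 are flagged.  No continuity correction.
    Returns (statistic, p_value, contingency table, low_expected flag).
    """
    labels = pd.Series(group_labels)
    stages = pd.Series(stages).reindex(labels.index)
    keep = stages.notna() & (stages != "NA")
    table = pd.crosstab(labels[keep], stages[keep])
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("need at least 2 stage categories with nonzero counts")
    stat, p, _, expected = chi2_contingency(table.to_numpy(), correction=False)
    low_expected = bool((expected < 5).any())
    if low_expected:
        warnings.warn("contingency cells with expected count < 5", stacklevel=2)
    return float(stat), float(p), table, low_expected


class ModuleSurvivalModel:
    """Survival stratification of a cohort by one or more miRNA modules.

    Built from a log2 expression matrix, a clinical table and the module
    feature list; ``fit`` clusters the patients, fits the Cox model and
    returns a :class:`StratificationResult`.
    """

    def __init__(self, expression, clinical: pd.DataFrame, module_features,
                 *, splitter: str = "hierarchical", label_high_low: bool = True):
        if splitter not in ("hierarchical", "mixture"):
            raise ValueError("splitter must be 'hierarchical' or 'mixture'")
        self.expression = expression
        self.clinical = clinical
        self.module_features = list(module_features)
        self.splitter = splitter
        self.label_high_low = label_high_low

    def stratify(self) -> pd.Series:
        if self.splitter == "hierarchical":
            return stratify_hierarchical(
                self.expression, self.module_features, self.label_high_low
            )
        from .mixture import select_model  # local import avoids cycle at module load

        data = _module_matrix(self.expression, self.module_features)
        calls = {}
        for fid in self.module_features:
            verdict = select_model(data.loc[fid].to_numpy(dtype=float))
            calls[fid] = verdict.fit.assignments
        return stratify_mixture_membership(calls, data.columns.astype(str))

    def fit(self) -> StratificationResult:
        return fit_cox(self.stratify(), self.clinical)

    def plot_km(self, result: StratificationResult | None = None, ax=None):
        """Kaplan-Meier curves per group (matplotlib Axes returned)."""
        import matplotlib.pyplot as plt

        result = result or self.fit()
        clin = self.clinical.set_index("sample_id") \
            if "sample_id" in self.clinical.columns else self.clinical
        if ax is None:
            _, ax = plt.subplots()
        for g in result.n_per_group:
            idx = result.group_labels[result.group_labels == g].index
            sub = clin.loc[idx]
            kmf = KaplanMeierFitter()
            kmf.fit(sub["time_days"], sub["event"], label=str(g))
            kmf.plot_survival_function(ax=ax)
        ax.set_xlabel("days")
        ax.set_ylabel("survival probability")
        return ax
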