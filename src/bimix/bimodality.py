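"""Bimodality index, control-cohort penalties and the CM / MM pipelines.

The bimodality index (BI) of a two-component Gaussian fit with ordered
means is

    BI = sqrt(pi1 * pi2) * (mu2 - mu1) / sqrt(pi2 * sigma1**2 + pi1 * sigma2**2)

which reduces to the classical sqrt(pi*(1-pi)) * |dmu| / sigma when the
component SDs are equal.  Controlled mixture modeling (CM) scores each
tumor feature with BI and, when the matched control cohort is itself
bimodal, penalizes the score by the inverse distance between tumor and
control component parameters:

    BI_mu_penalty = BI - 1 / (|mu1C - mu1T| + |mu2C - mu2T|)
    BI_pi_penalty = BI - 1 / (|pi1C - pi1T| + |pi2C - pi2T|)

The larger of the two penalized values is the final BI (clamped at 0).
A feature with identical tumor and control distributions therefore scores
0 — the defining behavior that removes population-level bimodality
(immunoglobulin-like features) from the candidate list.  MM is the
uncontrolled variant: mixture model + k-means + BI on tumor samples only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix
from .mixture import (
    PI_MIN_DEFAULT,
    DegenerateClusterError,
    MixtureFit,
    ModalityVerdict,
    kmeans_recluster,
    select_model,
)

__all__ = [
    "BimodalCall",
    "bimodality_index",
    "penalized_bi",
    "cm_score",
    "mm_score",
    "rank_features",
    "threshold_counts",
    "simulate_fpr",
    "ControlledMixtureModel",
    "BimodalityResults",
]

DEFAULT_BI_THRESHOLD = 1.4
_REPORT_THRESHOLDS = (0.0, 1.0, 1.2, 1.3, 1.4, 1.5)


def bimodality_index(
    pi1: float, pi2: float, mu1: float, mu2: float, sigma1: float, sigma2: float
) -> float:
    """Bimodality index of a two-component fit with mean-ordered components."""
    if not (0.0 < pi1 < 1.0 and 0.0 < pi2 < 1.0):
        raise ValueError("mixing proportions must lie strictly in (0, 1)")
    if abs(pi1 + pi2 - 1.0) > 1e-9:
        raise ValueError("mixing proportions must sum to 1")
    if mu1 > mu2:
        raise ValueError("components must be ordered (mu1 <= mu2)")
    if sigma1 <= 0.0 or sigma2 <= 0.0:
        raise ValueError("component SDs must be positive")
    if mu1 == mu2:
        return 0.0
    denom = math.sqrt(pi2 * sigma1**2 + pi1 * sigma2**2)
    return math.sqrt(pi1 * pi2) * (mu2 - mu1) / denom


def _bi_of(fit: MixtureFit) -> float:
    return bimodality_index(fit.pi1, fit.pi2, fit.mu1, fit.mu2, fit.sigma1, fit.sigma2)


def penalized_bi(
    bi_raw: float, tumor: MixtureFit, control: MixtureFit
) -> tuple[float, float, float]:
    """Control-cohort penalties and the final (clamped) bimodality index.

    Returns ``(bi_mu_penalty, bi_pi_penalty, bi_final)``.  A zero distance
    sum makes that penalty fully punitive (-inf, i.e. contributes 0 to the
    clamped final score); the final score is the max of the two penalized
    values, clamped at 0.
    """
    for fit in (tumor, control):
        if fit.k != 2:
            raise ValueError("penalty requires two-component fits for both cohorts")
        if fit.mu1 > fit.mu2:
            raise ValueError("components must be mean-ordered")
    mu_dist = abs(control.mu1 - tumor.mu1) + abs(control.mu2 - tumor.mu2)
    pi_dist = abs(control.pi1 - tumor.pi1) + abs(control.pi2 - tumor.pi2)
    bi_mu = bi_raw - 1.0 / mu_dist if mu_dist > 0 else -math.inf
    bi_pi = bi_raw - 1.0 / pi_dist if pi_dist > 0 else -math.inf
    bi_final = max(0.0, bi_mu, bi_pi)
    return bi_mu, bi_pi, bi_final


@dataclass
class BimodalCall:
    """Per-feature outcome of the CM or MM pipeline."""

    feature_id: str
    tumor_verdict: ModalityVerdict
    bi_raw: float = 0.0
    bi_final: float = 0.0
    penalized: bool = False
    control_verdict: ModalityVerdict | None = None
    bi_mu_penalty: float | None = None
    bi_pi_penalty: float | None = None
    tumor_kmeans: MixtureFit | None = None
    control_kmeans: MixtureFit | None = None
    mode: str = "cm"


def _score_fit(verdict: ModalityVerdict, values: np.ndarray, bi_source: str):
    """k-means re-clustering + the fit BI is computed from. Returns (km, fit)."""
    km = kmeans_recluster(values)
    fit = km if bi_source == "kmeans" else verdict.fit
    return km, fit


def mm_score(
    tumor_values: np.ndarray,
    seed: int | None = None,
    feature_id: str = "",
    bi_source: str = "kmeans",
    pi_min: float = PI_MIN_DEFAULT,
) -> BimodalCall:
    """Uncontrolled pipeline: BIC selection, proportion constraint, k-means, BI.

    Tumor-unimodal and proportion-excluded features score 0 so every input
    feature yields one output row.  A degenerate k-means cluster (fewer
    than 2 members, an extreme-outlier split) is likewise scored 0.
    """
    tumor_values = np.asarray(tumor_values, dtype=float)
    verdict = select_model(tumor_values, seed, pi_min=pi_min)
    call = BimodalCall(feature_id=feature_id, tumor_verdict=verdict, mode="mm")
    if verdict.modality != "bimodal":
        return call
    try:
        km, fit = _score_fit(verdict, tumor_values, bi_source)
    except DegenerateClusterError:
        return call
    call.tumor_kmeans = km
    call.bi_raw = _bi_of(fit)
    call.bi_final = call.bi_raw
    return call


def cm_score(
    tumor_values: np.ndarray,
    control_values: np.ndarray,
    seed: int | None = None,
    feature_id: str = "",
    bi_source: str = "kmeans",
    pi_min: float = PI_MIN_DEFAULT,
) -> BimodalCall:
    """Controlled pipeline: MM on tumor, penalized when control is bimodal.

    Decision tree: select the tumor model; unimodal / proportion-excluded
    features score 0.  Otherwise re-cluster the tumor, select the control
    model; a unimodal (or proportion-excluded) control leaves the BI
    unpenalized, a bimodal control is re-clustered and the two penalties
    are applied with the larger (clamped at 0) as the final score.
    """
    call = mm_score(tumor_values, seed, feature_id, bi_source, pi_min)
    call.mode = "cm"
    if call.tumor_verdict.modality != "bimodal" or call.tumor_kmeans is None:
        return call
    control_values = np.asarray(control_values, dtype=float)
    cv = select_model(control_values, seed, pi_min=pi_min)
    call.control_verdict = cv
    if cv.modality != "bimodal":
        return call  # unpenalized: bi_final == bi_raw
    try:
        ckm, cfit = _score_fit(cv, control_values, bi_source)
    except DegenerateClusterError:
        return call
    call.control_kmeans = ckm
    tfit = call.tumor_kmeans if bi_source == "kmeans" else call.tumor_verdict.fit
    bi_mu, bi_pi, bi_final = penalized_bi(call.bi_raw, tfit, cfit)
    call.bi_mu_penalty = bi_mu
    call.bi_pi_penalty = bi_pi
    call.bi_final = bi_final
    call.penalized = True
    return call


def _calls_frame(calls: list[BimodalCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        tf = c.tumor_kmeans or c.tumor_verdict.fit
        row = {
            "feature_id": c.feature_id,
            "tumor_verdict": c.tumor_verdict.modality,
            "control_verdict": c.control_verdict.modality if c.control_verdict else "",
            "mu1": tf.mu1, "mu2": tf.mu2, "sigma1": tf.sigma1, "sigma2": tf.sigma2,
            "pi1": tf.pi1, "pi2": tf.pi2,
            "bic1": c.tumor_verdict.bic1, "bic2": c.tumor_verdict.bic2,
            "bi_raw": c.bi_raw,
            "bi_mu_penalty": c.bi_mu_penalty,
            "bi_pi_penalty": c.bi_pi_penalty,
            "bi_final": c.bi_final,
            "penalized": c.penalized,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def rank_features(calls: list[BimodalCall], bi_threshold: float = DEFAULT_BI_THRESHOLD) -> pd.DataFrame:
    """Rank calls by final BI (descending, ties broken by feature id).

    Adds a ``passes`` column for ``bi_final > bi_threshold``; the ranking
    is what downstream module detection consumes.
    """
    frame = _calls_frame(calls)
    if frame.empty:
        return frame
    frame = frame.sort_values(
        ["bi_final", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame["passes"] = frame["bi_final"] > bi_threshold
    return frame


def threshold_counts(
    calls: list[BimodalCall], thresholds=_REPORT_THRESHOLDS
) -> pd.Series:
    """Number of features with final BI above each threshold."""
    bi = np.array([c.bi_final for c in calls])
    return pd.Series(
        {f"BI > {t:g}": int((bi > t).sum()) for t in thresholds}, name="n_features"
    )


class ControlledMixtureModel:
    """Bimodality model for a tumor cohort with an optional control cohort.

    Parameters
    ----------
    tumor : ExpressionMatrix or pandas.DataFrame
        log2-scale feature x sample matrix of the tumor cohort.
    control : ExpressionMatrix or pandas.DataFrame, optional
        Matched control cohort (same features).  When given, the fitted
        scores follow the CM pipeline; otherwise the MM pipeline.
    bi_source : {"kmeans", "em"}
        Whether the BI (and the penalties) use the k-means re-clustering
        parameters or the raw EM parameters.
    pi_min : float
        Minor-proportion constraint; two-component fits with
        min(pi) <= pi_min are excluded as outlier-driven.
    """

    def __init__(self, tumor, control=None, *, bi_source: str = "kmeans",
                 pi_min: float = PI_MIN_DEFAULT):
        if bi_source not in ("kmeans", "em"):
            raise ValueError("bi_source must be 'kmeans' or 'em'")
        self.tumor = self._coerce(tumor, "tumor")
        self.control = self._coerce(control, "control") if control is not None else None
        if self.control is not None:
            missing = set(self.tumor.feature_ids) - set(self.control.feature_ids)
            if missing:
                raise ValueError(f"features missing from control cohort: {sorted(missing)[:5]}")
        self.bi_source = bi_source
        self.pi_min = pi_min

    @staticmethod
    def _coerce(m, cohort: str) -> ExpressionMatrix:
        if isinstance(m, ExpressionMatrix):
            return m
        return ExpressionMatrix(pd.DataFrame(m), cohort=cohort, scale="log2")

    @property
    def mode(self) -> str:
        return "cm" if self.control is not None else "mm"

    def fit(self, seed: int | None = None) -> "BimodalityResults":
        """Score every feature; returns a :class:`BimodalityResults`."""
        calls = []
        for fid in self.tumor.feature_ids:
            tv = self.tumor.feature(fid)
            if self.control is not None:
                call = cm_score(tv, self.control.feature(fid), seed, fid,
                                self.bi_source, self.pi_min)
            else:
                call = mm_score(tv, seed, fid, self.bi_source, self.pi_min)
            calls.append(call)
        return BimodalityResults(self, calls)


class BimodalityResults:
    """Per-feature CM/MM calls with ranking and summary helpers."""

    def __init__(self, model: ControlledMixtureModel, calls: list[BimodalCall]):
        self.model = model
        self.calls = calls

    @property
    def frame(self) -> pd.DataFrame:
        return _calls_frame(self.calls)

    def ranked(self, bi_threshold: float = DEFAULT_BI_THRESHOLD) -> pd.DataFrame:
        return rank_features(self.calls, bi_threshold)

    def threshold_counts(self, thresholds=_REPORT_THRESHOLDS) -> pd.Series:
        return threshold_counts(self.calls, thresholds)

    def bimodal_features(self, bi_threshold: float = DEFAULT_BI_THRESHOLD) -> list[str]:
        return sorted(c.feature_id for c in self.calls if c.bi_final > bi_threshold)

    def summary(self, bi_threshold: float = DEFAULT_BI_THRESHOLD) -> str:
        counts = self.threshold_counts()
        lines = [
            f"{self.model.mode.upper()} bimodality scan: "
            f"{len(self.calls)} features, {self.model.tumor.n_samples} tumor samples"
            + (f", {self.model.control.n_samples} control samples"
               if self.model.control is not None else ""),
            "",
            counts.to_string(),
            "",
            f"features with BI > {bi_threshold:g}: "
            f"{len(self.bimodal_features(bi_threshold))}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.ranked().to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_fpr(
    n_samples: int,
    n_features: int,
    bi_threshold: float = DEFAULT_BI_THRESHOLD,
    seed: int = 0,
    pipeline: str = "mm",
    control_n: int | None = None,
) -> float:
    """False-positive rate of the pipeline on purely unimodal features.

    Draws ``n_features`` independent standard-normal features of length
    ``n_samples`` (CM mode also draws unimodal control features, of length
    ``control_n`` or ``n_samples``) and returns the fraction scored above
    ``bi_threshold``.  The BI is location/scale invariant, so the standard
    normal is fully general for the null.
    """
    if pipeline not in ("cm", "mm"):
        raise ValueError("pipeline must be 'cm' or 'mm'")
    rng = np.random.default_rng(seed)
    n_hits = 0
    cn = control_n or n_samples
    for i in range(n_features):
        x = rng.standard_normal(n_samples)
        if pipeline == "cm":
            c = rng.standard_normal(cn)
            call = cm_score(x, c, feature_id=str(i))
        else:
            call = mm_score(x, feature_id=str(i))
        if call.bi_final > bi_threshold:
            n_hits += 1
    return n_hits / n_features
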