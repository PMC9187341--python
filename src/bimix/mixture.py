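"""Per-feature Gaussian mixture fitting, BIC model selection and 1-D k-means.

Each feature's log2-expression vector is fit with a one-component Gaussian
(closed-form MLE) and a two-component Gaussian mixture (EM from multiple
deterministic starts).  The Bayesian information criterion decides between
the two; two-component winners whose minor mixing proportion is at or below
``pi_min`` (default 0.1) are excluded as outlier-driven rather than
genuinely bimodal.  Features judged bimodal are re-clustered with k-means
(k=2); in one dimension the optimal 2-means partition is a contiguous split
of the sorted values, so the split is found exactly by scanning all
split points instead of running Lloyd iterations from a heuristic start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._em import _em_k2_restarts, _loglik_k1, _posterior_k2

__all__ = [
    "MixtureFit",
    "ModalityVerdict",
    "DegenerateDataError",
    "DegenerateClusterError",
    "fit_em",
    "select_model",
    "kmeans_recluster",
    "optimal_split_labels",
]

EM_TOL = 1e-8
EM_MAX_ITER = 500
N_RESTARTS = 10
PI_MIN_DEFAULT = 0.1
_VAR_FLOOR_SCALE = 1e-4
_VAR_FLOOR_EPS = 1e-8


class DegenerateDataError(ValueError):
    """Two-component fit requested on data with no spread."""


class DegenerateClusterError(ValueError):
    """A k-means cluster has fewer than 2 members; its SD is undefined."""


@dataclass
class MixtureFit:
    """Fitted parameters of a one- or two-component Gaussian model.

    Components are ordered by mean (``mu1 <= mu2``); sigmas are standard
    deviations with a data-dependent floor.  ``assignments`` are hard
    per-sample component labels (0 = lower-mean component).
    """

    k: int
    mu1: float
    sigma1: float
    pi1: float
    loglik: float
    bic: float
    assignments: np.ndarray
    method: str = "em"
    mu2: float | None = None
    sigma2: float | None = None
    pi2: float | None = None

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if self.k == 2:
            if self.mu2 is None or self.sigma2 is None or self.pi2 is None:
                raise ValueError("two-component fit requires mu2/sigma2/pi2")
            if self.mu1 > self.mu2 + 1e-12:
                raise ValueError("components must be ordered by mean (mu1 <= mu2)")
            if abs(self.pi1 + self.pi2 - 1.0) > 1e-9:
                raise ValueError("mixing proportions must sum to 1")

    @property
    def means(self) -> tuple[float, ...]:
        return (self.mu1,) if self.k == 1 else (self.mu1, self.mu2)


@dataclass
class ModalityVerdict:
    """Model-selection outcome for one feature.

    ``modality`` is "unimodal" (one component won), "bimodal" (two
    components won and both proportions exceed the constraint), or
    "excluded_proportion" (two components won but the minor proportion was
    <= pi_min, i.e. a handful of outliers rather than a second mode).
    """

    modality: str
    fit: MixtureFit
    bic1: float = float("nan")
    bic2: float = float("nan")

    def __post_init__(self) -> None:
        if self.modality not in ("unimodal", "bimodal", "excluded_proportion"):
            raise ValueError(f"unknown modality {self.modality!r}")


def _var_floor(x: np.ndarray) -> float:
    return _VAR_FLOOR_SCALE * (float(np.var(x)) + _VAR_FLOOR_EPS)


def _check_values(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("mixture fitting requires at least 10 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return x


def _k2_inits(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic restart grid: 9 quantile splits + the optimal 2-means split."""
    n = x.size
    xs = np.sort(x)
    mu_init = np.empty((N_RESTARTS, 2))
    var_init = np.empty((N_RESTARTS, 2))
    pi_init = np.empty(N_RESTARTS)
    floor = _var_floor(x)
    qs = np.linspace(0.1, 0.9, N_RESTARTS - 1)
    for r, q in enumerate(qs):
        cut = min(max(int(round(q * n)), 1), n - 1)
        lo, hi = xs[:cut], xs[cut:]
        mu_init[r] = (lo.mean(), hi.mean())
        var_init[r] = (max(lo.var(), floor), max(hi.var(), floor))
        pi_init[r] = cut / n
    labels = optimal_split_labels(x)
    lo, hi = x[labels == 0], x[labels == 1]
    mu_init[-1] = (lo.mean(), hi.mean())
    var_init[-1] = (max(lo.var(), floor), max(hi.var(), floor))
    pi_init[-1] = lo.size / n
    return mu_init, var_init, pi_init


def fit_em(
    x: np.ndarray, k: int, seed: int | None = None, equal_var: bool = False
) -> MixtureFit:
    """Maximum-likelihood Gaussian (mixture) fit for one feature.

    ``k=1`` is the closed-form MLE.  ``k=2`` runs EM from a deterministic
    grid of restarts (quantile splits and the exact 1-D 2-means split) and
    keeps the best log-likelihood; the ``seed`` argument is accepted for
    interface uniformity but initialization is deterministic, so results
    do not depend on it.

    By default each component carries its own variance (floored at a small
    fraction of the data variance, since the unconstrained mixture
    likelihood is unbounded); near-singular solutions that hug a handful of
    points surface as a tiny mixing proportion and are screened out
    downstream by the proportion constraint.  ``equal_var=True`` shares one
    variance across components (the mclust "E" model), which removes the
    collapse pathology structurally.

    BIC = -2*loglik + p*ln(n), with p=2 for k=1 and p=5 (per-component
    variances: two means, two variances, one free proportion) or p=4
    (shared variance) for k=2.
    """
    x = _check_values(x)
    n = x.size
    floor = _var_floor(x)
    if k == 1:
        mu = float(x.mean())
        var = max(float(x.var()), floor)  # MLE variance (denominator n)
        ll = float(_loglik_k1(x, mu, var))
        bic = -2.0 * ll + 2.0 * np.log(n)
        return MixtureFit(
            k=1, mu1=mu, sigma1=float(np.sqrt(var)), pi1=1.0,
            loglik=ll, bic=bic, assignments=np.zeros(n, dtype=np.int64),
        )
    if k != 2:
        raise ValueError("k must be 1 or 2")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all values identical; two-component fit is degenerate")
    mu_init, var_init, pi_init = _k2_inits(x)
    mu1, mu2, v1, v2, p1, ll, mono_ok = _em_k2_restarts(
        x, mu_init, var_init, pi_init, floor, EM_TOL, EM_MAX_ITER, equal_var
    )
    if not mono_ok:
        raise RuntimeError("EM log-likelihood decreased beyond tolerance")
    n_params = 4.0 if equal_var else 5.0
    bic = -2.0 * ll + n_params * np.log(n)
    assignments = _posterior_k2(x, mu1, mu2, v1, v2, p1)
    return MixtureFit(
        k=2, mu1=float(mu1), mu2=float(mu2),
        sigma1=float(np.sqrt(v1)), sigma2=float(np.sqrt(v2)),
        pi1=float(p1), pi2=float(1.0 - p1),
        loglik=float(ll), bic=float(bic), assignments=np.asarray(assignments),
    )


def select_model(
    x: np.ndarray,
    seed: int | None = None,
    pi_min: float = PI_MIN_DEFAULT,
    equal_var: bool = False,
) -> ModalityVerdict:
    """Choose between one- and two-component models by BIC.

    Lower BIC wins.  When the two-component model wins but its minor
    proportion is <= ``pi_min``, the feature is excluded as proportion-
    constrained (``excluded_proportion``) rather than called bimodal.
    """
    x = _check_values(x)
    fit1 = fit_em(x, 1, seed)
    if np.ptp(x) == 0.0:
        return ModalityVerdict("unimodal", fit1, bic1=fit1.bic, bic2=float("inf"))
    fit2 = fit_em(x, 2, seed, equal_var=equal_var)
    if fit2.bic < fit1.bic:
        if min(fit2.pi1, fit2.pi2) <= pi_min:
            return ModalityVerdict("excluded_proportion", fit2, fit1.bic, fit2.bic)
        return ModalityVerdict("bimodal", fit2, fit1.bic, fit2.bic)
    return ModalityVerdict("unimodal", fit1, fit1.bic, fit2.bic)


def optimal_split_labels(x: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means partition as 0/1 labels (0 = lower-mean cluster).

    The optimal two-cluster k-means solution in one dimension is a
    contiguous split of the sorted values; the split minimizing total
    within-cluster SSE is found by a prefix-sum scan.  SSE ties are broken
    toward the larger lower cluster, i.e. boundary points join the
    lower-mean cluster.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values to split")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c = np.cumsum(xs)
    c2 = np.cumsum(xs * xs)
    total, total2 = c[-1], c2[-1]
    i = np.arange(1, n)  # lower-cluster sizes
    sse_lo = c2[:-1] - c[:-1] ** 2 / i
    sse_hi = (total2 - c2[:-1]) - (total - c[:-1]) ** 2 / (n - i)
    sse = sse_lo + sse_hi
    # ties -> largest split index (boundary values go to the lower cluster)
    m = sse.min()
    best = int(np.flatnonzero(sse <= m + 1e-12 * (1.0 + abs(m)))[-1]) + 1
    labels = np.empty(n, dtype=np.int64)
    labels[order[:best]] = 0
    labels[order[best:]] = 1
    return labels


def kmeans_recluster(x: np.ndarray, pi_min: float | None = None) -> MixtureFit:
    """Re-cluster a bimodal feature with exact 1-D k-means (k=2).

    Per-cluster sample mean, sample SD (n-1 denominator, floored) and
    proportion are reported as (mu, sigma, pi), clusters ordered by mean.
    A cluster with fewer than 2 members raises
    :class:`DegenerateClusterError` since its SD is undefined.
    """
    x = np.asarray(x, dtype=float).ravel()
    labels = optimal_split_labels(x)
    lo, hi = x[labels == 0], x[labels == 1]
    if lo.size < 2 or hi.size < 2:
        raise DegenerateClusterError(
            f"degenerate k-means cluster (sizes {lo.size}, {hi.size})"
        )
    floor_sd = float(np.sqrt(_var_floor(x)))
    mu1, mu2 = float(lo.mean()), float(hi.mean())
    s1 = max(float(lo.std(ddof=1)), floor_sd)
    s2 = max(float(hi.std(ddof=1)), floor_sd)
    p1 = lo.size / x.size
    return MixtureFit(
        k=2, mu1=mu1, mu2=mu2, sigma1=s1, sigma2=s2,
        pi1=p1, pi2=1.0 - p1, loglik=float("nan"), bic=float("nan"),
        assignments=labels, method="kmeans",
    )
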