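"""Synthetic tumor/control cohorts with planted ground truth.

Expression is generated directly on the log2 scale as draws from one- or
two-component Gaussians per feature, clipped at 0 (log2(raw + 1) is
non-negative); a raw-scale export applies 2**x - 1 so the preprocessing
log transform round-trips.  Four archetypes cover
the study conditions:

- ``unimodal``: one Gaussian in both cohorts (the null),
- ``tumor_bimodal``: two components in tumor, one in control (the signal
  the controlled pipeline should call),
- ``shared_bimodal``: the same two components in both cohorts (population
  bimodality the control penalty should suppress),
- ``low_expressed``: near-all-zero values that exercise the
  low-expression filter.

Survival times are exponential, with membership in the planted upper
component multiplying the hazard by a configurable ratio — the simplest
family in which the true Cox hazard ratio equals the configured
multiplier.  Censoring is independent exponential with its rate solved so
the expected censored fraction matches ``censor_rate``.  The drug panel
plants a target population correlation between per-cell-line expression
and log(IC50) via a linear Gaussian construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_preprocess import ExpressionMatrix, inverse_log2

__all__ = [
    "FeatureSpec",
    "CohortConfig",
    "ConfigError",
    "generate_cohort",
    "generate_clinical",
    "generate_drug_panel",
    "standard_config",
    "write_bundle",
]

ARCHETYPES = ("unimodal", "tumor_bimodal", "shared_bimodal", "low_expressed")
STAGES = ("I", "II", "III", "IV")
STAGE_PROBS = (0.30, 0.30, 0.25, 0.15)
STAGE_PROBS_LATE = (0.10, 0.20, 0.30, 0.40)  # used when stage_coupling > 0
BASELINE_HAZARD_PER_DAY = 1.0 / 1000.0
LOW_EXPRESSED_ZERO_FRAC = 0.97


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class FeatureSpec:
    """Generative parameters for one feature (log2 scale).

    ``mu1 <= mu2`` are component means, ``sigma1``/``sigma2`` their SDs and
    ``pi1`` the lower component's mixing proportion in the tumor cohort.
    ``control_params`` optionally overrides the control cohort with its own
    (mu1, mu2, sigma1, sigma2, pi1) tuple; by default the control is
    unimodal at (mu1, sigma1) for ``tumor_bimodal`` features and shares the
    tumor mixture for ``shared_bimodal`` features.

    Bimodal features carrying the same ``subgroup`` id share one
    per-sample component membership (drawn once per subgroup), which makes
    them concurrently expressed — the ground truth for co-expression
    module detection.  ``subgroup=None`` draws membership independently.
    """

    feature_id: str
    archetype: str
    mu1: float = 0.0
    mu2: float = 0.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    pi1: float = 0.5
    control_params: tuple | None = None
    subgroup: int | None = None

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ConfigError(f"unknown archetype {self.archetype!r}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ConfigError(f"{self.feature_id}: sigmas must be positive")
        if not (0.0 < self.pi1 < 1.0):
            raise ConfigError(f"{self.feature_id}: pi1 must lie in (0, 1)")
        if self.mu1 > self.mu2:
            raise ConfigError(f"{self.feature_id}: means must be ordered (mu1 <= mu2)")
        if self.archetype == "unimodal" and self.mu1 != self.mu2:
            raise ConfigError(f"{self.feature_id}: unimodal requires mu1 == mu2")
        if self.control_params is not None and len(self.control_params) != 5:
            raise ConfigError(
                f"{self.feature_id}: control_params must be (mu1, mu2, sigma1, sigma2, pi1)"
            )


@dataclass
class CohortConfig:
    """Full study configuration; the seed determines every output."""

    n_tumor: int
    n_control: int
    feature_specs: list
    hazard_ratio: float = 2.0
    censor_rate: float = 0.2
    stage_coupling: float = 0.0
    drug_panel: list = field(default_factory=list)  # (drug_id, target_corr)
    seed: int = 0

    def __post_init__(self):
        if self.n_control > self.n_tumor:
            raise ConfigError("n_control must not exceed n_tumor")
        if self.n_tumor < 1 or self.n_control < 1:
            raise ConfigError("cohort sizes must be positive")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ConfigError("censor_rate must lie in [0, 1)")
        if not (0.0 <= self.stage_coupling <= 1.0):
            raise ConfigError("stage_coupling must lie in [0, 1]")
        for drug_id, rho in self.drug_panel:
            if abs(rho) > 1.0:
                raise ConfigError(f"drug {drug_id!r}: |target_corr| must be <= 1")
        ids = [s.feature_id for s in self.feature_specs]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate feature ids in feature_specs")


def _draw_mixture(rng, n, mu1, mu2, s1, s2, pi1, subgroup=None, cache=None):
    """Draw n values and 0/1 component labels from a two-component Gaussian.

    When ``subgroup`` is given, the labels are drawn once per subgroup and
    reused for every feature in it (concurrent expression).
    """
    if subgroup is not None and cache is not None and subgroup in cache:
        labels = cache[subgroup]
    else:
        labels = (rng.random(n) >= pi1).astype(np.int64)  # 1 = upper component
        if subgroup is not None and cache is not None:
            cache[subgroup] = labels
    mu = np.where(labels == 0, mu1, mu2)
    sd = np.where(labels == 0, s1, s2)
    return rng.normal(mu, sd), labels


def generate_cohort(config: CohortConfig):
    """Generate tumor and control matrices (log2 scale) plus ground truth.

    Returns ``(tumor, control, truth)`` where truth records per-feature
    archetypes, per-sample component membership for bimodal features, and
    the "driver" membership vector (first bimodal-in-tumor feature) that
    the clinical generator couples to survival.
    """
    rng = np.random.default_rng([config.seed, 0])
    nt, nc = config.n_tumor, config.n_control
    tumor_samples = [f"T{i:04d}" for i in range(nt)]
    control_samples = [f"C{i:04d}" for i in range(nc)]
    t_rows, c_rows = [], []
    truth = {
        "archetypes": {},
        "tumor_membership": {},
        "control_membership": {},
        "driver_feature": None,
        "driver_membership": None,
        "tumor_samples": tumor_samples,
        "control_samples": control_samples,
    }
    t_cache: dict = {}
    c_cache: dict = {}
    for spec in config.feature_specs:
        truth["archetypes"][spec.feature_id] = spec.archetype
        if spec.archetype == "unimodal":
            tv = rng.normal(spec.mu1, spec.sigma1, nt)
            if spec.control_params is not None:
                cm1, _, cs1, _, _ = spec.control_params
            else:
                cm1, cs1 = spec.mu1, spec.sigma1
            cv = rng.normal(cm1, cs1, nc)
        elif spec.archetype == "tumor_bimodal":
            tv, lab = _draw_mixture(
                rng, nt, spec.mu1, spec.mu2, spec.sigma1, spec.sigma2, spec.pi1,
                spec.subgroup, t_cache,
            )
            truth["tumor_membership"][spec.feature_id] = lab.tolist()
            if spec.control_params is not None:
                cm1, _, cs1, _, _ = spec.control_params
            else:
                cm1, cs1 = spec.mu1, spec.sigma1  # controls sit in the low mode
            cv = rng.normal(cm1, cs1, nc)
        elif spec.archetype == "shared_bimodal":
            tv, lab = _draw_mixture(
                rng, nt, spec.mu1, spec.mu2, spec.sigma1, spec.sigma2, spec.pi1,
                spec.subgroup, t_cache,
            )
            truth["tumor_membership"][spec.feature_id] = lab.tolist()
            cp = spec.control_params or (
                spec.mu1, spec.mu2, spec.sigma1, spec.sigma2, spec.pi1
            )
            cv, clab = _draw_mixture(
                rng, nc, *cp,
                subgroup=None if spec.subgroup is None else -1 - spec.subgroup,
                cache=c_cache,
            )
            truth["control_membership"][spec.feature_id] = clab.tolist()
        else:  # low_expressed
            tv = _low_expressed(rng, nt)
            cv = _low_expressed(rng, nc)
        # log2(raw + 1) is non-negative by construction; clip stray draws at 0
        t_rows.append(np.maximum(tv, 0.0))
        c_rows.append(np.maximum(cv, 0.0))
    ids = [s.feature_id for s in config.feature_specs]
    tumor = ExpressionMatrix(
        pd.DataFrame(np.array(t_rows) if t_rows else np.empty((0, nt)),
                     index=ids, columns=tumor_samples),
        cohort="tumor", scale="log2",
    )
    control = ExpressionMatrix(
        pd.DataFrame(np.array(c_rows) if c_rows else np.empty((0, nc)),
                     index=ids, columns=control_samples),
        cohort="control", scale="log2",
    )
    for spec in config.feature_specs:
        if spec.archetype in ("tumor_bimodal", "shared_bimodal"):
            truth["driver_feature"] = spec.feature_id
            truth["driver_membership"] = truth["tumor_membership"][spec.feature_id]
            break
    if truth["driver_membership"] is None:
        truth["driver_membership"] = [0] * nt
    return tumor, control, truth


def _low_expressed(rng, n):
    x = np.abs(rng.normal(0.8, 0.4, n))
    zero = rng.random(n) < LOW_EXPRESSED_ZERO_FRAC
    x[zero] = 0.0
    return x


def _censor_rate_for(rate_c, hazards, target):
    return float(np.mean(rate_c / (hazards + rate_c))) - target


def generate_clinical(truth: dict, config: CohortConfig) -> pd.DataFrame:
    """Clinical table (sample_id, time_days, event, stage, sex) for the tumor cohort.

    Survival is exponential with per-day baseline hazard 1/1000; samples in
    the planted upper component have their hazard multiplied by
    ``config.hazard_ratio``.  Censoring is independent exponential with its
    rate solved so the expected censored fraction equals ``censor_rate``;
    the recorded time is min(event, censoring) with event = 1 when death
    is observed.  Stage is categorical and independent of expression
    unless ``stage_coupling > 0``, which shifts upper-component samples
    toward later stages.
    """
    if config.hazard_ratio <= 0:
        raise ConfigError("hazard_ratio must be positive")
    rng = np.random.default_rng([config.seed, 1])
    membership = np.asarray(truth["driver_membership"], dtype=int)
    samples = list(truth["tumor_samples"])
    if len(membership) != len(samples):
        raise ConfigError("driver membership does not cover all tumor samples")
    hazards = BASELINE_HAZARD_PER_DAY * np.where(membership == 1, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        lam_c = brentq(
            _censor_rate_for, 1e-12, 1e3, args=(hazards, config.censor_rate)
        )
        t_cens = rng.exponential(1.0 / lam_c, size=len(samples))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(samples), dtype=int)
        time = t_event
    probs = np.array(STAGE_PROBS)
    late = np.array(STAGE_PROBS_LATE)
    stage = np.empty(len(samples), dtype=object)
    for i in range(len(samples)):
        p = probs
        if config.stage_coupling > 0 and membership[i] == 1:
            p = (1 - config.stage_coupling) * probs + config.stage_coupling * late
        stage[i] = rng.choice(STAGES, p=p / p.sum())
    sex = rng.choice(["F", "M"], size=len(samples))
    return pd.DataFrame(
        {
            "sample_id": samples,
            "time_days": np.round(time, 2),
            "event": event,
            "stage": stage,
            "sex": sex,
        }
    )


def generate_drug_panel(config: CohortConfig, n_cell_lines: int = 13):
    """Cell-line expression vector and IC50 table with planted correlations.

    For each (drug, target_corr) in ``config.drug_panel``, log(IC50) is
    rho * z + sqrt(1 - rho**2) * noise with z the standardized expression,
    so the population correlation equals the target exactly (and the draw
    is deterministic with |rho| = 1).  IC50 is exp of that value (a
    micromolar-scale lognormal).
    """
    if n_cell_lines < 3:
        raise ConfigError("need at least 3 cell lines")
    for _, rho in config.drug_panel:
        if abs(rho) > 1:
            raise ConfigError("|target_corr| must be <= 1")
    rng = np.random.default_rng([config.seed, 2])
    lines = [f"CL{i:02d}" for i in range(n_cell_lines)]
    expr = rng.normal(5.0, 1.5, n_cell_lines)
    z = (expr - expr.mean()) / expr.std()
    ic50 = {}
    for drug_id, rho in config.drug_panel:
        noise = rng.standard_normal(n_cell_lines)
        log_ic50 = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        ic50[drug_id] = np.exp(log_ic50)
    expr_s = pd.Series(expr, index=lines, name="expression")
    ic50_df = pd.DataFrame(ic50, index=lines)
    return expr_s, ic50_df


def standard_config(
    seed: int = 0,
    n_tumor: int = 300,
    n_control: int = 50,
    n_unimodal: int = 50,
    n_tumor_bimodal: int = 25,
    n_shared_bimodal: int = 25,
    n_low_expressed: int = 0,
    mu_low: float = 2.0,
    mu_high: float = 8.0,
    sigma: float = 1.0,
    pi1: float = 0.5,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.2,
    drug_panel=None,
) -> CohortConfig:
    """The default study conditions: a mid-size tumor cohort with a smaller
    control cohort, well-separated planted mixtures (6 SD between modes,
    balanced proportions) and a doubled hazard for upper-component patients.
    """
    specs = []
    for i in range(n_unimodal):
        specs.append(FeatureSpec(f"uni-{i:03d}", "unimodal",
                                 mu1=mu_low + 3.0, mu2=mu_low + 3.0, sigma1=sigma, sigma2=sigma))
    for i in range(n_tumor_bimodal):
        specs.append(FeatureSpec(f"tb-{i:03d}", "tumor_bimodal",
                                 mu1=mu_low, mu2=mu_high, sigma1=sigma, sigma2=sigma,
                                 pi1=pi1, subgroup=0))
    for i in range(n_shared_bimodal):
        specs.append(FeatureSpec(f"sb-{i:03d}", "shared_bimodal",
                                 mu1=mu_low, mu2=mu_high, sigma1=sigma, sigma2=sigma,
                                 pi1=pi1, subgroup=1))
    for i in range(n_low_expressed):
        specs.append(FeatureSpec(f"low-{i:03d}", "low_expressed"))
    if drug_panel is None:
        drug_panel = []
    return CohortConfig(
        n_tumor=n_tumor, n_control=n_control, feature_specs=specs,
        hazard_ratio=hazard_ratio, censor_rate=censor_rate,
        drug_panel=list(drug_panel), seed=seed,
    )


def write_bundle(config: CohortConfig, outdir, n_cell_lines: int = 13) -> dict:
    """Write TSV/CSV/JSON artifacts for a full synthetic study.

    Expression matrices are exported on the raw scale (2**x - 1) so the
    standard preprocessing (log2 transform) round-trips.  Returns the
    paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tumor, control, truth = generate_cohort(config)
    clinical = generate_clinical(truth, config)
    paths = {
        "tumor": outdir / "tumor_expression.tsv",
        "control": outdir / "control_expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    inverse_log2(tumor).to_tsv(paths["tumor"])
    inverse_log2(control).to_tsv(paths["control"])
    clinical.to_csv(paths["clinical"], sep="\t", index=False, lineterminator="\n")
    if config.drug_panel:
        expr, ic50 = generate_drug_panel(config, n_cell_lines)
        paths["cellline_expression"] = outdir / "cellline_expression.tsv"
        paths["ic50"] = outdir / "ic50.csv"
        expr.to_frame().to_csv(paths["cellline_expression"], sep="\t", lineterminator="\n")
        ic50.to_csv(paths["ic50"], lineterminator="\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
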