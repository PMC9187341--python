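import numpy as np
import pandas as pd
import pytest

from bimix.survival import (
    ModuleSurvivalModel,
    fit_cox,
    stage_association,
    stratify_hierarchical,
)
from bimix.synthetic import generate_clinical, generate_cohort, standard_config


def two_blob_matrix(rng, n_per_group=50, sigma=0.5):
    lo = rng.normal(0.0, sigma, (3, n_per_group))
    hi = rng.normal(8.0, sigma, (3, n_per_group))
    data = pd.DataFrame(
        np.hstack([lo, hi]),
        index=["m1", "m2", "m3"],
        columns=[f"s{i:03d}" for i in range(2 * n_per_group)],
    )
    truth = np.array(["low"] * n_per_group + ["high"] * n_per_group)
    return data, truth


def exp_clinical(rng, labels, hr, censor_frac=0.2, base=1e-3):
    hazards = np.where(labels == "high", base * hr, base)
    t = rng.exponential(1 / hazards)
    if censor_frac > 0:
        lam_c = base * censor_frac / (1 - censor_frac)
        c = rng.exponential(1 / lam_c, len(t))
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    else:
        event = np.ones(len(t), dtype=int)
    return pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(len(t))],
        "time_days": t, "event": event,
    })


class TestStratifyHierarchical:
    def test_separated_blobs_recovered_exactly(self, rng):
        data, truth = two_blob_matrix(rng)
        labels = stratify_hierarchical(data, ["m1", "m2", "m3"])
        assert (labels.to_numpy() == truth).all()

    def test_two_samples_split(self):
        data = pd.DataFrame([[0.0, 3.0], [0.0, 4.0]], index=["m1", "m2"],
                            columns=["a", "b"])
        labels = stratify_hierarchical(data, ["m1", "m2"])
        assert set(labels) == {"high", "low"}
        # L1 distance between (0,0) and (3,4) is 7; sample b is the high one
        assert labels["b"] == "high"

    def test_invariant_to_sample_order(self, rng):
        data, _ = two_blob_matrix(rng)
        perm = rng.permutation(data.shape[1])
        labels_a = stratify_hierarchical(data, ["m1", "m2", "m3"])
        labels_b = stratify_hierarchical(data.iloc[:, perm], ["m1", "m2", "m3"])
        assert labels_a.sort_index().equals(labels_b.sort_index())

    def test_single_sample_rejected(self):
        data = pd.DataFrame([[1.0]], index=["m1"], columns=["a"])
        with pytest.raises(ValueError):
            stratify_hierarchical(data, ["m1"])


class TestFitCox:
    def test_hr_recovery(self, rng):
        labels = pd.Series(
            np.repeat(["low", "high"], 250),
            index=[f"s{i:03d}" for i in range(500)],
        )
        clin = exp_clinical(rng, labels.to_numpy(), hr=2.0)
        res = fit_cox(labels, clin)
        assert 1.5 < res.hr < 2.6
        assert res.ci_low <= res.hr <= res.ci_high
        assert res.wald_p < 0.05
        assert set(res.n_per_group) == {"high", "low"}
        assert all(np.isfinite(v[0]) for v in res.median_survival.values())

    def test_label_swap_inverts_hr(self, rng):
        labels = pd.Series(np.repeat(["group1", "group2"], 100),
                           index=[f"s{i:03d}" for i in range(200)])
        clin = exp_clinical(rng, np.repeat(["low", "high"], 100), hr=2.0)
        res = fit_cox(labels, clin)
        swapped = labels.map({"group1": "group2", "group2": "group1"})
        res_swapped = fit_cox(swapped, clin)
        assert res_swapped.hr == pytest.approx(1.0 / res.hr, rel=1e-6)
        assert res_swapped.wald_p == pytest.approx(res.wald_p, rel=1e-6)

    def test_zero_events_in_group_rejected(self):
        labels = pd.Series(["high"] * 10 + ["low"] * 10,
                           index=[f"s{i}" for i in range(20)])
        clin = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)],
            "time_days": np.arange(1.0, 21.0),
            "event": [1] * 10 + [0] * 10,  # no events in "low"
        })
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(labels, clin)

    def test_all_censored_rejected(self):
        labels = pd.Series(["high"] * 10 + ["low"] * 10,
                           index=[f"s{i}" for i in range(20)])
        clin = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)],
            "time_days": np.arange(1.0, 21.0),
            "event": 0,
        })
        with pytest.raises(ValueError, match="censored"):
            fit_cox(labels, clin)


class TestStageAssociation:
    def test_perfect_independence(self):
        labels = pd.Series(["high"] * 20 + ["low"] * 20)
        stages = pd.Series((["I"] * 10 + ["II"] * 10) * 2)
        stat, p, table, _ = stage_association(labels, stages)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        # 2x2 table [[20,0],[0,20]]: chi2 = sum (O-E)^2/E with E=10 -> 40
        labels = pd.Series(["high"] * 20 + ["low"] * 20)
        stages = pd.Series(["I"] * 20 + ["II"] * 20)
        stat, p, table, _ = stage_association(labels, stages)
        assert stat == pytest.approx(40.0, abs=1e-9)

    def test_single_stage_rejected(self):
        labels = pd.Series(["high", "low"] * 10)
        stages = pd.Series(["I"] * 20)
        with pytest.raises(ValueError):
            stage_association(labels, stages)

    def test_stage_coupled_generator_detected(self):
        cfg = standard_config(seed=5, n_tumor=600, n_control=50, n_unimodal=0,
                              n_tumor_bimodal=1, n_shared_bimodal=0)
        cfg.stage_coupling = 1.0
        _, _, truth = generate_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        labels = pd.Series(
            np.where(np.array(truth["driver_membership"]) == 1, "high", "low"),
            index=truth["tumor_samples"],
        )
        stages = clin.set_index("sample_id")["stage"]
        _, p, _, _ = stage_association(labels, stages)
        assert p < 0.05

    def test_independent_stages_mostly_null(self):
        cfg = standard_config(seed=6, n_tumor=600, n_control=50, n_unimodal=0,
                              n_tumor_bimodal=1, n_shared_bimodal=0)
        _, _, truth = generate_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        labels = pd.Series(
            np.where(np.array(truth["driver_membership"]) == 1, "high", "low"),
            index=truth["tumor_samples"],
        )
        _, p, _, _ = stage_association(labels, clin.set_index("sample_id")["stage"])
        assert p > 0.001  # no planted association


class TestModuleSurvivalModel:
    def test_end_to_end_on_planted_cohort(self):
        cfg = standard_config(seed=11, n_tumor=300, n_control=50, n_unimodal=2,
                              n_tumor_bimodal=3, n_shared_bimodal=0)
        tumor, _, truth = generate_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        module = [f for f, a in truth["archetypes"].items() if a == "tumor_bimodal"]
        model = ModuleSurvivalModel(tumor, clin, module)
        res = model.fit()
        # high expressers carry doubled hazard
        assert res.hr > 1.2
        assert res.comparison == "high"
        assert "HR" in res.summary()

    def test_mixture_splitter_agrees_with_truth(self):
        cfg = standard_config(seed=12, n_tumor=200, n_control=50, n_unimodal=0,
                              n_tumor_bimodal=3, n_shared_bimodal=0)
        tumor, _, truth = generate_cohort(cfg)
        clin = generate_clinical(truth, cfg)
        module = list(truth["tumor_membership"])
        model = ModuleSurvivalModel(tumor, clin, module, splitter="mixture")
        labels = model.stratify()
        planted = np.where(np.array(truth["driver_membership"]) == 1, "high", "low")
        agreement = (labels.to_numpy() == planted).mean()
        assert agreement > 0.95
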