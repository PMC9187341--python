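import math

import numpy as np
import pandas as pd
import pytest

from bimix.bimodality import (
    BimodalityResults,
    ControlledMixtureModel,
    bimodality_index,
    cm_score,
    mm_score,
    penalized_bi,
    rank_features,
    simulate_fpr,
    threshold_counts,
)
from bimix.mixture import MixtureFit
from tests.conftest import planted_mixture


def _fit(mu1, mu2, pi1, sigma=1.0):
    n = 10
    return MixtureFit(
        k=2, mu1=mu1, mu2=mu2, sigma1=sigma, sigma2=sigma, pi1=pi1, pi2=1 - pi1,
        loglik=0.0, bic=0.0, assignments=np.zeros(n, dtype=np.int64),
    )


class TestBimodalityIndex:
    def test_balanced_hand_value(self):
        # sqrt(0.25) * 2 / sqrt(0.5 + 0.5) = 1
        assert bimodality_index(0.5, 0.5, 0, 2, 1, 1) == pytest.approx(1.0, abs=1e-12)

    def test_unbalanced_hand_value(self):
        # sqrt(0.16) * 3 / sqrt(0.8 + 0.2) = 1.2
        assert bimodality_index(0.2, 0.8, 0, 3, 1, 1) == pytest.approx(1.2, abs=1e-12)

    def test_zero_separation(self):
        assert bimodality_index(0.3, 0.7, 5, 5, 1, 2) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bimodality_index(0.5, 0.5, 3, 1, 1, 1)  # unordered means
        with pytest.raises(ValueError):
            bimodality_index(0.0, 1.0, 0, 1, 1, 1)  # boundary proportion
        with pytest.raises(ValueError):
            bimodality_index(0.5, 0.5, 0, 1, 0, 1)  # zero sigma


class TestPenalizedBI:
    def test_ledger_example(self):
        tumor = _fit(0.0, 10.0, 0.5)
        control = _fit(5.0, 15.0, 0.525)  # mean distances sum 10, pi distances 0.05
        bi_mu, bi_pi, bi_final = penalized_bi(1.92, tumor, control)
        assert bi_mu == pytest.approx(1.82, abs=1e-12)
        assert bi_pi == pytest.approx(1.92 - 20.0, abs=1e-9)
        assert bi_final == pytest.approx(1.82, abs=1e-12)

    def test_identical_distributions_fully_penalized(self):
        tumor = _fit(0.0, 6.0, 0.4)
        bi_mu, bi_pi, bi_final = penalized_bi(2.5, tumor, _fit(0.0, 6.0, 0.4))
        assert bi_final == 0.0
        assert bi_mu == -math.inf and bi_pi == -math.inf

    def test_penalty_vanishes_with_distance(self):
        tumor = _fit(0.0, 6.0, 0.5)
        control = _fit(500.0, 506.0, 0.5)  # mean distance sum 1000, equal proportions
        bi_mu, bi_pi, bi_final = penalized_bi(2.0, tumor, control)
        assert bi_final == pytest.approx(2.0 - 1e-3, abs=1e-12)
        assert bi_pi == -math.inf

    def test_penalty_monotone_in_mean_distance(self):
        tumor = _fit(0.0, 6.0, 0.5)
        prev = -math.inf
        for shift in (0.1, 0.5, 1.0, 5.0, 50.0):
            bi_mu, _, _ = penalized_bi(2.0, tumor, _fit(shift, 6.0 + shift, 0.5))
            assert bi_mu >= prev
            prev = bi_mu

    def test_requires_two_component_fits(self):
        one = MixtureFit(k=1, mu1=0.0, sigma1=1.0, pi1=1.0, loglik=0.0, bic=0.0,
                         assignments=np.zeros(10, dtype=np.int64))
        with pytest.raises(ValueError):
            penalized_bi(1.0, one, _fit(0, 1, 0.5))


class TestScoring:
    def test_tumor_unimodal_scores_zero(self, rng):
        x = rng.normal(5, 1, 200)
        call = mm_score(x)
        assert call.bi_final == 0.0 and call.tumor_verdict.modality == "unimodal"
        call_cm = cm_score(x, rng.normal(5, 1, 50))
        assert call_cm.bi_final == 0.0

    def test_tumor_bimodal_control_unimodal_unpenalized(self, rng):
        t = planted_mixture(rng, 300, 2.0, 8.0, 1.0, 0.5)
        c = rng.normal(2.0, 1.0, 50)
        call = cm_score(t, c)
        assert not call.penalized
        assert call.bi_final == call.bi_raw > 1.4

    def test_shared_mixture_suppressed(self, rng):
        """A feature bimodal in both cohorts is heavily penalized: the final
        score drops far below the raw BI (~3 here) for every draw, and below
        the 1.4 call threshold for most; the residual leakage reflects
        sampling noise in the control component means at n=50."""
        finals, raws = [], []
        for _ in range(30):
            t = planted_mixture(rng, 300, 2.0, 8.0, 1.0, 0.5)
            c = planted_mixture(rng, 50, 2.0, 8.0, 1.0, 0.5)
            call = cm_score(t, c)
            finals.append(call.bi_final)
            raws.append(call.bi_raw)
        finals, raws = np.array(finals), np.array(raws)
        assert (finals < raws - 0.5).all()
        assert np.median(finals) < 0.5
        assert (finals < 1.4).mean() >= 0.8

    def test_cm_never_exceeds_mm(self, rng):
        for _ in range(20):
            t = planted_mixture(rng, 200, 2.0, 8.0, 1.0, 0.5)
            c = planted_mixture(rng, 50, 2.0, 8.0, 1.0, 0.5)
            assert cm_score(t, c).bi_final <= mm_score(t).bi_final + 1e-12

    def test_bi_shift_and_scale_invariant(self, rng):
        t = planted_mixture(rng, 300, 2.0, 8.0, 1.0, 0.4)
        base = mm_score(t).bi_final
        assert mm_score(t + 100.0).bi_final == pytest.approx(base, rel=1e-6)
        assert mm_score(t * 3.0).bi_final == pytest.approx(base, rel=1e-6)


class TestRanking:
    def _calls(self, bis, ids=None):
        ids = ids or [f"f{i}" for i in range(len(bis))]
        return [_stub_call(fid, bi) for fid, bi in zip(ids, bis)]

    def test_descending_order_and_counts(self):
        calls = self._calls([1.92, 0.5, 2.2])
        frame = rank_features(calls, 1.4)
        assert frame["bi_final"].tolist() == [2.2, 1.92, 0.5]
        assert frame["passes"].sum() == 2
        counts = threshold_counts(calls)
        assert counts["BI > 1.4"] == 2 and counts["BI > 0"] == 3

    def test_empty_input(self):
        assert rank_features([], 1.4).empty

    def test_tie_broken_lexicographically(self):
        calls = self._calls([1.0, 1.0, 1.0], ids=["c", "a", "b"])
        assert rank_features(calls)["feature_id"].tolist() == ["a", "b", "c"]


def _stub_call(fid, bi):
    from bimix.bimodality import BimodalCall
    from bimix.mixture import ModalityVerdict

    fit = MixtureFit(k=1, mu1=0.0, sigma1=1.0, pi1=1.0, loglik=0.0, bic=0.0,
                     assignments=np.zeros(10, dtype=np.int64))
    call = BimodalCall(fid, ModalityVerdict("unimodal", fit))
    call.bi_raw = bi
    call.bi_final = bi
    return call


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, rng):
        tumor = pd.DataFrame(
            [planted_mixture(rng, 120, 2.0, 8.0, 1.0, 0.5), rng.normal(5, 1, 120)],
            index=["bim", "uni"], columns=[f"s{i}" for i in range(120)],
        )
        control = pd.DataFrame(
            [rng.normal(2, 1, 40), rng.normal(5, 1, 40)],
            index=["bim", "uni"], columns=[f"c{i}" for i in range(40)],
        )
        model = ControlledMixtureModel(tumor, control)
        assert model.mode == "cm"
        res = model.fit()
        assert isinstance(res, BimodalityResults)
        assert res.bimodal_features() == ["bim"]
        text = res.summary()
        assert "CM" in text and "BI > 1.4" in text
        frame = res.frame
        assert set(frame["feature_id"]) == {"bim", "uni"}

    def test_missing_control_features_rejected(self, rng):
        tumor = pd.DataFrame([rng.normal(5, 1, 50)], index=["a"])
        control = pd.DataFrame([rng.normal(5, 1, 20)], index=["b"])
        with pytest.raises(ValueError, match="missing"):
            ControlledMixtureModel(tumor, control)


class TestSimulateFPR:
    def test_infinite_threshold_is_zero(self):
        assert simulate_fpr(50, 20, math.inf, seed=0, pipeline="mm") == 0.0

    def test_monotone_in_threshold_and_n(self):
        f_low = simulate_fpr(50, 300, 1.0, seed=3, pipeline="mm")
        f_high = simulate_fpr(50, 300, 1.4, seed=3, pipeline="mm")
        assert f_high <= f_low
        f_big_n = simulate_fpr(200, 300, 1.4, seed=3, pipeline="mm")
        assert f_big_n <= f_high + 0.01

    def test_power_on_separated_mixture(self, rng):
        hits = 0
        for _ in range(60):
            x = planted_mixture(rng, 50, 2.0, 8.0, 1.0, 0.5)
            hits += mm_score(x).bi_final > 1.4
        assert hits >= 57  # >= 95% detection at delta = 6 sigma
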