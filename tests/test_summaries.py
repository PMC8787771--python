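"""Posterior standardization and effect summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from bayeshte.errors import ContractError, InputError
from bayeshte.models import ModelSpec, PosteriorDraws, fit_continuous_interaction
from bayeshte.summaries import (CovariateProfile, effect_summary,
                                interaction_summary, most_common_profile,
                                standardized_event_probs)
from bayeshte.synthetic import GeneratorConfig, TrialDataset, generate_trial


def _draws_from(columns, arrays, meta=None):
    vals = np.stack([np.asarray(a, float) for a in arrays], axis=1)[None, :, :]
    return PosteriorDraws(values=vals, columns=list(columns), divergences=0,
                          meta=meta or {"kind": "primary", "site_levels": []})


PROFILE = CovariateProfile({"copd": 0, "haem": 0})


class TestMostCommonProfile:
    def test_clear_mode(self):
        df = pd.DataFrame({"copd": [0] * 8 + [1] * 2, "haem": [1] * 7 + [0] * 3,
                           "site_id": [2] * 6 + [1] * 4, "open_system": 0})
        ds = TrialDataset(df=df)
        prof = most_common_profile(ds, ModelSpec())
        assert prof["copd"] == 0 and prof["haem"] == 1 and prof["site"] == 2

    def test_tie_breaks_to_reference(self):
        df = pd.DataFrame({"copd": [0, 1], "haem": [1, 0],
                           "site_id": [3, 1], "open_system": [0, 1]})
        prof = most_common_profile(TrialDataset(df=df),
                                   ModelSpec(adjust_open_system=True))
        assert prof["copd"] == 0 and prof["haem"] == 0
        assert prof["open_system"] == 0 and prof["site"] == 1

    def test_cohort_modal_levels(self, default_cohort):
        """The emulated cohort's modal profile: no COPD, no haematological
        malignancy, closed oxygen system."""
        prof = most_common_profile(default_cohort, ModelSpec(adjust_open_system=True))
        assert prof["copd"] == 0 and prof["haem"] == 0 and prof["open_system"] == 0


class TestStandardizedProbs:
    def test_null_linear_predictor(self):
        d = _draws_from(["alpha", "beta", "gamma_copd", "gamma_haem"],
                        [[0.0], [0.0], [0.0], [0.0]])
        p0, p1 = standardized_event_probs(d, PROFILE)
        assert p0[0] == 0.5 and p1[0] == 0.5

    def test_beta_log2(self):
        d = _draws_from(["alpha", "beta", "gamma_copd", "gamma_haem"],
                        [[0.0], [np.log(2.0)], [0.0], [0.0]])
        p0, p1 = standardized_event_probs(d, PROFILE)
        assert p0[0] == pytest.approx(0.5)
        assert p1[0] == pytest.approx(2.0 / 3.0)

    def test_monotone_in_beta(self, rng):
        n = 500
        d = _draws_from(["alpha", "beta", "gamma_copd", "gamma_haem"],
                        [rng.standard_normal(n), np.abs(rng.standard_normal(n)) + 1e-9,
                         rng.standard_normal(n), rng.standard_normal(n)])
        p0, p1 = standardized_event_probs(d, PROFILE)
        assert (p1 > p0).all()

    def test_profile_contract_error(self):
        d = _draws_from(["alpha", "beta", "gamma_copd", "gamma_haem"],
                        [[0.0], [0.0], [0.0], [0.0]])
        with pytest.raises(ContractError, match="haem"):
            standardized_event_probs(d, CovariateProfile({"copd": 0}))


class TestEffectSummary:
    def test_four_draw_hand_enumeration(self):
        p0 = np.array([0.4, 0.4, 0.5, 0.2])
        p1 = np.array([0.4, 0.5, 0.4, 0.4])
        s = effect_summary(p0, p1, rr_thresholds=(1.0,), rd_thresholds=(0.0,))
        # RDs are {0, .1, -.1, .2}: median .05; only one of four RRs < 1
        assert s.rd[0] == pytest.approx(5.0)  # percentage points
        assert s.prob_rr_below[1.0] == pytest.approx(0.25)

    def test_identity_draws(self):
        p = np.full(100, 0.3)
        s = effect_summary(p, p)
        assert s.rr[0] == 1.0 and s.rd[0] == 0.0
        assert s.prob_rr_below[0.80] == 0.0

    def test_permutation_invariance(self, rng):
        p0 = rng.uniform(0.2, 0.6, 400)
        p1 = rng.uniform(0.2, 0.6, 400)
        perm = rng.permutation(400)
        assert effect_summary(p0, p1) == effect_summary(p0[perm], p1[perm])

    def test_per_draw_identities_exact(self, rng):
        p0 = rng.uniform(0.05, 0.9, 1000)
        p1 = rng.uniform(0.05, 0.9, 1000)
        rr, rd = p1 / p0, p1 - p0
        or_ = (p1 / (1 - p1)) / (p0 / (1 - p0))
        s = effect_summary(p0, p1)
        assert s.rr[0] == np.percentile(rr, 50)
        assert s.rd[0] == np.percentile(100 * rd, 50)
        assert s.or_[0] == np.percentile(or_, 50)
        # complementary probabilities partition the draws
        assert s.prob_rr_below[1.0] + np.mean(rr >= 1.0) == 1.0

    def test_threshold_map_monotone(self, rng):
        p0 = rng.uniform(0.2, 0.6, 500)
        p1 = rng.uniform(0.2, 0.6, 500)
        s = effect_summary(p0, p1)
        probs = [s.prob_rr_below[c] for c in sorted(s.prob_rr_below)]
        assert all(a <= b for a, b in zip(probs, probs[1:]))
        probs_rd = [s.prob_rd_below[c] for c in sorted(s.prob_rd_below)]
        assert all(a <= b for a, b in zip(probs_rd, probs_rd[1:]))

    def test_cri_brackets_median(self, rng):
        p0 = rng.uniform(0.2, 0.6, 500)
        p1 = rng.uniform(0.2, 0.6, 500)
        s = effect_summary(p0, p1)
        for med, lo, hi in (s.p0, s.p1, s.rr, s.rd, s.or_):
            assert lo <= med <= hi

    def test_threshold_probs_converge_to_normal_cdf(self, rng):
        """Draws with a known normal log-OR: empirical threshold
        probabilities approach the normal CDF."""
        m, sd = -0.1, 0.2
        log_or = rng.normal(m, sd, 50_000)
        p0 = np.full(log_or.size, 0.4)
        odds1 = (0.4 / 0.6) * np.exp(log_or)
        p1 = odds1 / (1 + odds1)
        s = effect_summary(p0, p1, rr_thresholds=(), rd_thresholds=())
        or_draws = (p1 / (1 - p1)) / (p0 / (1 - p0))
        for c in (0.8, 1.0, 1.2):
            emp = np.mean(or_draws < c)
            assert emp == pytest.approx(stats.norm.cdf((np.log(c) - m) / sd), abs=0.01)

    def test_errors(self):
        with pytest.raises(InputError):
            effect_summary(np.array([]), np.array([]))
        with pytest.raises(InputError, match="RR undefined"):
            effect_summary(np.array([0.0, 0.5]), np.array([0.5, 0.5]))


class TestInteractionSummary:
    def _interaction_draws(self, eta, n=None):
        n = n or len(np.atleast_1d(eta))
        eta = np.broadcast_to(np.asarray(eta, float), (n,))
        zeros = np.zeros(n)
        return _draws_from(
            ["alpha", "beta", "delta", "eta", "gamma_copd", "gamma_haem"],
            [zeros, zeros, zeros, eta, zeros, zeros],
            meta={"kind": "interaction", "site_levels": [], "variable": "lactate",
                  "x_mean": 2.0, "x_sd": 1.5, "x_range": (0.1, 20.0)})

    def test_point_mass_at_null(self):
        s = interaction_summary(self._interaction_draws(0.0, n=200), [2.0], PROFILE)
        assert s.prob_below_1 == 0.0 and s.prob_above_1 == 0.0
        assert s.prob_equal_1 == 1.0

    def test_symmetric_eta(self, rng):
        eta = rng.normal(0.0, 0.3, 20_000)
        s = interaction_summary(self._interaction_draws(eta), [2.0], PROFILE)
        assert s.prob_above_1 == pytest.approx(0.5, abs=0.02)
        assert s.prob_below_1 + s.prob_above_1 + s.prob_equal_1 == 1.0

    def test_curve_null_point(self):
        s = interaction_summary(self._interaction_draws(0.0, n=200), [2.0], PROFILE)
        assert set(s.curve["arm"]) == {"lower", "higher"}
        assert np.allclose(s.curve["median"], 0.5)

    def test_curve_probabilities_in_unit_interval(self, rng):
        eta = rng.normal(0.2, 0.1, 500)
        s = interaction_summary(self._interaction_draws(eta),
                                np.linspace(0.5, 6.0, 7), PROFILE)
        assert ((s.curve["median"] > 0) & (s.curve["median"] < 1)).all()
        assert (s.curve["cri_low"] <= s.curve["median"]).all()

    def test_out_of_range_grid_warns(self):
        d = self._interaction_draws(0.1, n=200)
        with pytest.warns(UserWarning, match="beyond the observed"):
            interaction_summary(d, [50.0], PROFILE)

    def test_non_interaction_model_rejected(self):
        d = _draws_from(["alpha", "beta", "gamma_copd", "gamma_haem"],
                        [[0.0], [0.0], [0.0], [0.0]])
        with pytest.raises(ContractError):
            interaction_summary(d, [1.0], PROFILE)


def test_subgroup_probs_use_group_effects():
    labels = ["g0", "g1"]
    d = _draws_from(
        ["alpha", "beta", "gamma_copd", "gamma_haem",
         "a_subgroup[g0]", "a_subgroup[g1]", "b_subgroup[g0]", "b_subgroup[g1]"],
        [[0.0], [0.0], [0.0], [0.0], [0.0], [0.5], [0.0], [np.log(2)]],
        meta={"kind": "subgroup", "site_levels": [], "subgroup_labels": labels})
    p0, p1 = standardized_event_probs(d, PROFILE, subgroup=0)
    assert p0[0] == 0.5 and p1[0] == 0.5
    p0, p1 = standardized_event_probs(d, PROFILE, subgroup=1)
    assert p0[0] == pytest.approx(expit(0.5))
    assert p1[0] == pytest.approx(expit(0.5 + np.log(2)))
    with pytest.raises(ContractError):
        standardized_event_probs(d, PROFILE)  # subgroup model needs an index
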