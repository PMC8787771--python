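"""Prior families: calibration constants and the DL meta-analysis."""

from math import exp, log, sqrt

import numpy as np
import pytest
from scipy import stats

from bayeshte.errors import ConfigurationError, InputError
from bayeshte.priors import (MetaAnalysisResult, PriorSpec, StudyTable,
                             evidence_based_prior, illustrative_study_tables,
                             random_effects_meta, read_study_tables,
                             sceptic_prior, weakly_informative_prior)
from helpers import dersimonian_laird_by_hand


class TestWeakPrior:
    def test_95pct_or_interval(self):
        lo, hi = weakly_informative_prior().or_interval()
        assert (round(lo, 2), round(hi, 2)) == (0.14, 7.10)

    def test_median_or_is_one(self):
        p = weakly_informative_prior()
        assert exp(p.mean) == 1.0

    def test_prob_or_below_half(self):
        # P(OR < 0.5) = Phi(log 0.5) for a standard normal log-OR
        expected = stats.norm.cdf(log(0.5))
        assert weakly_informative_prior().prob_or_below(0.5) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.244, abs=5e-4)


class TestScepticPrior:
    def test_centred_on_no_difference(self):
        p = sceptic_prior()
        assert p.mean == 0.0
        assert p.prob_or_below(1.0) == pytest.approx(0.5)

    def test_default_sd_calibration(self):
        lo, hi = sceptic_prior().or_interval()
        assert (round(lo, 2), round(hi, 2)) == (0.50, 2.01)
        assert sceptic_prior().prob_or_below(0.8) == pytest.approx(
            stats.norm.cdf(log(0.8) / 0.355), abs=1e-12)

    def test_sd_overridable(self):
        assert sceptic_prior(0.2).sd == 0.2
        with pytest.raises(ConfigurationError):
            sceptic_prior(0.0)


def _table(study, a, n1, c, n2):
    return StudyTable(study, a, n1, c, n2)


class TestMetaAnalysis:
    def test_identical_studies_no_heterogeneity(self):
        t = _table("s", 10, 100, 20, 100)
        res = random_effects_meta([t, _table("s2", 10, 100, 20, 100)])
        assert res.tau2 == 0.0
        assert res.mu == pytest.approx(log((10 * 80) / (90 * 20)), abs=1e-12)

    def test_single_study_closed_form(self):
        res = random_effects_meta([_table("s", 10, 100, 20, 100)])
        assert res.mu == pytest.approx(log((10 * 80) / (90 * 20)), abs=1e-12)
        assert res.se_mu == pytest.approx(sqrt(1 / 10 + 1 / 90 + 1 / 20 + 1 / 80), abs=1e-12)
        assert res.tau2 == 0.0

    def test_three_study_worked_example(self):
        """DL pooling matches an explicit step-by-step computation to 1e-10."""
        rows = [(25, 216, 44, 218), (44, 99, 30, 102), (78, 484, 68, 481)]
        tables = [_table(f"s{i}", *r) for i, r in enumerate(rows)]
        mu, se, tau2 = dersimonian_laird_by_hand(rows)
        res = random_effects_meta(tables)
        assert res.mu == pytest.approx(mu, abs=1e-10)
        assert res.se_mu == pytest.approx(se, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)
        assert sum(res.weights) == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_continuity_correction(self):
        y, v = _table("z", 0, 10, 5, 10).log_or()
        assert y == pytest.approx(log((0.5 * 5.5) / (10.5 * 5.5)), abs=1e-12)
        assert v == pytest.approx(1 / 0.5 + 1 / 10.5 + 1 / 5.5 + 1 / 5.5, abs=1e-12)

    def test_order_invariance(self):
        tables = [_table("a", 12, 50, 20, 55), _table("b", 5, 40, 9, 35),
                  _table("c", 30, 90, 22, 88)]
        res1 = random_effects_meta(tables)
        res2 = random_effects_meta(tables[::-1])
        assert res1.mu == pytest.approx(res2.mu, abs=1e-12)
        assert res1.tau2 == pytest.approx(res2.tau2, abs=1e-12)

    def test_dl_reduces_to_fixed_effect_when_tau_zero(self):
        tables = [_table("a", 10, 100, 11, 100), _table("b", 9, 100, 10, 100)]
        res = random_effects_meta(tables)
        assert res.tau2 == 0.0
        y = np.array([t.log_or()[0] for t in tables])
        v = np.array([t.log_or()[1] for t in tables])
        w = 1 / v
        assert res.mu == pytest.approx(float(np.sum(w * y) / np.sum(w)), abs=1e-12)

    def test_errors(self):
        with pytest.raises(InputError):
            random_effects_meta([])
        with pytest.raises(InputError):
            _table("bad", 0, 0, 1, 10)
        with pytest.raises(InputError):
            _table("bad", 11, 10, 1, 10)


class TestEvidencePrior:
    def test_homogeneous_sd_equals_se(self):
        res = MetaAnalysisResult(mu=0.2, se_mu=0.15, tau2=0.0,
                                 study_labels=("a",), study_log_ors=(0.2,),
                                 study_variances=(0.0225,), weights=(1.0,))
        assert evidence_based_prior(res).sd == pytest.approx(0.15)

    def test_predictive_sd_arithmetic(self):
        res = MetaAnalysisResult(mu=0.1, se_mu=0.2, tau2=0.05,
                                 study_labels=("a",), study_log_ors=(0.1,),
                                 study_variances=(0.04,), weights=(1.0,))
        p = evidence_based_prior(res)
        assert p.mean == pytest.approx(0.1)
        assert p.sd == pytest.approx(sqrt(0.04 + 0.05), abs=1e-12)

    def test_consistency_with_identical_studies(self):
        t = _table("s", 15, 120, 25, 118)
        prior = evidence_based_prior(random_effects_meta([t, t]))
        assert prior.mean == pytest.approx(t.log_or()[0], abs=1e-12)
        assert prior.label == "evidence"


def test_prior_sd_must_be_positive():
    with pytest.raises(ConfigurationError):
        PriorSpec(label="custom", mean=0.0, sd=0.0)


def test_fixture_csv_loads_and_pools(tmp_path):
    tables = illustrative_study_tables()
    assert len(tables) == 3
    res = random_effects_meta(tables)
    assert res.k == 3 and res.tau2 >= 0
    # round-trip through a user CSV
    p = tmp_path / "studies.csv"
    p.write_text("study,e_int,n_int,e_ctl,n_ctl\nx,5,50,9,48\n")
    assert read_study_tables(p)[0].events_control == 9
    with pytest.raises(InputError, match="columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("study,events\nx,5\n")
        read_study_tables(bad)
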