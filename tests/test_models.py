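"""Model fitting: prior dominance, recovery, structure, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from bayeshte.errors import ConfigurationError, InputError
from bayeshte.models import (ModelSpec, PosteriorDraws, diagnostics,
                             fit_continuous_interaction, fit_primary,
                             fit_subgroup_hte)
from bayeshte.priors import sceptic_prior
from bayeshte.subgroups import quintile_subgroups
from bayeshte.synthetic import GeneratorConfig, TrialDataset, generate_trial


def test_empty_dataset_reproduces_prior():
    """With no data the treatment-effect posterior is the prior itself."""
    ds = generate_trial(GeneratorConfig(n_patients=0))
    prior = sceptic_prior()
    spec = ModelSpec(prior=prior, chains=4, warmup=300, draws=5000, seed=1)
    draws = fit_primary(ds, spec)
    beta = draws.param("beta")
    assert beta.size == 20_000
    assert abs(beta.mean() - prior.mean) < 0.02
    assert beta.std() == pytest.approx(prior.sd, rel=0.05)


def test_primary_recovers_true_effect(matched_cohort, fast_spec):
    draws = fit_primary(matched_cohort, fast_spec)
    assert np.median(draws.param("beta")) == pytest.approx(0.3, abs=0.15)
    # all named parameters present
    for col in ("alpha", "beta", "gamma_copd", "gamma_haem", "sigma_site"):
        assert col in draws.columns


def test_seeded_fit_determinism(matched_cohort):
    spec = ModelSpec(chains=2, warmup=100, draws=100, seed=5)
    a = fit_primary(matched_cohort, spec)
    b = fit_primary(matched_cohort, spec)
    np.testing.assert_array_equal(a.values, b.values)


def test_site_relabel_invariance(fast_spec):
    """Permuting site IDs leaves the treatment-effect posterior unchanged
    up to Monte Carlo error."""
    cfg = GeneratorConfig(n_patients=1200, n_sites=6, treatment_log_or=0.3,
                          covariate_log_ors={"copd": 0.2}, baseline_logit=-0.3,
                          missing_rates={}, seed=9)
    ds = generate_trial(cfg)
    perm = {1: 4, 2: 6, 3: 1, 4: 5, 5: 2, 6: 3}
    df2 = ds.df.assign(site_id=ds.df["site_id"].map(perm))
    ds2 = TrialDataset(df=df2, config="external")
    m1 = np.median(fit_primary(ds, fast_spec).param("beta"))
    m2 = np.median(fit_primary(ds2, fast_spec).param("beta"))
    assert m1 == pytest.approx(m2, abs=0.1)


def test_non_binary_outcome_rejected(matched_cohort, fast_spec):
    df = matched_cohort.df.copy()
    df.loc[df.index[0], "dead_90d"] = 2
    with pytest.raises(InputError, match="binary"):
        fit_primary(TrialDataset(df=df), fast_spec)


class TestSubgroupModel:
    def test_complete_pooling_limit(self, matched_cohort):
        """Forcing the pooling SD to ~0 collapses all subgroup effects onto
        the overall effect."""
        scheme = quintile_subgroups(matched_cohort.df["sofa"], variable="sofa")
        spec = ModelSpec(chains=2, warmup=200, draws=300, seed=3,
                         nuisance_scales={"sigma_subgroup_effect": 1e-3})
        draws = fit_subgroup_hte(matched_cohort, scheme, spec)
        beta = draws.param("beta")
        for lbl in draws.meta["subgroup_labels"]:
            b_g = draws.param(f"b_subgroup[{lbl}]")
            assert np.abs(np.median(beta + b_g) - np.median(beta)) < 0.02

    def test_homogeneous_effect_recovery(self, fast_spec):
        cfg = GeneratorConfig(n_patients=4000, n_sites=5, treatment_log_or=0.2,
                              covariate_log_ors={}, baseline_logit=-0.2,
                              missing_rates={}, seed=17)
        ds = generate_trial(cfg)
        scheme = quintile_subgroups(ds.df["sofa"], variable="sofa")
        draws = fit_subgroup_hte(ds, scheme, fast_spec)
        beta = draws.param("beta")
        for lbl in draws.meta["subgroup_labels"]:
            est = np.median(beta + draws.param(f"b_subgroup[{lbl}]"))
            assert est == pytest.approx(0.2, abs=0.2)

    def test_empty_arm_subgroup_warns(self, fast_spec):
        cfg = GeneratorConfig(n_patients=200, n_sites=2, missing_rates={}, seed=2)
        ds = generate_trial(cfg)
        df = ds.df.copy()
        # force one subgroup to be single-arm: all lowest-sofa patients to 'lower'
        scheme = quintile_subgroups(df["sofa"], variable="sofa")
        df.loc[scheme.assignments == 0, "allocation"] = "lower"
        ds2 = TrialDataset(df=df)
        with pytest.warns(UserWarning, match="pooling alone"):
            fit_subgroup_hte(ds2, quintile_subgroups(df["sofa"], variable="sofa"),
                             fast_spec)

    def test_scheme_dataset_mismatch(self, matched_cohort, fast_spec):
        scheme = quintile_subgroups([1, 2, 3, 4, 5], variable="sofa")
        with pytest.raises(InputError, match="not built on this dataset"):
            fit_subgroup_hte(matched_cohort, scheme, fast_spec)


class TestInteractionModel:
    def test_open_system_adjustment_only_for_pf_ratio(self, matched_cohort, fast_spec):
        d_pf = fit_continuous_interaction(matched_cohort, "pf_ratio", fast_spec)
        assert "gamma_open_system" in d_pf.columns
        d_sofa = fit_continuous_interaction(matched_cohort, "sofa", fast_spec)
        assert "gamma_open_system" not in d_sofa.columns

    def test_constant_variable_rejected(self, fast_spec):
        cfg = GeneratorConfig(n_patients=100, n_sites=2, missing_rates={}, seed=1)
        ds = generate_trial(cfg)
        df = ds.df.assign(lactate=2.0)
        with pytest.raises(InputError, match="constant"):
            fit_continuous_interaction(TrialDataset(df=df), "lactate", fast_spec)

    def test_unknown_variable_rejected(self, matched_cohort, fast_spec):
        with pytest.raises(InputError, match="interaction variable"):
            fit_continuous_interaction(matched_cohort, "copd", fast_spec)

    def test_eta_reported_per_original_unit(self, fast_spec):
        """Scaling the variable by 10 scales the per-unit interaction by 1/10."""
        cfg = GeneratorConfig(n_patients=3000, n_sites=3, missing_rates={},
                              interaction_log_ors={"lactate": 0.3},
                              covariate_log_ors={"lactate": 0.2},
                              baseline_logit=-0.8, seed=31)
        ds = generate_trial(cfg)
        d1 = fit_continuous_interaction(ds, "lactate", fast_spec)
        df10 = ds.df.assign(lactate=ds.df["lactate"] * 10)
        d10 = fit_continuous_interaction(TrialDataset(df=df10), "lactate", fast_spec)
        m1 = np.median(d1.param("eta"))
        m10 = np.median(d10.param("eta"))
        assert m10 == pytest.approx(m1 / 10, abs=0.05 * abs(m1) + 0.02)
        assert m1 == pytest.approx(0.3, abs=0.12)


class TestDiagnostics:
    def _fake_draws(self, values):
        values = np.asarray(values, float)
        return PosteriorDraws(values=values, columns=["theta"], divergences=0,
                              meta={})

    def test_identical_chains_rhat_one(self, rng):
        chain = rng.standard_normal((1, 500, 1))
        draws = self._fake_draws(np.concatenate([chain, chain], axis=0))
        rep = diagnostics(draws)
        assert rep.table.loc["theta", "rhat"] == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_fail(self, rng):
        c1 = rng.standard_normal((1, 500, 1))
        draws = self._fake_draws(np.concatenate([c1, c1 + 10.0], axis=0))
        rep = diagnostics(draws)
        assert rep.table.loc["theta", "rhat"] > 1.01
        assert not rep.acceptable

    def test_single_chain_rhat_undefined(self, rng):
        draws = self._fake_draws(rng.standard_normal((1, 500, 1)))
        rep = diagnostics(draws)
        assert np.isnan(rep.table.loc["theta", "rhat"])
        assert "single chain" in rep.note

    def test_iid_bulk_ess_calibration(self, rng):
        """Independent draws: bulk ESS within 10% of the nominal 4 x 5000."""
        draws = self._fake_draws(rng.standard_normal((4, 5000, 1)))
        rep = diagnostics(draws)
        assert rep.table.loc["theta", "ess_bulk"] == pytest.approx(20_000, rel=0.10)

    def test_divergences_block_acceptance(self, rng):
        vals = rng.standard_normal((2, 500, 1))
        draws = PosteriorDraws(values=vals, columns=["theta"], divergences=3, meta={})
        assert not diagnostics(draws).acceptable


def test_model_spec_validation():
    with pytest.raises(ConfigurationError):
        ModelSpec(kind="nonsense")
    with pytest.raises(ConfigurationError):
        ModelSpec(chains=1)


def test_draws_csv_round_trip(tmp_path, matched_cohort):
    spec = ModelSpec(chains=2, warmup=100, draws=150, seed=2)
    draws = fit_primary(matched_cohort, spec)
    path = tmp_path / "draws.csv"
    draws.to_csv(path)
    back = PosteriorDraws.from_csv(path)
    assert back.n_chains == 2 and back.n_draws == 300
    np.testing.assert_allclose(back.param("beta"), draws.param("beta"), rtol=1e-6)
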