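import warnings

import numpy as np
import pytest

import condorcet as cc
from condorcet.data import DataError
from condorcet.inference import ConvergenceWarning, _attach_diagnostics
from conftest import make_draws

T, F, D = cc.TRUE, cc.FALSE, cc.DONT_KNOW


class TestGelmanRubin:
    def test_constant_chains_give_one(self):
        chains = np.full((3, 100), 2.5)
        assert cc.gelman_rubin(chains) == 1.0

    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(8)
        chains = rng.standard_normal((2, 1000))
        assert abs(cc.gelman_rubin(chains) - 1.0) < 0.05

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(8)
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert cc.gelman_rubin(chains) > 2.0

    def test_split_detects_within_chain_drift(self):
        # a trend inside a single chain inflates split-R-hat even though the
        # two chains look identical to an unsplit diagnostic
        trend = np.linspace(0, 10, 400)
        chains = np.stack([trend, trend]) + np.random.default_rng(0).normal(0, 0.1, (2, 400))
        assert cc.gelman_rubin(chains) > 1.5

    def test_agrees_with_arviz_on_well_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(42)
        chains = rng.standard_normal((4, 800)) * 1.7 + 0.3
        mine = cc.gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[..., None]))["x"].values[0])
        assert mine == pytest.approx(theirs, abs=0.05)

    def test_rejects_single_chain(self):
        with pytest.raises(ValueError):
            cc.gelman_rubin(np.zeros((1, 100)))


class TestFitBasics:
    def test_seeded_determinism(self, small_dataset):
        ds = small_dataset
        config = cc.McmcConfig(n_chains=2, n_burnin=50, n_samples=50, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cc.fit_ecm(ds.responses, config=config)
            b = cc.fit_ecm(ds.responses, config=config)
        for name in a.arrays:
            np.testing.assert_array_equal(a.get(name), b.get(name))

    def test_different_seeds_differ(self, small_dataset):
        ds = small_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cc.fit_ecm(ds.responses, config=cc.McmcConfig(2, 50, 50, seed=9))
            b = cc.fit_ecm(ds.responses, config=cc.McmcConfig(2, 50, 50, seed=10))
        assert not np.array_equal(a.get("theta"), b.get("theta"))

    def test_unanimous_item_has_certain_consensus(self):
        rng = np.random.default_rng(4)
        values = rng.choice([T, F, D], size=(25, 8), p=[0.45, 0.45, 0.1]).astype(np.int8)
        values[:, 0] = T  # every respondent endorses item 1
        data = cc.ResponseMatrix(
            values, [f"r{i}" for i in range(25)], [f"i{k}" for k in range(8)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = cc.fit_ecm(data, config=cc.McmcConfig(2, 200, 200, seed=3))
        assert draws.consensus_probability()[0] > 0.99

    def test_unstandardized_covariates_rejected(self, small_dataset):
        ds = small_dataset
        raw = cc.CovariateTable(
            ds.covariates.values * 3 + 1,
            ds.covariates.covariate_names,
            ds.covariates.respondent_ids,
        )
        with pytest.raises(DataError, match="standardized"):
            cc.fit_ecm(ds.responses, raw, config=cc.McmcConfig(2, 10, 10))

    def test_regression_without_covariates_rejected(self, small_dataset):
        reg = cc.RegressionSpec({"ability": ["age"]})
        with pytest.raises(DataError, match="covariate table"):
            cc.fit_ecm(small_dataset.responses, None, reg, cc.McmcConfig(2, 10, 10))

    def test_draws_round_trip_npz(self, small_fit, tmp_path):
        path = tmp_path / "draws.npz"
        small_fit.save(path)
        back = cc.PosteriorDraws.load(path)
        for name in small_fit.arrays:
            np.testing.assert_array_equal(back.get(name), small_fit.get(name))
        assert back.coef_names == small_fit.coef_names
        assert back.config == small_fit.config


class TestSamplerCorrectness:
    def test_prior_only_sampling_matches_prior_marginals(self):
        """With the likelihood removed, the chain must reproduce the prior:
        a basic validity check of every conditional update."""
        ds = cc.generate_dataset(
            cc.GeneratorConfig(n_respondents=20, n_items=10, seed=5, covariate_design=[])
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = cc.fit_ecm(
                ds.responses,
                config=cc.McmcConfig(n_chains=8, n_burnin=1000, n_samples=2000, seed=2),
                prior_only=True,
                coef_prior_sd=1.0,
                scale_prior_sd=1.0,
            )
        half_normal_mean = np.sqrt(2 / np.pi)  # of half-Normal(0, 1)
        assert pr.stacked("z").mean() == pytest.approx(0.5, abs=0.01)
        assert abs(pr.stacked("delta").mean()) < 1e-12  # recentering identity
        assert pr.stacked("theta").mean() == pytest.approx(0.0, abs=0.35)
        assert pr.coefficient_draws("ability", "intercept").mean() == pytest.approx(
            0.0, abs=0.35
        )
        assert pr.coefficient_draws("ability", "intercept").std() == pytest.approx(
            1.0, abs=0.25
        )
        for name in ("sigma:ability", "sigma_delta", "sigma:willingness_logit"):
            assert pr.stacked(name).mean() == pytest.approx(half_normal_mean, abs=0.15)

    def test_posterior_key_probability_monotone_in_true_count(self):
        """More True responses can only push P(Z=1) up, all else fixed."""
        n = 10
        d = np.full(n, 0.55)
        b = np.full(n, 0.8)
        g = np.full(n, 0.5)
        probs = [
            cc.consensus_conditional(np.array([T] * k + [F] * (n - k)), d, b, g)
            for k in range(n + 1)
        ]
        assert all(a < b_ for a, b_ in zip(probs, probs[1:]))

    def test_duplicating_respondents_sharpens_consensus(self):
        ds = cc.generate_dataset(
            cc.GeneratorConfig(
                n_respondents=20, n_items=12, seed=13, ability_mean=0.0, covariate_design=[]
            )
        )
        doubled_values = np.vstack([ds.responses.values, ds.responses.values])
        doubled = cc.ResponseMatrix(
            doubled_values,
            [f"r{i}" for i in range(40)],
            ds.responses.item_ids,
        )
        config = cc.McmcConfig(2, 300, 300, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sd_single = cc.fit_ecm(ds.responses, config=config).stacked("z").std(axis=0)
            sd_double = cc.fit_ecm(doubled, config=config).stacked("z").std(axis=0)
        assert sd_double.mean() <= sd_single.mean() + 0.02


class TestConvergenceFlag:
    def test_disjoint_chains_warn_and_flag(self):
        rng = np.random.default_rng(0)
        theta = rng.standard_normal((2, 100, 3))
        theta[1] += 8.0  # chains exploring different regions
        draws = make_draws(theta=theta)
        with pytest.warns(ConvergenceWarning):
            _attach_diagnostics(draws)
        assert not draws.converged
        assert float(np.nanmax(draws.rhat["theta"])) > draws.config.rhat_threshold


class TestSummaries:
    def test_certain_key_gives_label_and_zero_sd(self, small_dataset):
        m = 3
        z = np.ones((2, 10, m), dtype=np.int8)
        z[:, :, 1] = 0
        delta = np.tile(np.array([-1.2, 0.3, 0.9]), (2, 10, 1))
        draws = make_draws(z=z, delta=delta)
        data = cc.ResponseMatrix(
            np.array([[T, F, T], [T, F, F]], dtype=np.int8), ["a", "b"], draws.item_ids
        )
        report = cc.summarize_consensus(draws, data)
        assert list(report["consensus_label"]) == ["True", "False", "True"]
        np.testing.assert_allclose(report["posterior_sd"], 0.0)
        assert list(report["difficulty_rank"]) == [3, 2, 1]

    def test_split_key_has_half_sd(self):
        z = np.zeros((2, 10, 2), dtype=np.int8)
        z[:, ::2, :] = 1  # alternating draws: P(Z=1) = 0.5
        draws = make_draws(z=z)
        data = cc.ResponseMatrix(
            np.array([[T, T], [F, F], [T, F]], dtype=np.int8), list("abc"), draws.item_ids
        )
        report = cc.summarize_consensus(draws, data)
        np.testing.assert_allclose(report["posterior_sd"], 0.5)
        # exact tie resolves by raw mean: item1 2/3 True, item2 1/3 True
        assert list(report["consensus_label"]) == ["True", "False"]

    def test_person_summary_population_moments(self, small_fit):
        summary = cc.summarize_persons(small_fit)
        persons = summary.persons
        assert {"ability_mean", "willingness_mean", "guess_bias_mean"} <= set(persons)
        pop = summary.population.set_index("parameter")
        assert pop.loc["ability", "mean"] == pytest.approx(
            persons["ability_mean"].mean()
        )
        assert (persons["willingness_mean"] > 0).all()
        assert (persons["willingness_mean"] < 1).all()

    def test_identical_person_draws_have_zero_spread(self):
        theta = np.full((2, 10, 4), 1.3)
        draws = make_draws(theta=theta)
        summary = cc.summarize_persons(draws)
        assert summary.population.set_index("parameter").loc["ability", "sd"] == 0.0
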