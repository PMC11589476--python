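import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from bayesrct.cohort import TrialDataset
from bayesrct.engine import (
    ModelSpec,
    PosteriorDraws,
    diagnose,
    log_partial_likelihood_cox,
    log_posterior_logistic,
    sample,
    save_draws_csv,
)
from bayesrct.priors import PriorSpec, mortality_prior_family

from _oracles import grid_posterior_two_param
from conftest import survival_dataset, two_arm_dataset

SCEPTICAL = mortality_prior_family()["sceptical"]


def empty_dataset() -> TrialDataset:
    return TrialDataset(
        pd.DataFrame({"site_id": [], "arm": [], "death60": []})
    )


class TestLogPosteriorLogistic:
    def test_empty_dataset_equals_joint_log_prior(self):
        model = ModelSpec(site_term="none", treatment_prior=SCEPTICAL)
        value = log_posterior_logistic({"alpha": 0.3, "beta": -0.2}, empty_dataset(), model)
        expected = stats.norm.logpdf(0.3, 0, 2.5) + stats.norm.logpdf(-0.2, 0, 0.355)
        assert value == pytest.approx(expected, abs=1e-10)

    def test_single_record_hand_computation(self):
        # one record (arm=1, death=1) at alpha = beta = 0: Bernoulli(expit(0))
        ds = two_arm_dataset((0, 1), (0, 1))
        model = ModelSpec(site_term="none", treatment_prior=SCEPTICAL)
        value = log_posterior_logistic({"alpha": 0.0, "beta": 0.0}, ds, model)
        expected = (
            np.log(0.5)
            + stats.norm.logpdf(0, 0, 2.5)
            + stats.norm.logpdf(0, 0, 0.355)
        )
        assert value == pytest.approx(expected, abs=1e-10)

    def test_shifting_site_deviations_changes_density(self):
        ds = two_arm_dataset((3, 5), (10, 10))
        model = ModelSpec(treatment_prior=SCEPTICAL)
        base = {"alpha": 0.1, "beta": 0.0, "tau": 0.5, "z": np.array([0.0])}
        shifted = dict(base, z=np.array([1.0]))
        assert log_posterior_logistic(base, ds, model) != log_posterior_logistic(
            shifted, ds, model
        )

    def test_nonfinite_parameters_rejected(self):
        ds = two_arm_dataset((1, 1), (2, 2))
        model = ModelSpec(site_term="none", treatment_prior=SCEPTICAL)
        with pytest.raises(ValueError, match="finite"):
            log_posterior_logistic({"alpha": np.inf, "beta": 0.0}, ds, model)


class TestCoxPartialLikelihood:
    def test_two_subject_hand_computation(self):
        # event times 1 and 2, x = (1, 0), beta = 0: risk sets of size 2 then 1
        ds = survival_dataset([1.0, 2.0], [1, 1], [1, 0])
        assert log_partial_likelihood_cox([0.0], ds) == pytest.approx(-np.log(2))

    def test_beta_zero_independent_of_covariate(self):
        ds_a = survival_dataset([1, 1, 2, 3], [1, 1, 1, 0], [1, 0, 1, 0])
        ds_b = survival_dataset([1, 1, 2, 3], [1, 1, 1, 0], [0, 1, 0, 1])
        assert log_partial_likelihood_cox([0.0], ds_a) == pytest.approx(
            log_partial_likelihood_cox([0.0], ds_b)
        )

    def test_all_censored_rejected(self):
        ds = survival_dataset([5.0, 6.0], [0, 0], [1, 0])
        with pytest.raises(ValueError, match="event"):
            log_partial_likelihood_cox([0.0], ds)

    def test_time_scaling_leaves_partial_likelihood_unchanged(self):
        times = [3.0, 7.0, 12.0, 30.0, 44.0]
        events = [1, 1, 0, 1, 1]
        arms = [1, 0, 1, 0, 1]
        a = survival_dataset(times, events, arms)
        b = survival_dataset([t / 3 for t in times], events, arms)
        for beta in (-0.7, 0.0, 1.2):
            assert log_partial_likelihood_cox([beta], a) == pytest.approx(
                log_partial_likelihood_cox([beta], b)
            )

    def test_efron_map_matches_lifelines_newton_fit(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n = 180
        arms = rng.integers(0, 2, n)
        # day-granularity times produce heavy ties, exercising Efron
        times = np.ceil(rng.exponential(12, n) * np.exp(-0.4 * arms)).clip(1, 60)
        events = (rng.random(n) < 0.8).astype(int)
        ds = survival_dataset(times, events, arms)

        from bayesrct.discharge import build_cox_design

        design = build_cox_design(ds)
        res = minimize(
            lambda b: -design.log_partial_likelihood(design.X @ b),
            np.zeros(design.p),
            method="BFGS",
        )
        df = pd.DataFrame({"T": design.time, "E": design.event.astype(int),
                           "treatment": design.X[:, 0]})
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df, duration_col="T", event_col="E")
        assert abs(res.x[0] - cph.params_["treatment"]) < 1e-4


class TestSampler:
    def test_matches_grid_quadrature_on_two_parameter_model(self):
        # deaths 10/20 (high) vs 5/20 (usual), single site, sceptical prior
        ds = two_arm_dataset((5, 10), (20, 20))
        model = ModelSpec(site_term="none", treatment_prior=SCEPTICAL)
        draws = sample(model, ds, n_chains=4, n_iterations=6000, warmup=2500, seed=3)
        beta = draws.stacked("beta")
        _, _, quantile, p_pos = grid_posterior_two_param((5, 10), (20, 20), 0.0, 0.355)
        for q in (0.025, 0.5, 0.975):
            assert abs(np.quantile(beta, q) - quantile(q)) < 0.02
        assert abs((beta > 0).mean() - p_pos) < 0.01

    def test_same_seed_gives_identical_draws(self):
        ds = two_arm_dataset((3, 6), (15, 15))
        model = ModelSpec(treatment_prior=SCEPTICAL)
        a = sample(model, ds, n_chains=2, n_iterations=200, warmup=200, seed=5)
        b = sample(model, ds, n_chains=2, n_iterations=200, warmup=200, seed=5)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_prior_dominance_on_empty_dataset(self):
        model = ModelSpec(site_term="none", treatment_prior=SCEPTICAL)
        draws = sample(model, empty_dataset(), n_chains=4, n_iterations=5000,
                       warmup=2000, seed=8)
        beta = draws.stacked("beta")
        assert np.median(beta) == pytest.approx(0.0, abs=0.02)
        assert np.std(beta) == pytest.approx(0.355, abs=0.02)
        assert np.quantile(beta, 0.975) == pytest.approx(1.96 * 0.355, abs=0.04)

    def test_posterior_contraction_on_replicated_data(self):
        prior = PriorSpec("weakly_informative", 0.0, 2.5)
        model = ModelSpec(site_term="none", treatment_prior=prior)
        ds1 = two_arm_dataset((60, 75), (200, 200))
        ds2 = two_arm_dataset((120, 150), (400, 400))  # every record duplicated
        sd = []
        for ds in (ds1, ds2):
            draws = sample(model, ds, n_chains=4, n_iterations=4000, warmup=2000, seed=4)
            sd.append(np.std(draws.stacked("beta")))
        assert 0.65 < sd[1] / sd[0] < 0.75

    def test_single_chain_rejected(self):
        ds = two_arm_dataset((1, 1), (4, 4))
        with pytest.raises(ValueError, match="chains"):
            sample(ModelSpec(site_term="none"), ds, n_chains=1, n_iterations=10)


class TestDiagnostics:
    def _draws_from_array(self, arr):
        return PosteriorDraws(draws={"beta": arr}, meta={"acceptance_rate": {}})

    def test_iid_chains_have_rhat_near_one_and_full_ess(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 2000))
        diag = diagnose(self._draws_from_array(arr))
        assert 1.0 <= diag.rhat["beta"] < 1.01
        # ESS of i.i.d. draws is close to the number of draws
        assert diag.ess_bulk["beta"] == pytest.approx(8000, rel=0.2)
        assert diag.acceptable

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 1000))
        arr[0] -= 5
        arr[1] += 5
        diag = diagnose(self._draws_from_array(arr))
        assert diag.rhat["beta"] > 1.1
        assert not diag.acceptable

    def test_single_chain_rejected(self):
        arr = np.random.default_rng(2).standard_normal((1, 100))
        with pytest.raises(ValueError, match="chains"):
            diagnose(self._draws_from_array(arr))


def test_draws_persist_to_long_csv(tmp_path):
    ds = two_arm_dataset((2, 4), (10, 10))
    draws = sample(ModelSpec(treatment_prior=SCEPTICAL), ds, n_chains=2,
                   n_iterations=50, warmup=100, seed=1)
    path = tmp_path / "draws.csv"
    save_draws_csv(draws, path)
    back = pd.read_csv(path)
    assert set(back.columns) == {"chain", "iteration", "parameter", "value"}
    assert {"alpha", "beta", "tau", "z[0]"} <= set(back.parameter.unique())
    assert len(back) == 2 * 50 * (3 + draws.draws["z"].shape[2])
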