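import math

import numpy as np
import pytest
from scipy import integrate

from volprior.fitting import (
    DEFAULT_PRIORS,
    RW_SOFTMAX,
    STATIC_SOFTMAX,
    BlockData,
    ModelSpec,
    PriorSpec,
    fit_block,
    fit_dataset,
    laplace_lme,
    neg_log_joint,
    to_native,
    to_unconstrained,
)
from volprior.response_models import ChoiceSeries, SoftmaxParams, simulate_choices
from volprior.rw_core import PerceptualParams, rw_filter


def simulated_block(alpha, beta, T=80, seed=0, v0=0.5):
    rng = np.random.default_rng(seed)
    u = (rng.random(T) < 0.7).astype(int)
    traj = rw_filter(u, PerceptualParams(alpha, v0))
    choices = simulate_choices(traj, SoftmaxParams(beta), rng)
    return BlockData(u=u, response=choices)


class TestTransforms:
    @pytest.mark.parametrize("name,value", [
        ("alpha", 0.37), ("beta", 4.2), ("sigma_rs", 0.15),
        ("zeta1", -1.3), ("zeta2", 0.0),
    ])
    def test_round_trip(self, name, value):
        theta = to_unconstrained([name], {name: value})
        assert to_native([name], theta)[name] == pytest.approx(value, abs=1e-10)

    def test_native_domains_guaranteed(self):
        extreme = np.array([-50.0, 50.0])
        for x in extreme:
            nat = to_native(["alpha", "beta"], [x, x])
            assert 0.0 <= nat["alpha"] <= 1.0
            assert nat["beta"] >= 0.0


class TestNegLogJoint:
    def test_prior_only_at_mean_with_empty_data(self):
        """With all trials masked, the objective is the negative log prior."""
        priors = PriorSpec()
        data = BlockData(
            u=np.ones(5, int),
            response=ChoiceSeries(i=np.ones(5, int), response_made=np.zeros(5, bool)),
        )
        theta = np.array([priors.mean(n) for n in RW_SOFTMAX.free])
        expected = sum(
            0.5 * math.log(2 * math.pi * priors.var(n)) for n in RW_SOFTMAX.free
        )
        assert neg_log_joint(theta, data, RW_SOFTMAX, priors) == pytest.approx(expected)

    def test_tight_prior_dominates_objective(self):
        tight = PriorSpec({"alpha": (0.0, 1e-8), "beta": (0.0, 4.0)})
        data = simulated_block(0.4, 4.0, seed=1)
        base = np.array([0.0, 0.0])
        moved = np.array([0.1, 0.0])
        diff = neg_log_joint(moved, data, RW_SOFTMAX, tight) - neg_log_joint(
            base, data, RW_SOFTMAX, tight
        )
        assert diff > 1e4  # quadratic penalty swamps any likelihood change

    def test_flat_prior_argmin_matches_grid_mle(self):
        """1-D problem (beta free): near-flat prior MAP equals the grid-search MLE."""
        flat = PriorSpec({"beta": (0.0, 1e6)})
        data = simulated_block(0.0, 3.0, T=200, seed=2)
        grid = np.linspace(-2, 3, 4001)
        vals = [neg_log_joint(np.array([g]), data, STATIC_SOFTMAX, flat) for g in grid]
        g_best = grid[int(np.argmin(vals))]
        fit = fit_block(data, STATIC_SOFTMAX, flat, n_starts=4, seed=0)
        assert fit.unconstrained_estimates[0] == pytest.approx(g_best, abs=2e-3)


class TestFitBlock:
    def test_determinism(self):
        data = simulated_block(0.4, 4.0, seed=5)
        a = fit_block(data, RW_SOFTMAX, seed=11)
        b = fit_block(data, RW_SOFTMAX, seed=11)
        assert a.map_estimates == b.map_estimates
        assert a.lme == b.lme

    def test_native_domains(self):
        data = simulated_block(0.6, 2.0, seed=6)
        fit = fit_block(data, RW_SOFTMAX, seed=0)
        assert 0.0 <= fit.map_estimates["alpha"] <= 1.0
        assert fit.map_estimates["beta"] > 0.0

    def test_uninformative_data_shrinks_alpha_to_prior(self):
        """Incompressible alternating choices drive beta to ~0, leaving the
        likelihood flat in alpha, so the alpha MAP falls back to its prior mean."""
        data = BlockData(u=np.ones(80, int),
                         response=ChoiceSeries(i=np.tile([1, 0], 40)))
        fit = fit_block(data, RW_SOFTMAX, seed=0)
        prior_alpha = to_native(["alpha"], [DEFAULT_PRIORS["alpha"][0]])["alpha"]
        assert fit.map_estimates["beta"] < 0.5
        assert fit.map_estimates["alpha"] == pytest.approx(prior_alpha, abs=0.05)

    def test_gradient_near_zero_at_optimum(self):
        data = simulated_block(0.4, 4.0, seed=7)
        priors = PriorSpec()
        fit = fit_block(data, RW_SOFTMAX, priors, seed=0)
        theta = fit.unconstrained_estimates
        eps = 1e-5
        for k in range(len(theta)):
            e = np.zeros_like(theta)
            e[k] = eps
            g = (
                neg_log_joint(theta + e, data, RW_SOFTMAX, priors)
                - neg_log_joint(theta - e, data, RW_SOFTMAX, priors)
            ) / (2 * eps)
            assert abs(g) < 1e-3

    def test_recovers_generating_alpha_on_average(self):
        errs = []
        for seed in range(20):
            data = simulated_block(0.4, 4.0, seed=seed)
            fit = fit_block(data, RW_SOFTMAX, seed=seed)
            errs.append(fit.map_estimates["alpha"] - 0.4)
        assert abs(np.mean(errs)) < 0.15

    def test_insufficient_trials_error(self):
        data = BlockData(u=np.ones(5, int), response=ChoiceSeries(i=np.ones(5, int)))
        with pytest.raises(ValueError):
            fit_block(data, RW_SOFTMAX)


class TestLaplaceLme:
    def test_exact_for_gaussian_toy(self):
        """For a pure Gaussian log joint the Laplace integral is exact."""
        var = 0.5
        logZ_true = 0.5 * math.log(2 * math.pi * var)  # integral of exp(-x^2/(2 var))
        lme = laplace_lme(0.0, np.array([[1.0 / var]]))
        assert lme == pytest.approx(logZ_true, abs=1e-12)

    def test_within_half_nat_of_quadrature_1d(self):
        """Static-belief model (beta free, v0=0.7): Laplace vs numerical marginal."""
        model = ModelSpec("static_v07", "softmax", ("beta",), fixed={"alpha": 0.0},
                          v0=0.7)
        priors = PriorSpec({"beta": DEFAULT_PRIORS["beta"]})
        data = simulated_block(0.0, 2.5, T=80, seed=3, v0=0.7)
        fit = fit_block(data, model, priors, seed=0)
        # factor out the MAP value so the integrand is O(1)
        m = neg_log_joint(fit.unconstrained_estimates, data, model, priors)
        quad, _ = integrate.quad(
            lambda x: math.exp(m - neg_log_joint(np.array([x]), data, model, priors)),
            -10, 10,
        )
        assert fit.lme == pytest.approx(math.log(quad) - m, abs=0.5)

    def test_tight_irrelevant_parameter_leaves_lme_unchanged(self):
        """Adding a parameter pinned by its prior changes the evidence by ~0."""
        data = simulated_block(0.0, 2.5, T=80, seed=4, v0=0.7)
        m1 = ModelSpec("m1", "softmax", ("beta",), fixed={"alpha": 0.0}, v0=0.7)
        p1 = PriorSpec({"beta": (0.0, 4.0)})
        # alpha free but pinned at logit scale -20 (native ~ 0) with tiny variance
        m2 = ModelSpec("m2", "softmax", ("beta", "alpha"), v0=0.7)
        p2 = PriorSpec({"beta": (0.0, 4.0), "alpha": (-20.0, 1e-6)})
        f1 = fit_block(data, m1, p1, seed=0)
        f2 = fit_block(data, m2, p2, seed=0)
        assert f2.lme == pytest.approx(f1.lme, abs=0.1)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            laplace_lme(0.0, np.array([[-1.0]]))


class TestFitDataset:
    def test_bookkeeping_and_roundtrip(self, small_study, predictive_fits, tmp_path):
        _, _, trials = small_study
        n_participants = trials["participant"].nunique()
        rw = predictive_fits[predictive_fits["model"] == "rw_softmax"]
        assert len(rw) == n_participants * 4
        # JSON round-trip is lossless
        import json

        path = tmp_path / "fits.json"
        with open(path, "w") as fh:
            json.dump(predictive_fits.to_dict(orient="records"), fh, default=float)
        back = json.load(open(path))
        assert len(back) == len(predictive_fits)
        assert back[0]["lme"] == pytest.approx(predictive_fits["lme"].iloc[0])

    def test_condition_ordering_recovered(self, small_study, predictive_fits,
                                          small_population):
        """Mean fitted alpha preserves the generative cell ordering (rev true > false)."""
        _, pop = small_population
        rw = predictive_fits[predictive_fits["model"] == "rw_softmax"]
        merged = rw.merge(
            pop[["participant", "environment", "prior", "alpha_predictive"]],
            on=["participant", "environment", "prior"],
        )
        cells = merged.groupby(["environment", "prior"])[["alpha", "alpha_predictive"]].mean()
        fitted = cells["alpha"]
        true = cells["alpha_predictive"]
        assert (
            (fitted["reversal"]["true"] > fitted["reversal"]["false"])
            == (true["reversal"]["true"] > true["reversal"]["false"])
        )
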