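"""Simulation-based validation: parameter recovery, posterior-predictive
checks, and re-analysis of simulated data with the model-free battery.

Recovery quality is scored per condition and parameter by the Pearson
correlation r between generating and recovered values across participants,
averaged over seeded simulation replicates, and converted to Cohen's
f^2 = r^2 / (1 - r^2); f^2 >= 0.35 counts as good recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior_metrics, stats, synthetic_data
from .fitting import RW_SOFTMAX, PriorSpec, fit_dataset
from .response_models import SoftmaxParams, simulate_choices
from .rw_core import PerceptualParams, rw_filter
from .stats import pearson_r

F2_CRITERION = 0.35


def cohens_f2(r: float) -> float:
    """Effect-size transform f^2 = r^2 / (1 - r^2)."""
    return r**2 / (1.0 - r**2)


@dataclass
class RecoveryResult:
    table: pd.DataFrame          # condition x parameter: mean_r, cohens_f2, pass
    n_replicates: int
    per_replicate: pd.DataFrame  # replicate-level correlations

    def min_f2(self) -> float:
        return float(self.table["cohens_f2"].min())

    def all_pass(self) -> bool:
        return bool(self.table["pass"].all())


def parameter_recovery(
    population_spec: synthetic_data.PopulationSpec | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    task: str = "predictive",
    parameters: tuple[str, ...] = ("alpha", "beta"),
    priors: PriorSpec | None = None,
    n_starts: int = 8,
    f2_criterion: float = F2_CRITERION,
) -> RecoveryResult:
    """Simulate-and-refit recovery study for the predictive-task RW model.

    One population of generating parameters is sampled; ``n_replicates``
    datasets are simulated from it with distinct seeds, each refit blockwise,
    and true-vs-recovered correlations are computed per condition across
    participants, then averaged over replicates.
    """
    if task != "predictive":
        raise NotImplementedError("recovery is implemented for the predictive task")
    spec = population_spec or synthetic_data.PopulationSpec()
    rng = np.random.default_rng(seed)
    population = synthetic_data.sample_population(spec, int(rng.integers(2**31 - 1)))
    if population["alpha_predictive"].std() == 0 or population["beta"].std() == 0:
        raise ValueError("degenerate population: zero spread in generating parameters")

    truth = population.rename(
        columns={"alpha_predictive": "true_alpha", "beta": "true_beta"}
    )[["participant", "environment", "prior", "true_alpha", "true_beta"]]

    rep_rows = []
    for rep in range(n_replicates):
        sim_seed = int(rng.integers(2**31 - 1))
        fit_seed = int(rng.integers(2**31 - 1))
        trials = synthetic_data.simulate_study(
            population, sim_seed, tasks=("predictive",), spec=spec
        )
        fits = fit_dataset(trials, [RW_SOFTMAX], priors, seed=fit_seed,
                           n_starts=n_starts)
        merged = fits.merge(truth, on=["participant", "environment", "prior"])
        for (env, prior), g in merged.groupby(["environment", "prior"]):
            for par in parameters:
                r, _ = pearson_r(g[f"true_{par}"], g[par])
                rep_rows.append(
                    {
                        "replicate": rep,
                        "environment": env,
                        "prior": prior,
                        "parameter": par,
                        "r": r,
                    }
                )
    per_rep = pd.DataFrame(rep_rows)
    table = (
        per_rep.groupby(["environment", "prior", "parameter"])["r"]
        .mean().rename("mean_r").reset_index()
    )
    table["cohens_f2"] = table["mean_r"].apply(cohens_f2)
    table["pass"] = table["cohens_f2"] >= f2_criterion
    return RecoveryResult(table=table, n_replicates=n_replicates, per_replicate=per_rep)


def posterior_predictive_bins(
    trials: pd.DataFrame,
    fits: pd.DataFrame,
    n_bins: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs model-simulated choice means per belief bin.

    Beliefs are the fitted model's predictions v_hat; trials are grouped into
    ``n_bins`` equal-width bins on [0, 1], observed and simulated responses are
    averaged per bin within subject and then across subjects.
    """
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pred = trials[trials["task"] == "predictive"]
    per_subject = []
    for (pid, block), g in pred.groupby(["participant", "block_index"]):
        g = g.sort_values("trial")
        fit = fits[
            (fits["participant"] == pid)
            & (fits["block_index"] == block)
            & (fits["model"] == RW_SOFTMAX.name)
        ]
        if fit.empty:
            raise ValueError(f"no rw_softmax fit for participant {pid} block {block}")
        alpha = float(fit["alpha"].iloc[0])
        beta = float(fit["beta"].iloc[0])
        u = g["u"].to_numpy(dtype=int)
        traj = rw_filter(u, PerceptualParams(alpha))
        sim = simulate_choices(traj, SoftmaxParams(beta), rng)
        bins = np.clip(np.digitize(traj.v_hat, edges[1:-1]), 0, n_bins - 1)
        obs = g["choice_coded"].to_numpy(dtype=float)
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                per_subject.append(
                    {
                        "participant": pid,
                        "bin": b + 1,
                        "observed": float(np.nanmean(obs[sel])),
                        "simulated": float(sim.i[sel].mean()),
                        "n_trials": int(sel.sum()),
                    }
                )
    subj = pd.DataFrame(per_subject)
    subj_means = subj.groupby(["participant", "bin"])[["observed", "simulated"]].mean()
    group = subj_means.groupby("bin").agg(["mean", "sem", "count"])
    group.columns = ["_".join(c) for c in group.columns]
    return group.reset_index()


def simulate_and_reanalyze(
    fits: pd.DataFrame,
    seed: int = 0,
    spec: synthetic_data.PopulationSpec | None = None,
) -> dict:
    """Generate one dataset from fitted parameters and rerun the model-free suite.

    Takes a predictive-task fit table (rw_softmax rows), treats the per-block
    MAP estimates as generative parameters, simulates one study with the same
    design, and returns choice probabilities, switch rates and the factorial
    ANOVA on the simulated data.
    """
    spec = spec or synthetic_data.PopulationSpec()
    rw = fits[fits["model"] == RW_SOFTMAX.name]
    population = rw.rename(
        columns={"alpha": "alpha_predictive"}
    )[["participant", "environment", "prior", "alpha_predictive", "beta"]].copy()
    # reactive-side parameters are irrelevant here but the simulator expects them
    population["alpha_reactive"] = population["alpha_predictive"]
    population["zeta1"] = spec.zeta1_mean
    population["zeta2"] = spec.zeta2_mean
    population["sigma_rs"] = float(np.exp(spec.sigma_rs_log_mean))
    sim = synthetic_data.simulate_study(population, seed, tasks=("predictive",),
                                        spec=spec)
    cp = behavior_metrics.choice_probability(sim)
    sw = behavior_metrics.switch_rates(sim)
    anova = stats.rm_anova(cp, dv="choice_prob",
                           within=["phase", "environment", "prior"])
    return {"trials": sim, "choice_probability": cp, "switch_rates": sw,
            "anova_choice_prob": anova}
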