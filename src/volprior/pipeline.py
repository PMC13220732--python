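"""End-to-end orchestration: simulate (or load) a study, run model-free
metrics, model fits, Bayesian model selection, group statistics and
posterior-predictive checks, and write a plain-text result bundle.

Every stochastic stage derives its seed deterministically from the run seed,
so a rerun with the same config reproduces every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_metrics, model_selection, stats, synthetic_data, validation
from .fitting import RW_LINEAR_RS, RW_SOFTMAX, STATIC_LINEAR_RS, STATIC_SOFTMAX, fit_dataset

log = logging.getLogger("volprior")


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "volprior_run"
    input_trials: str | None = None     # path to a trial table; None -> simulate
    n_participants: int = 32
    tasks: tuple[str, ...] = ("reactive", "predictive")
    n_starts: int = 8
    run_recovery: bool = False
    recovery_replicates: int = 20
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg["tasks"] = tuple(cfg.get("tasks", ("reactive", "predictive")))
        return cls(**cfg)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the result bundle to config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31 - 1))
             for k in ("simulate", "fit", "bms", "ppc", "recovery")}
    results: dict = {"config_hash": config.config_hash()}

    # ------------------------------------------------------------ stage: data
    if config.input_trials:
        trials = pd.read_csv(config.input_trials, sep=None, engine="python")
        log.info("loaded %d trials from %s", len(trials), config.input_trials)
    else:
        spec = synthetic_data.PopulationSpec(n_participants=config.n_participants)
        population = synthetic_data.sample_population(spec, seeds["simulate"])
        population.to_csv(out / "population_ground_truth.csv", index=False)
        trials = synthetic_data.simulate_study(
            population, seeds["simulate"] + 1, tasks=config.tasks, spec=spec
        )
        log.info("simulated %d trials for %d participants",
                 len(trials), config.n_participants)
    trials.to_csv(out / "trials.csv", index=False)
    results["n_trials"] = len(trials)

    # --------------------------------------------------------- stage: metrics
    reactive = trials[trials["task"] == "reactive"]
    predictive = trials[trials["task"] == "predictive"]
    metrics: dict[str, pd.DataFrame] = {}
    if len(reactive):
        masked = behavior_metrics.exclude_rt_outliers(reactive)
        metrics["cueing_effects"] = behavior_metrics.cueing_effects(masked)
    if len(predictive):
        metrics["choice_probability"] = behavior_metrics.choice_probability(predictive)
        metrics["switch_rates"] = behavior_metrics.switch_rates(predictive)
    for name, df in metrics.items():
        df.to_csv(out / f"{name}.csv", index=False)
    results["metrics"] = metrics

    # -------------------------------------------------------------- stage: fit
    fit_frames = []
    if len(predictive):
        fit_frames.append(fit_dataset(predictive, [RW_SOFTMAX, STATIC_SOFTMAX],
                                      seed=seeds["fit"], n_starts=config.n_starts))
    if len(reactive):
        fit_frames.append(fit_dataset(reactive, [RW_LINEAR_RS, STATIC_LINEAR_RS],
                                      seed=seeds["fit"], n_starts=config.n_starts))
    fits = pd.concat(fit_frames, ignore_index=True)
    fits.to_csv(out / "fits.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump(fits.to_dict(orient="records"), fh, indent=1, default=str)
    results["fits"] = fits

    # -------------------------------------------------------------- stage: bms
    bms_out = {}
    for task, models in (
        ("predictive", [RW_SOFTMAX.name, STATIC_SOFTMAX.name]),
        ("reactive", [RW_LINEAR_RS.name, STATIC_LINEAR_RS.name]),
    ):
        sub = fits[fits["task"] == task] if "task" in fits else fits
        if not len(sub):
            continue
        lme, _ = model_selection.lme_matrix(sub, models)
        bms = model_selection.rfx_bms(lme, seed=seeds["bms"])
        bms_out[task] = {"models": models, **bms.to_dict()}
    with open(out / "bms.json", "w") as fh:
        json.dump(bms_out, fh, indent=1)
    results["bms"] = bms_out

    # ------------------------------------------------------------ stage: stats
    stats_out = {}
    if "choice_probability" in metrics:
        stats_out["anova_choice_prob"] = stats.rm_anova(
            metrics["choice_probability"], dv="choice_prob",
            within=["phase", "environment", "prior"],
        )
    if "cueing_effects" in metrics:
        ce = metrics["cueing_effects"].dropna(subset=["rt_ce"])
        stats_out["anova_rt_ce"] = stats.rm_anova(
            ce, dv="rt_ce", within=["phase", "environment", "prior"]
        )
    for name, df in stats_out.items():
        df.to_csv(out / f"{name}.csv", index=False)
    results["stats"] = stats_out

    # -------------------------------------------------------------- stage: ppc
    if len(predictive):
        ppc = validation.posterior_predictive_bins(trials, fits, seed=seeds["ppc"])
        ppc.to_csv(out / "posterior_predictive_bins.csv", index=False)
        results["ppc"] = ppc

    # --------------------------------------------------------- stage: recovery
    if config.run_recovery:
        rec = validation.parameter_recovery(
            synthetic_data.PopulationSpec(n_participants=config.n_participants),
            n_replicates=config.recovery_replicates,
            seed=seeds["recovery"], n_starts=config.n_starts,
        )
        rec.table.to_csv(out / "parameter_recovery.csv", index=False)
        results["recovery"] = rec

    if config.make_figures:
        try:
            _figures(out, trials, results)
        except Exception as exc:  # plotting must never sink a run
            log.warning("figure generation failed: %s", exc)

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "config_hash": results["config_hash"],
                "stage_seeds": seeds,
                "outputs": sorted(p.name for p in out.iterdir()),
            },
            fh, indent=1, default=str,
        )
    return results


def _figures(out: Path, trials: pd.DataFrame, results: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .rw_core import PerceptualParams, rw_filter

    pred = trials[trials["task"] == "predictive"]
    if not len(pred):
        return
    pid = pred["participant"].iloc[0]
    one = pred[(pred["participant"] == pid)
               & (pred["environment"] == "reversal")].sort_values("trial")
    block = one[one["block_index"] == one["block_index"].iloc[0]]
    u = block["u"].to_numpy(dtype=int)
    traj = rw_filter(u, PerceptualParams(0.4))
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(np.arange(1, len(u) + 1), traj.v_post, label="belief v")
    ax.scatter(np.arange(1, len(u) + 1), u, s=8, c="firebrick", label="outcome u")
    ax.set(xlabel="trial", ylabel="P(initial contingency outcome)",
           title="RW belief trajectory, reversal block")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "belief_trajectory.png", dpi=120)
    plt.close(fig)
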