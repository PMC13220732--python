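"""Synthetic study generator.

Emulates the study conditions end to end — 32 participants, two task versions
sharing identical trial sequences, four 80-trial blocks crossing environment
(stable/reversal) with prior truth (true/false) at a 0.7 contingency — with
behavior generated by the Rescorla-Wagner filter coupled to the task-specific
response models. Generative parameters are sampled per participant and
condition cell on their transformed scales (logit for alpha, log for beta and
sigma_rs), so native-space constraints hold by construction.

Default cell means encode the qualitative effect directions of interest:
lower predictive-task alpha under a false prior in the reversal environment,
and lower beta (noisier choices, more switching) under a false prior in the
stable environment. These are synthetic population values, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import task_design
from .response_models import (
    LinearRSParams,
    SoftmaxParams,
    simulate_choices,
    simulate_response_speeds,
)
from .rw_core import PerceptualParams, code_outcomes, rw_filter

CELLS = task_design.CONDITION_CELLS


def _logit(p: float) -> float:
    return float(logit(p))


@dataclass(frozen=True)
class PopulationSpec:
    """Generative population: per-cell parameter means (transformed scale) + SDs."""

    n_participants: int = 32
    # predictive task: learning rate (logit scale) per (environment, prior) cell
    alpha_predictive_logit_mean: dict = field(
        default_factory=lambda: {
            ("stable", "true"): _logit(0.35),
            ("stable", "false"): _logit(0.35),
            ("reversal", "true"): _logit(0.5),
            ("reversal", "false"): _logit(0.3),
        }
    )
    alpha_logit_sd: float = 0.7
    # predictive task: inverse decision noise (log scale) per cell
    beta_log_mean: dict = field(
        default_factory=lambda: {
            ("stable", "true"): float(np.log(6.0)),
            ("stable", "false"): float(np.log(3.0)),
            ("reversal", "true"): float(np.log(4.5)),
            ("reversal", "false"): float(np.log(4.5)),
        }
    )
    beta_log_sd: float = 0.5
    # reactive task: faster updating overall, no cell differences by default
    alpha_reactive_logit_mean: dict = field(
        default_factory=lambda: {cell: _logit(0.6) for cell in CELLS}
    )
    # reactive response-speed model (RS ~ 2 /s, i.e. RT ~ 500 ms)
    zeta1_mean: float = 2.0
    zeta1_sd: float = 0.2
    zeta2_mean: float = 0.5
    zeta2_sd: float = 0.15
    sigma_rs_log_mean: float = float(np.log(0.2))
    sigma_rs_log_sd: float = 0.3
    # accuracy side-model and omissions
    accuracy_intercept: float = 0.90
    accuracy_slope: float = 0.07
    omission_rate: float = 0.0
    contingency: float = 0.7
    n_trials: int = 80


def sample_population(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Ground-truth parameter table: one row per participant x condition cell."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, spec.n_participants + 1):
        # response-speed parameters are participant-level (shared across cells)
        zeta1 = rng.normal(spec.zeta1_mean, spec.zeta1_sd)
        zeta2 = rng.normal(spec.zeta2_mean, spec.zeta2_sd)
        sigma_rs = float(np.exp(rng.normal(spec.sigma_rs_log_mean, spec.sigma_rs_log_sd)))
        for cell in CELLS:
            env, prior = cell
            rows.append(
                {
                    "participant": pid,
                    "environment": env,
                    "prior": prior,
                    "alpha_predictive": float(
                        expit(rng.normal(spec.alpha_predictive_logit_mean[cell],
                                         spec.alpha_logit_sd))
                    ),
                    "beta": float(
                        np.exp(rng.normal(spec.beta_log_mean[cell], spec.beta_log_sd))
                    ),
                    "alpha_reactive": float(
                        expit(rng.normal(spec.alpha_reactive_logit_mean[cell],
                                         spec.alpha_logit_sd))
                    ),
                    "zeta1": float(zeta1),
                    "zeta2": float(zeta2),
                    "sigma_rs": sigma_rs,
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    population: pd.DataFrame,
    seed: int,
    tasks: tuple[str, ...] = ("reactive", "predictive"),
    spec: PopulationSpec | None = None,
) -> pd.DataFrame:
    """Simulate full trial tables for every participant and requested task.

    Per participant: build the session (block order and trial sequences are a
    function of the participant seed only, hence identical across tasks), run
    the RW filter on the coded outcomes with the cell's generative learning
    rate, and draw responses from the task's response model.
    """
    spec = spec or PopulationSpec()
    master = np.random.default_rng(seed)
    frames = []
    for pid, params in population.groupby("participant", sort=True):
        cell_params = {
            (r["environment"], r["prior"]): r for _, r in params.iterrows()
        }
        participant_seed = int(master.integers(0, 2**31 - 1))
        behav_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        for task in tasks:
            session, sequences = task_design.build_session(
                task, participant_seed,
                contingency=spec.contingency, n_trials=spec.n_trials,
            )
            table = task_design.session_to_frame(session, sequences, pid)
            table = _simulate_responses_for_session(
                table, session, sequences, cell_params, task, behav_rng, spec
            )
            frames.append(table)
    return pd.concat(frames, ignore_index=True)


def _simulate_responses_for_session(
    table: pd.DataFrame,
    session,
    sequences,
    cell_params: dict,
    task: str,
    rng: np.random.Generator,
    spec: PopulationSpec,
) -> pd.DataFrame:
    n = spec.n_trials
    choice_coded = np.full(len(table), np.nan)
    rt_ms = np.full(len(table), np.nan)
    correct = np.full(len(table), np.nan)
    made = np.ones(len(table), dtype=bool)
    for b, (block, seq) in enumerate(zip(session.blocks, sequences)):
        sl = slice(b * n, (b + 1) * n)
        p = cell_params[(block.environment, block.prior_truth)]
        u = code_outcomes(seq)
        if task == "predictive":
            traj = rw_filter(u, PerceptualParams(p["alpha_predictive"]))
            choices = simulate_choices(
                traj, SoftmaxParams(p["beta"]), rng,
                omission_rate=spec.omission_rate,
            )
            choice_coded[sl] = choices.i
            # prediction matches the target iff coded choice equals coded outcome
            correct[sl] = (choices.i == u).astype(float)
            made[sl] = choices.response_made
        else:
            traj = rw_filter(u, PerceptualParams(p["alpha_reactive"]))
            rs = simulate_response_speeds(
                traj, u,
                LinearRSParams(p["zeta1"], p["zeta2"], p["sigma_rs"]), rng,
                accuracy_intercept=spec.accuracy_intercept,
                accuracy_slope=spec.accuracy_slope,
                omission_rate=spec.omission_rate,
            )
            rt_ms[sl] = 1000.0 / rs.rs
            correct[sl] = rs.correct
            made[sl] = rs.valid_mask
    table = table.copy()
    table["response_made"] = made
    table["choice_coded"] = choice_coded
    table["rt_ms"] = rt_ms
    table["correct"] = correct
    return table
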