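"""Response models mapping beliefs to behavior.

Predictive task: a binary softmax over the belief difference,

    P(i_t = 1) = 1 / (1 + exp(-beta * (v_hat_t - (1 - v_hat_t)))),

with inverse decision noise ``beta`` (higher beta, more deterministic choices).

Reactive task: response speed RS = 1/RT (in 1/s) is affine in the belief about
the presented location,

    RS_t = u_t (zeta1 + zeta2 * v_hat_t) + (1 - u_t) (zeta1 + zeta2 * (1 - v_hat_t)),

with Gaussian observation noise of SD ``sigma_rs`` around that mean (the linear
model needs a noise distribution to define a likelihood; Gaussian residuals are
the conventional choice for speed-transformed reaction times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .rw_core import BeliefTrajectory

_LOG_HALF = float(np.log(0.5))


@dataclass(frozen=True)
class SoftmaxParams:
    beta: float  # inverse decision noise, > 0 (0 accepted as the chance limit)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass(frozen=True)
class LinearRSParams:
    zeta1: float        # intercept, response-speed units (1/s)
    zeta2: float        # slope per unit belief
    sigma_rs: float     # residual SD, response-speed units

    def __post_init__(self) -> None:
        if self.sigma_rs <= 0:
            raise ValueError("sigma_rs must be positive")


@dataclass
class ChoiceSeries:
    """Predictive-task choices, constant-coded like u (1 = matches initial contingency)."""

    i: np.ndarray
    response_made: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        if self.response_made is None:
            self.response_made = np.ones_like(self.i, dtype=bool)
        else:
            self.response_made = np.asarray(self.response_made, dtype=bool)


@dataclass
class ResponseSpeedSeries:
    """Reactive-task response speeds with accuracy flags and validity mask."""

    rs: np.ndarray
    correct: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rs = np.asarray(self.rs, dtype=float)
        self.correct = np.asarray(self.correct, dtype=int)
        if self.valid_mask is None:
            self.valid_mask = np.ones_like(self.rs, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)


def softmax_prob(v_hat, beta: float):
    """P(choice i=1) under the binary softmax; symmetric in v_hat <-> 1-v_hat."""
    v_hat = np.asarray(v_hat, dtype=float)
    # argument is beta*(2 v_hat - 1); expit is log-domain safe for extreme beta
    return expit(beta * (2.0 * v_hat - 1.0))


def rs_mean(v_hat, u, params: LinearRSParams):
    """Expected response speed for the presented location."""
    v_hat = np.asarray(v_hat, dtype=float)
    u = np.asarray(u)
    belief_in_presented = np.where(u == 1, v_hat, 1.0 - v_hat)
    return params.zeta1 + params.zeta2 * belief_in_presented


def choice_loglik(choices: ChoiceSeries, v_hat: np.ndarray, beta: float) -> float:
    """Bernoulli log-likelihood of the coded choices under the softmax model."""
    v_hat = np.asarray(v_hat, dtype=float)
    if len(v_hat) != len(choices.i):
        raise ValueError("choice and belief series differ in length")
    mask = choices.response_made
    if not mask.any():
        return 0.0
    if beta == 0.0:
        return float(mask.sum()) * _LOG_HALF
    x = beta * (2.0 * v_hat[mask] - 1.0)  # logit of P(i=1)
    i = choices.i[mask]
    # log P(i) = i*x - log(1+exp(x)), stable via logaddexp
    return float(np.sum(i * x - np.logaddexp(0.0, x)))


def rs_loglik(
    rs: ResponseSpeedSeries, v_hat: np.ndarray, u: np.ndarray, params: LinearRSParams
) -> float:
    """Gaussian log-likelihood of observed response speeds around the linear mean."""
    mask = rs.valid_mask
    mu = rs_mean(v_hat, u, params)
    resid = rs.rs[mask] - mu[mask]
    n = resid.size
    s2 = params.sigma_rs**2
    return float(-0.5 * n * np.log(2.0 * np.pi * s2) - 0.5 * np.sum(resid**2) / s2)


def simulate_choices(
    trajectory: BeliefTrajectory,
    params: SoftmaxParams,
    rng: np.random.Generator,
    omission_rate: float = 0.0,
) -> ChoiceSeries:
    p = softmax_prob(trajectory.v_hat, params.beta)
    i = (rng.random(len(p)) < p).astype(int)
    made = rng.random(len(p)) >= omission_rate
    return ChoiceSeries(i=i, response_made=made)


def simulate_response_speeds(
    trajectory: BeliefTrajectory,
    u: np.ndarray,
    params: LinearRSParams,
    rng: np.random.Generator,
    accuracy_intercept: float = 0.90,
    accuracy_slope: float = 0.07,
    omission_rate: float = 0.0,
) -> ResponseSpeedSeries:
    """Draw response speeds (truncated-positive Gaussian) and Bernoulli accuracy.

    Accuracy follows p_correct = clip(c0 + c1 * belief-in-presented-location, 0, 1):
    the task fits no accuracy model, but the model-free accuracy pipeline needs
    accuracy data with an expectedness gradient.
    """
    mu = rs_mean(trajectory.v_hat, u, params)
    if np.any(mu <= 0):
        raise ValueError("rs_mean must be positive over the belief range")
    # truncated-at-zero normal via scipy (a = (0 - mu)/sigma)
    a = -mu / params.sigma_rs
    rs = stats.truncnorm.rvs(
        a, np.inf, loc=mu, scale=params.sigma_rs, random_state=rng
    )
    belief_presented = np.where(np.asarray(u) == 1, trajectory.v_hat, 1 - trajectory.v_hat)
    p_corr = np.clip(accuracy_intercept + accuracy_slope * belief_presented, 0.0, 1.0)
    correct = (rng.random(len(mu)) < p_corr).astype(int)
    made = rng.random(len(mu)) >= omission_rate
    return ResponseSpeedSeries(rs=rs, correct=correct, valid_mask=made)


def simulate_responses(
    trajectory: BeliefTrajectory,
    u: np.ndarray,
    response_params,
    task_version: str,
    seed: int | np.random.Generator,
    **kwargs,
):
    """Dispatch simulation by task version ('predictive' -> choices, 'reactive' -> RS)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if task_version == "predictive":
        return simulate_choices(trajectory, response_params, rng, **kwargs)
    if task_version == "reactive":
        return simulate_response_speeds(trajectory, u, response_params, rng, **kwargs)
    raise ValueError(f"unknown task version {task_version!r}")
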