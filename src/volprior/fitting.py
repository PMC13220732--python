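"""MAP estimation of perceptual + response parameters, per block, with a
Laplace approximation to the log model evidence (LME).

Parameters are estimated in an unconstrained space (logit for the learning
rate, log for the inverse decision noise and the residual variance, identity
for the linear-model coefficients) under independent Gaussian priors. The
objective is the negative log joint; the curvature of the log joint at the MAP
yields the Laplace evidence

    LME = log p(y, theta_MAP) + (d/2) log 2*pi - (1/2) log det(-H),

with H the Hessian of the log joint at the optimum.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .response_models import (
    ChoiceSeries,
    LinearRSParams,
    ResponseSpeedSeries,
    choice_loglik,
    rs_loglik,
)
from .rw_core import PerceptualParams, rw_filter

MIN_TRIALS = 10


# ---------------------------------------------------------------- transforms

def _to_native(name: str, x: float) -> float:
    if name == "alpha":
        return float(expit(x))
    if name == "beta":
        return float(np.exp(x))
    if name == "sigma_rs":  # unconstrained coordinate is log sigma^2
        return float(np.exp(0.5 * x))
    return float(x)  # zeta1, zeta2


def _to_unconstrained(name: str, x: float) -> float:
    if name == "alpha":
        return float(logit(x))
    if name == "beta":
        return float(np.log(x))
    if name == "sigma_rs":
        return float(2.0 * np.log(x))
    return float(x)


def to_native(names, theta) -> dict[str, float]:
    return {n: _to_native(n, t) for n, t in zip(names, theta)}


def to_unconstrained(names, values: dict[str, float]) -> np.ndarray:
    return np.array([_to_unconstrained(n, values[n]) for n in names])


# ------------------------------------------------------------------- priors

#: default Gaussian priors in unconstrained space: (mean, variance)
DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "alpha": (float(logit(0.2)), 4.0),
    "beta": (0.0, 4.0),
    "zeta1": (2.0, 4.0),
    "zeta2": (0.0, 4.0),
    "sigma_rs": (float(np.log(0.01)), 4.0),  # prior on log sigma^2
}


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter Gaussian priors in unconstrained space."""

    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS)
    )

    def __post_init__(self) -> None:
        for name, (_, var) in self.params.items():
            if var <= 0:
                raise ValueError(f"prior variance for {name} must be positive")

    def mean(self, name: str) -> float:
        return self.params[name][0]

    def var(self, name: str) -> float:
        return self.params[name][1]


# -------------------------------------------------------------- model specs

@dataclass(frozen=True)
class ModelSpec:
    """One candidate observation model for a block of data.

    ``fixed`` pins parameters at native-space values (excluded from the
    optimization and from the Laplace dimensionality), e.g. the static-belief
    null model fixes alpha = 0 so the belief never moves from v0.
    """

    name: str
    response: str                       # 'softmax' | 'linear_rs'
    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    v0: float = 0.5

    def loglik(self, theta_native: dict[str, float], data: "BlockData") -> float:
        alpha = theta_native.get("alpha", 0.0)
        if alpha == 0.0:
            v_hat = np.full(len(data.u), self.v0)
        else:
            v_hat = rw_filter(data.u, PerceptualParams(alpha, self.v0)).v_hat
        if self.response == "softmax":
            return choice_loglik(data.response, v_hat, theta_native["beta"])
        if self.response == "linear_rs":
            params = LinearRSParams(
                theta_native["zeta1"], theta_native["zeta2"], theta_native["sigma_rs"]
            )
            return rs_loglik(data.response, v_hat, data.u, params)
        raise ValueError(f"unknown response model {self.response!r}")


RW_SOFTMAX = ModelSpec("rw_softmax", "softmax", ("alpha", "beta"))
STATIC_SOFTMAX = ModelSpec("static_softmax", "softmax", ("beta",), fixed={"alpha": 0.0})
RW_LINEAR_RS = ModelSpec(
    "rw_linear_rs", "linear_rs", ("alpha", "zeta1", "zeta2", "sigma_rs")
)
STATIC_LINEAR_RS = ModelSpec(
    "static_linear_rs", "linear_rs", ("zeta1", "zeta2", "sigma_rs"), fixed={"alpha": 0.0}
)


@dataclass
class BlockData:
    """Prepared inputs for one block fit: coded outcomes plus the response series."""

    u: np.ndarray
    response: ChoiceSeries | ResponseSpeedSeries

    @property
    def n_usable(self) -> int:
        if isinstance(self.response, ChoiceSeries):
            return int(self.response.response_made.sum())
        return int(self.response.valid_mask.sum())


@dataclass
class FitResult:
    map_estimates: dict[str, float]
    unconstrained_estimates: np.ndarray
    neg_hessian: np.ndarray
    lme: float
    converged: bool
    n_trials_used: int
    model_id: str
    block_id: object = None
    participant_id: object = None

    def to_record(self) -> dict:
        return {
            "participant": self.participant_id,
            "block": self.block_id,
            "model": self.model_id,
            "params": dict(self.map_estimates),
            "lme": self.lme,
            "converged": self.converged,
            "n_trials_used": self.n_trials_used,
        }


# ---------------------------------------------------------------- objective

def neg_log_joint(
    theta: np.ndarray, data: BlockData, model_spec: ModelSpec, priors: PriorSpec
) -> float:
    """Negative log joint density: -(log-likelihood + log prior)."""
    native = to_native(model_spec.free, theta)
    native.update(model_spec.fixed)
    ll = model_spec.loglik(native, data)
    lp = 0.0
    for name, t in zip(model_spec.free, theta):
        m, v = priors.params[name]
        lp += -0.5 * math.log(2.0 * math.pi * v) - 0.5 * (t - m) ** 2 / v
    return -(ll + lp)


def _fd_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def laplace_lme(
    log_joint_at_map: float, neg_hessian: np.ndarray, d: int | None = None
) -> float:
    """Laplace approximation to the log marginal likelihood.

    Raises on non-positive-definite curvature (the approximation is undefined
    off a local maximum).
    """
    d = neg_hessian.shape[0] if d is None else d
    sign, logdet = np.linalg.slogdet(neg_hessian)
    if sign <= 0:
        raise np.linalg.LinAlgError("neg-Hessian is not positive definite")
    return float(log_joint_at_map + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet)


def fit_block(
    data: BlockData,
    model_spec: ModelSpec,
    priors: PriorSpec | None = None,
    n_starts: int = 8,
    seed: int = 0,
    participant_id=None,
    block_id=None,
) -> FitResult:
    """Multistart MAP fit of one block with Laplace model evidence.

    Starts at the prior mean plus seeded Gaussian jitter (half a prior SD);
    the best local optimum is retained. Deterministic for a fixed seed.
    """
    priors = priors or PriorSpec()
    if data.n_usable < MIN_TRIALS:
        raise ValueError(
            f"needs >= {MIN_TRIALS} usable trials, got {data.n_usable}"
        )
    names = model_spec.free
    mean = np.array([priors.mean(n) for n in names])
    sd = np.sqrt([priors.var(n) for n in names])
    rng = np.random.default_rng(seed)

    def objective(theta):
        return neg_log_joint(theta, data, model_spec, priors)

    best = None
    for s in range(n_starts):
        x0 = mean if s == 0 else mean + 0.5 * sd * rng.standard_normal(len(names))
        res = optimize.minimize(objective, x0, method="BFGS", options={"gtol": 1e-6})
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta_hat = best.x
    neg_h = _fd_hessian(objective, theta_hat)
    converged = bool(np.isfinite(best.fun))
    lme = math.nan
    try:
        lme = laplace_lme(-best.fun, neg_h)
    except np.linalg.LinAlgError:
        converged = False
    native = to_native(names, theta_hat)
    native.update(model_spec.fixed)
    return FitResult(
        map_estimates=native,
        unconstrained_estimates=theta_hat,
        neg_hessian=neg_h,
        lme=lme,
        converged=converged,
        n_trials_used=data.n_usable,
        model_id=model_spec.name,
        block_id=block_id,
        participant_id=participant_id,
    )


# ------------------------------------------------------------ dataset level

def block_data_from_frame(block_df: pd.DataFrame, task: str) -> BlockData:
    """Build BlockData from one block of the standard trial table."""
    u = block_df["u"].to_numpy(dtype=int)
    made = block_df.get("response_made")
    made = made.to_numpy(dtype=bool) if made is not None else np.ones(len(u), bool)
    if task == "predictive":
        choice = block_df["choice_coded"].to_numpy()
        choice = np.where(made, choice, 0).astype(int)
        return BlockData(u=u, response=ChoiceSeries(i=choice, response_made=made))
    rt_s = block_df["rt_ms"].to_numpy(dtype=float) / 1000.0
    rs = np.where(made & (rt_s > 0), 1.0 / np.where(rt_s > 0, rt_s, 1.0), np.nan)
    correct = block_df["correct"].to_numpy()
    mask = made & np.isfinite(rs)
    return BlockData(
        u=u, response=ResponseSpeedSeries(rs=np.nan_to_num(rs, nan=1.0),
                                          correct=correct, valid_mask=mask)
    )


def fit_dataset(
    trials: pd.DataFrame,
    model_specs: list[ModelSpec],
    priors: PriorSpec | None = None,
    seed: int = 0,
    n_starts: int = 8,
) -> pd.DataFrame:
    """Fit every participant x task x block with each candidate model.

    Returns a flat table with one row per fit (native-space estimates, LME,
    convergence flag). Fit seeds are derived deterministically from ``seed``
    and the (participant, block, model) identity.
    """
    rows = []
    for (pid, task, block), block_df in trials.groupby(
        ["participant", "task", "block_index"], sort=True
    ):
        data = block_data_from_frame(block_df, task)
        meta = block_df.iloc[0]
        for spec in model_specs:
            key = f"{seed}|{pid}|{task}|{block}|{spec.name}".encode()
            fit_seed = zlib.crc32(key) & 0x7FFFFFFF
            fit = fit_block(
                data, spec, priors, n_starts=n_starts, seed=fit_seed,
                participant_id=pid, block_id=block,
            )
            row = {
                "participant": pid,
                "task": task,
                "block_index": block,
                "environment": meta.get("environment"),
                "prior": meta.get("prior"),
                "condition": meta.get("condition"),
                "model": spec.name,
                "lme": fit.lme,
                "converged": fit.converged,
                "n_trials_used": fit.n_trials_used,
            }
            row.update(fit.map_estimates)
            rows.append(row)
    return pd.DataFrame(rows)


def fits_to_json(fits: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(fits.to_dict(orient="records"), fh, indent=1, default=float)
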