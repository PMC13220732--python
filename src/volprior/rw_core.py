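"""Rescorla-Wagner belief filter over binary, constant-coded outcomes.

The belief ``v_t`` is the estimated probability that the outcome coded 1 (the
target location favored by the initial cue-target contingency) occurs on trial
t. Updating follows the delta rule

    v_t = v_{t-1} + alpha * (u_t - v_{t-1}),

so the learning rate ``alpha`` weights the trial's prediction error
``delta_t = u_t - v_hat_t`` with ``v_hat_t = v_{t-1}`` the pre-observation
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter


@dataclass(frozen=True)
class PerceptualParams:
    """Learning rate and initial belief of the RW filter."""

    alpha: float
    v0: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 < self.v0 < 1.0):
            raise ValueError("v0 must lie in (0, 1)")


@dataclass
class BeliefTrajectory:
    """Trial-wise predictions, posteriors and prediction errors."""

    v_hat: np.ndarray   # v_hat_t = v_{t-1}, prediction before trial t
    v_post: np.ndarray  # v_t, posterior after trial t
    pe: np.ndarray      # delta_t = u_t - v_hat_t

    def __len__(self) -> int:
        return len(self.v_hat)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "v_hat": self.v_hat,
                "v_post": self.v_post,
                "pe": self.pe,
            }
        )


def code_outcomes(sequence) -> np.ndarray:
    """Binary outcome series coded against the first-half contingency.

    ``u_t = 1`` iff trial t's target falls at the location the initial
    cue-target contingency makes more likely, for the whole block (so trials
    obeying a reversed contingency are coded 0). For a generated
    :class:`~volprior.task_design.TrialSequence` this is the stored ``u``;
    recomputed here from validity and the reversal index so externally loaded
    sequences only need ``valid_now``.
    """
    valid_now = np.asarray(sequence.valid_now, dtype=int)
    r = sequence.spec.reversal_after
    u = valid_now.copy()
    if r is not None:
        u[r:] = 1 - valid_now[r:]
    return u


def rw_filter(u: np.ndarray, params: PerceptualParams) -> BeliefTrajectory:
    """Run the RW delta rule over a binary outcome series.

    ``v_t = (1 - alpha) v_{t-1} + alpha u_t`` is a first-order IIR recursion,
    evaluated with :func:`scipy.signal.lfilter` for speed.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("u must be one-dimensional")
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("u must be binary")
    a = params.alpha
    if a == 0.0:
        v_post = np.full_like(u, params.v0)
    else:
        v_post, _ = lfilter([a], [1.0, -(1.0 - a)], u, zi=[(1.0 - a) * params.v0])
    v_hat = np.empty_like(v_post)
    v_hat[0] = params.v0
    v_hat[1:] = v_post[:-1]
    return BeliefTrajectory(v_hat=v_hat, v_post=v_post, pe=u - v_hat)


def trajectory_frame(
    trajectory: BeliefTrajectory, participant=None, block=None
) -> pd.DataFrame:
    """Tidy export (participant, block, trial, v_hat, v_post, pe)."""
    df = trajectory.to_dataframe()
    if block is not None:
        df.insert(0, "block", block)
    if participant is not None:
        df.insert(0, "participant", participant)
    return df
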