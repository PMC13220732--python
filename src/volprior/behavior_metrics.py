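"""Model-free behavioral measures.

All operations act on the standard trial table (one row per trial with columns
participant, task, block_index, environment, prior, condition, trial, u,
valid_now, phase plus the behavioral columns response_made, choice_coded,
rt_ms, correct). Expectedness is coded against the first-half contingency
throughout, so cueing effects are always "unexpected minus expected" relative
to the initial block rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ------------------------------------------------------------- exclusions

def exclude_rt_outliers(trials: pd.DataFrame, sd_criterion: float = 2.0) -> pd.DataFrame:
    """Mask trials whose RT deviates more than ``sd_criterion`` SDs from the
    participant's mean RT (single pass; statistics over all responded trials
    of that participant and task, not per condition).

    Returns a copy with a boolean ``rt_valid`` column (False for omissions and
    outliers). A degenerate SD of 0 masks nothing.
    """
    out = trials.copy()
    made = out.get("response_made")
    made = made.to_numpy(dtype=bool) if made is not None else np.ones(len(out), bool)
    rt = out["rt_ms"].to_numpy(dtype=float)
    valid = made & np.isfinite(rt)
    out["rt_valid"] = valid
    for (_, _), idx in out.groupby(["participant", "task"]).groups.items():
        sel = out.loc[idx]
        resp = sel["rt_valid"].to_numpy()
        r = sel["rt_ms"].to_numpy(dtype=float)
        if resp.sum() == 0:
            continue
        m = r[resp].mean()
        s = r[resp].std(ddof=1) if resp.sum() > 1 else 0.0
        if s == 0.0:
            continue
        keep = resp & (np.abs(r - m) <= sd_criterion * s)
        out.loc[idx, "rt_valid"] = keep
    return out


def participant_inclusion(
    accuracies: pd.Series | np.ndarray, sd_criterion: float = 2.0
) -> np.ndarray:
    """Inclusion flags: False where a participant's accuracy deviates more than
    ``sd_criterion`` group SDs from the group mean (boundary counts as within)."""
    acc = np.asarray(accuracies, dtype=float)
    if len(acc) < 3:
        raise ValueError("needs at least 3 participants")
    m, s = acc.mean(), acc.std(ddof=1)
    if s == 0.0:
        return np.ones(len(acc), dtype=bool)
    return np.abs(acc - m) <= sd_criterion * s


# ----------------------------------------------------------- cueing effects

def cueing_effects(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "environment", "prior", "phase"),
) -> pd.DataFrame:
    """Reaction-time and accuracy cueing effects per grouping cell.

    rt_ce (ms)   = mean RT(u=0) - mean RT(u=1), over correct, non-outlier,
                   responded trials (requires ``rt_valid`` from
                   :func:`exclude_rt_outliers`).
    acc_ce (pts) = %correct(u=0) - %correct(u=1), over responded trials.

    Cells with an empty expected or unexpected side yield NaN.
    """
    if "rt_valid" not in trials.columns:
        raise ValueError("run exclude_rt_outliers first (rt_valid column missing)")
    rows = []
    for key, g in trials.groupby(list(by)):
        made = g.get("response_made")
        made = made.to_numpy(dtype=bool) if made is not None else np.ones(len(g), bool)
        u = g["u"].to_numpy(dtype=int)
        correct = g["correct"].to_numpy(dtype=float)
        rt = g["rt_ms"].to_numpy(dtype=float)
        rt_ok = g["rt_valid"].to_numpy(dtype=bool) & (correct == 1)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        for name, vals, mask in (
            ("rt_ce", rt, rt_ok),
            ("acc_ce", correct * 100.0, made),
        ):
            un = vals[mask & (u == 0)]
            ex = vals[mask & (u == 1)]
            row[name] = un.mean() - ex.mean() if len(un) and len(ex) else np.nan
        row["n_unexpected"] = int((made & (u == 0)).sum())
        row["n_expected"] = int((made & (u == 1)).sum())
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- choices

def choice_probability(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "environment", "prior", "phase"),
) -> pd.DataFrame:
    """Mean of constant-coded choices over responded trials per cell (NaN if empty)."""
    rows = []
    for key, g in trials.groupby(list(by)):
        made = g.get("response_made")
        made = made.to_numpy(dtype=bool) if made is not None else np.ones(len(g), bool)
        coded = g["choice_coded"].to_numpy(dtype=float)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["choice_prob"] = coded[made].mean() if made.any() else np.nan
        row["n_trials"] = int(made.sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SwitchSeries:
    flags: np.ndarray      # per-trial switch indicators (first 4 trials ineligible)
    switch_rate: float     # events / (T - 4) eligible trials


def detect_switches(choices: np.ndarray, response_made: np.ndarray | None = None) -> SwitchSeries:
    """Switch = a choice differing from each of the four immediately preceding
    choices; a flag directly following a flagged trial is removed so each
    switch event counts once. Windows containing an omission yield no flag.
    """
    c = np.asarray(choices, dtype=int)
    T = len(c)
    if T < 5:
        raise ValueError("series must have at least 5 trials")
    made = (
        np.ones(T, dtype=bool)
        if response_made is None
        else np.asarray(response_made, dtype=bool)
    )
    flags = np.zeros(T, dtype=bool)
    for t in range(4, T):
        window = slice(t - 4, t)
        if not (made[t] and made[window].all()):
            continue
        if np.all(c[window] != c[t]):
            flags[t] = True
    # one count per event: drop a flag immediately after a flagged trial
    for t in range(1, T):
        if flags[t] and flags[t - 1]:
            flags[t] = False
    return SwitchSeries(flags=flags, switch_rate=float(flags.sum()) / (T - 4))


def switch_rates(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "environment", "prior"),
) -> pd.DataFrame:
    """Per-cell switch rates of the coded predictive-task choices (per block,
    then averaged if a cell spans several blocks)."""
    rows = []
    for key, g in trials.groupby(list(by)):
        rates = []
        for _, block in g.groupby("block_index"):
            block = block.sort_values("trial")
            made = block.get("response_made")
            made = made.to_numpy(dtype=bool) if made is not None else None
            rates.append(
                detect_switches(block["choice_coded"].to_numpy(), made).switch_rate
            )
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["switch_rate"] = float(np.mean(rates))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------- sliding window

def sliding_window_choice(
    choices: np.ndarray, window: int = 4, step: int = 1
) -> np.ndarray:
    """Windowed proportion of coded-1 choices (length (T - window)//step + 1)."""
    c = np.asarray(choices, dtype=float)
    if len(c) < window:
        raise ValueError("series shorter than window")
    kernel = np.ones(window) / window
    full = np.convolve(c, kernel, mode="valid")
    return full[::step]


def sliding_window_table(
    trials: pd.DataFrame, window: int = 4, step: int = 1
) -> pd.DataFrame:
    """Sliding-window choice series per participant x condition block.

    ``window_start`` is the 1-based trial index at which each window begins.
    """
    rows = []
    for (pid, env, prior, block), g in trials.groupby(
        ["participant", "environment", "prior", "block_index"]
    ):
        g = g.sort_values("trial")
        series = sliding_window_choice(g["choice_coded"].to_numpy(), window, step)
        for k, val in enumerate(series):
            rows.append(
                {
                    "participant": pid,
                    "environment": env,
                    "prior": prior,
                    "block_index": block,
                    "window_start": 1 + k * step,
                    "choice_prob": val,
                }
            )
    return pd.DataFrame(rows)
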