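"""Block and trial-sequence generation for the cueing / reversal-learning task.

A session consists of four 80-trial blocks crossing *environment*
(stable vs. reversal of the cue-target contingency) with *prior instruction*
(stability vs. reversal announcement, hence true vs. false prior). An auditory
cue (one of two tones) predicts the side of a visual target with probability
``contingency`` (default 0.7); in reversal blocks the mapping flips once, after
half of the trials.

Expectedness is **constant-coded**: ``u = 1`` when the target matches the
cue-target contingency of the *first* block half, for the whole block, so that
after a reversal the currently valid trials carry ``u = 0``. ``valid_now``
tracks validity under the contingency currently in force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

Environment = Literal["stable", "reversal"]
PriorInstruction = Literal["stability", "reversal"]
TaskVersion = Literal["reactive", "predictive"]

#: canonical per-phase unexpected-trial counts per condition cell
CANONICAL_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("stable", "true"): (9, 6, 9),
    ("stable", "false"): (8, 8, 8),
    ("reversal", "true"): (8, 13, 19),
    ("reversal", "false"): (8, 13, 19),
}

CONDITION_CELLS = [
    ("stable", "true"),
    ("stable", "false"),
    ("reversal", "true"),
    ("reversal", "false"),
]


class InfeasibleDesignError(ValueError):
    """Raised when the requested unexpected-trial counts cannot be realized."""


@dataclass(frozen=True)
class BlockSpec:
    """Generative description of one experimental block."""

    environment: Environment
    prior_instruction: PriorInstruction
    contingency: float = 0.7
    n_trials: int = 80
    reversal_after: int | None = None
    phase_boundaries: tuple[int, int] = (27, 53)
    target_unexpected_counts: tuple[int, int, int] | None = None
    # carried as metadata only, never simulated
    cue_tones_hz: tuple[float, float] = (587.33, 349.23)
    iti_range_ms: tuple[int, int] = (1300, 3000)

    def __post_init__(self) -> None:
        if not (0.5 < self.contingency <= 1.0):
            raise ValueError("contingency must lie in (0.5, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        b1, b2 = self.phase_boundaries
        if not (1 <= b1 < b2 < self.n_trials):
            raise ValueError("phase boundaries must satisfy 1 <= b1 < b2 < n_trials")
        if self.environment == "reversal":
            if self.reversal_after is None:
                object.__setattr__(self, "reversal_after", self.n_trials // 2)
            elif not (0 < self.reversal_after < self.n_trials):
                raise ValueError("reversal_after out of range")
        elif self.reversal_after is not None:
            raise ValueError("stable blocks take no reversal_after")
        if self.target_unexpected_counts is not None:
            counts = self.target_unexpected_counts
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValueError("target_unexpected_counts must be three non-negative ints")
            if sum(counts) > self.n_trials:
                raise ValueError("target_unexpected_counts exceed n_trials")

    @property
    def prior_truth(self) -> str:
        """'true' iff the instruction matches the environment's actual structure."""
        matches = (self.environment == "stable") == (self.prior_instruction == "stability")
        return "true" if matches else "false"

    @property
    def condition(self) -> str:
        return f"{self.environment}/{self.prior_truth}"

    def phase_lengths(self) -> tuple[int, int, int]:
        b1, b2 = self.phase_boundaries
        return (b1, b2 - b1, self.n_trials - b2)


def canonical_block(
    environment: Environment, prior_truth: str, n_trials: int = 80, **kwargs
) -> BlockSpec:
    """Block spec for one of the four condition cells.

    At the canonical 80-trial length the printed per-phase unexpected counts
    and phase boundaries (27, 53) apply; other lengths scale the boundaries
    proportionally and derive counts from the contingency.
    """
    instruction: PriorInstruction = "stability" if (
        (environment == "stable" and prior_truth == "true")
        or (environment == "reversal" and prior_truth == "false")
    ) else "reversal"
    if n_trials == 80:
        kwargs.setdefault("target_unexpected_counts",
                          CANONICAL_COUNTS[(environment, prior_truth)])
        kwargs.setdefault("phase_boundaries", (27, 53))
    else:
        kwargs.setdefault(
            "phase_boundaries",
            (max(1, round(27 / 80 * n_trials)), round(53 / 80 * n_trials)),
        )
    return BlockSpec(
        environment=environment,
        prior_instruction=instruction,
        n_trials=n_trials,
        **kwargs,
    )


@dataclass
class TrialSequence:
    """One realized block: per-trial arrays of length ``n_trials`` (0-based storage)."""

    spec: BlockSpec
    cue: np.ndarray          # 0 = tone1, 1 = tone2
    target_side: np.ndarray  # 0 = left, 1 = right
    u: np.ndarray            # expectedness vs. first-half contingency
    valid_now: np.ndarray    # validity vs. contingency currently in force
    phase: np.ndarray        # 1, 2, 3
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.u)

    def phase_unexpected_counts(self) -> tuple[int, int, int]:
        """Number of u=0 trials in each of the three block phases."""
        return tuple(int(np.sum((self.phase == p) & (self.u == 0))) for p in (1, 2, 3))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy trial table with 1-based trial indices."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "cue": np.where(self.cue == 0, "tone1", "tone2"),
                "target_side": np.where(self.target_side == 0, "left", "right"),
                "u": self.u,
                "valid_now": self.valid_now,
                "phase": self.phase,
            }
        )


def assign_phases(n_trials: int, boundaries: tuple[int, int] = (27, 53)) -> np.ndarray:
    """Label trials 1..b1 phase 1, b1+1..b2 phase 2, b2+1..n phase 3 (1-based, inclusive)."""
    b1, b2 = boundaries
    if not (1 <= b1 < b2 < n_trials):
        raise ValueError(f"invalid phase boundaries {boundaries} for {n_trials} trials")
    phase = np.empty(n_trials, dtype=int)
    phase[:b1] = 1
    phase[b1:b2] = 2
    phase[b2:] = 3
    return phase


def _default_counts(spec: BlockSpec) -> tuple[int, int, int]:
    """Per-phase u=0 counts implied by the contingency when none are requested."""
    q = 1.0 - spec.contingency
    lengths = spec.phase_lengths()
    if spec.environment == "stable":
        return tuple(int(round(q * L)) for L in lengths)
    # reversal: u=0 rate is q before the flip and (1-q) after
    r = spec.reversal_after
    counts = []
    start = 0
    for L in lengths:
        end = start + L
        pre = max(0, min(end, r) - start)
        post = L - pre
        counts.append(int(round(q * pre + (1 - q) * post)))
        start = end
    return tuple(counts)


def _segment_counts(spec: BlockSpec, counts: tuple[int, int, int]) -> list[tuple[int, int]]:
    """Split phases at the reversal into (length, n_unexpected) segments.

    A phase straddling the reversal divides its budget so each side's realized
    current-rule validity is as close as possible to the nominal contingency.
    """
    q = 1.0 - spec.contingency
    segments: list[tuple[int, int]] = []
    r = spec.reversal_after if spec.environment == "reversal" else None
    start = 0
    for L, m in zip(spec.phase_lengths(), counts):
        end = start + L
        if m > L:
            raise InfeasibleDesignError(
                f"requested {m} unexpected trials in a phase of {L} trials"
            )
        if r is None or r <= start or r >= end:
            segments.append((L, m))
        else:
            len_pre = r - start
            len_post = end - r
            # pre-reversal side: u=0 occurs at rate q; post: at rate 1-q
            m_pre = int(round(q * len_pre))
            m_pre = max(m - len_post, min(m_pre, min(len_pre, m)))
            segments.append((len_pre, m_pre))
            segments.append((len_post, m - m_pre))
        start = end
    return segments


def generate_block_sequence(
    spec: BlockSpec,
    seed: int,
    max_attempts: int = 10_000,
    tone_target_mapping: int = 0,
) -> TrialSequence:
    """Generate one pseudo-random trial sequence satisfying the design constraints.

    Constraints: exact per-phase unexpected-trial counts (``target_unexpected_counts``
    or counts implied by the contingency), balanced cue identities, and no run of
    three or more consecutive trials that violate the contingency currently in
    force. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    counts = spec.target_unexpected_counts or _default_counts(spec)
    if sum(counts) > spec.n_trials:
        raise InfeasibleDesignError("unexpected counts exceed block length")
    segments = _segment_counts(spec, counts)

    r = spec.reversal_after if spec.environment == "reversal" else None
    for _ in range(max_attempts):
        parts = []
        for L, m in segments:
            seg = np.zeros(L, dtype=int)
            seg[:m] = 1  # mark u=0 positions
            rng.shuffle(seg)
            parts.append(seg)
        unexpected = np.concatenate(parts)
        u = 1 - unexpected
        valid_now = u.copy()
        if r is not None:
            valid_now[r:] = 1 - u[r:]
        # reject runs of >=3 currently-unexpected trials
        if _max_zero_run(valid_now) < 3:
            break
    else:
        raise InfeasibleDesignError(
            f"could not satisfy run constraints within {max_attempts} attempts"
        )

    n = spec.n_trials
    cue = np.zeros(n, dtype=int)
    cue[n // 2:] = 1
    rng.shuffle(cue)
    # likely side of each cue under the rule currently in force
    likely = (cue ^ tone_target_mapping) if r is None else np.where(
        np.arange(n) < r, cue ^ tone_target_mapping, 1 - (cue ^ tone_target_mapping)
    )
    target_side = np.where(valid_now == 1, likely, 1 - likely)
    phase = assign_phases(n, spec.phase_boundaries)
    return TrialSequence(
        spec=spec, cue=cue, target_side=target_side, u=u,
        valid_now=valid_now, phase=phase, seed=seed,
    )


def _max_zero_run(x: np.ndarray) -> int:
    run = best = 0
    for v in x:
        run = run + 1 if v == 0 else 0
        best = max(best, run)
    return best


@dataclass
class SessionSpec:
    """One participant-session: four condition blocks in pseudo-random order."""

    task_version: TaskVersion
    blocks: list[BlockSpec]
    block_order_seed: int
    tone_target_mapping: int = 0
    target_grating: Literal["horizontal", "vertical"] = "horizontal"

    def __post_init__(self) -> None:
        cells = sorted((b.environment, b.prior_truth) for b in self.blocks)
        if cells != sorted(CONDITION_CELLS):
            raise ValueError("session must contain each condition cell exactly once")


def build_session(
    task_version: TaskVersion,
    participant_seed: int,
    contingency: float = 0.7,
    n_trials: int = 80,
) -> tuple[SessionSpec, list[TrialSequence]]:
    """Build a four-block session with seeded block order and trial sequences.

    Both task versions of one participant share identical trial sequences: all
    randomness derives from ``participant_seed`` alone, never from the task.
    """
    rng = np.random.default_rng(participant_seed)
    order = rng.permutation(4)
    mapping = int(rng.integers(2))
    grating = "horizontal" if rng.integers(2) == 0 else "vertical"
    cells = [CONDITION_CELLS[i] for i in order]
    blocks = [
        canonical_block(env, truth, contingency=contingency, n_trials=n_trials)
        for env, truth in cells
    ]
    seq_seeds = rng.integers(0, 2**31 - 1, size=4)
    sequences = [
        generate_block_sequence(b, int(s), tone_target_mapping=mapping)
        for b, s in zip(blocks, seq_seeds)
    ]
    session = SessionSpec(
        task_version=task_version,
        blocks=blocks,
        block_order_seed=participant_seed,
        tone_target_mapping=mapping,
        target_grating=grating,
    )
    return session, sequences


def session_to_frame(
    session: SessionSpec,
    sequences: Sequence[TrialSequence],
    participant: int | str,
) -> pd.DataFrame:
    """Long trial table for one session (1-based trial indices)."""
    frames = []
    for i, (block, seq) in enumerate(zip(session.blocks, sequences), start=1):
        df = seq.to_dataframe()
        df.insert(0, "participant", participant)
        df.insert(1, "task", session.task_version)
        df.insert(2, "block_index", i)
        df.insert(3, "environment", block.environment)
        df.insert(4, "prior", block.prior_truth)
        df.insert(5, "condition", block.condition)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def block_spec_from_yaml(path) -> BlockSpec:
    """Read a block design config (YAML) into a BlockSpec."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    counts = cfg.get("unexpected_counts")
    return BlockSpec(
        environment=cfg["environment"],
        prior_instruction=cfg["prior_instruction"],
        contingency=cfg.get("contingency", 0.7),
        n_trials=cfg.get("n_trials", 80),
        reversal_after=cfg.get("reversal_after"),
        phase_boundaries=tuple(cfg.get("phase_boundaries", (27, 53))),
        target_unexpected_counts=tuple(counts) if counts else None,
    )
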