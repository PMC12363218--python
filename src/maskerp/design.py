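"""Factorial trial design and pseudorandomized sequences.

The full design crosses 3 target stimulus types (face, scramble, blank) with
2 target-mask ISIs (0 and 200 ms) over 80 exemplars, each combination shown
twice: 960 trials.  Trial order is shuffled until no condition cell
(stimulus type x ISI) repeats more than ``max_run`` times in a row; four
such sequence versions are balanced across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STIM_TYPES = ("face", "scramble", "blank")
ISI_LEVELS_MS = (0, 200)

__all__ = [
    "STIM_TYPES",
    "ISI_LEVELS_MS",
    "TimingSpec",
    "build_trial_list",
    "longest_condition_run",
    "pseudorandomize",
    "make_versions",
    "assign_version",
]


@dataclass(frozen=True)
class TimingSpec:
    """Within-trial timing (ms): jittered fixation, 17-ms target, PAS prompt
    600 ms after target offset, 200-ms feedback frame around the response."""

    fixation_ms: tuple[int, int] = (500, 700)
    target_ms: int = 17
    pas_prompt_delay_ms: int = 600
    feedback_frame_ms: int = 200

    def __post_init__(self) -> None:
        if self.target_ms <= 0 or self.pas_prompt_delay_ms <= 0:
            raise ValueError("durations must be positive")
        if not 0 < self.fixation_ms[0] <= self.fixation_ms[1]:
            raise ValueError("invalid fixation range")


def build_trial_list(n_exemplars: int = 80, reps: int = 2) -> pd.DataFrame:
    """Unordered trial multiset: stim_type x exemplar x ISI x repetition.

    Returns ``3 * n_exemplars * 2 * reps`` rows with columns
    ``exemplar_id`` (1-based), ``stim_type``, ``isi_ms``, ``repetition``.
    """
    if n_exemplars < 1 or reps < 1:
        raise ValueError("n_exemplars and reps must be >= 1")
    rows = [
        (ex + 1, st, isi, rep + 1)
        for st in STIM_TYPES
        for ex in range(n_exemplars)
        for isi in ISI_LEVELS_MS
        for rep in range(reps)
    ]
    return pd.DataFrame(rows, columns=["exemplar_id", "stim_type", "isi_ms", "repetition"])


def longest_condition_run(stim_types, isis) -> int:
    """Longest run of consecutive trials sharing (stim_type, isi)."""
    st = np.asarray(stim_types)
    isi = np.asarray(isis)
    if len(st) == 0:
        return 0
    same = (st[1:] == st[:-1]) & (isi[1:] == isi[:-1])
    longest = run = 1
    for s in same:
        run = run + 1 if s else 1
        longest = max(longest, run)
    return longest


def pseudorandomize(
    trials: pd.DataFrame,
    max_run: int = 3,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Shuffle the trial list until no condition repeats more than
    ``max_run`` times consecutively (rejection sampling).

    Returns a reindexed copy with a 1-based ``trial_index`` column.  Raises
    ``RuntimeError`` reporting the attempt count if no valid ordering is
    found within ``max_attempts``.
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        shuffled = trials.iloc[perm]
        if longest_condition_run(shuffled["stim_type"].to_numpy(), shuffled["isi_ms"].to_numpy()) <= max_run:
            out = shuffled.reset_index(drop=True)
            out.insert(0, "trial_index", np.arange(1, n + 1))
            return out
    raise RuntimeError(
        f"no ordering with max run {max_run} found in {max_attempts} attempts"
    )


def make_versions(
    n_versions: int = 4,
    n_exemplars: int = 80,
    reps: int = 2,
    max_run: int = 3,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[pd.DataFrame]:
    """Independent pseudorandomized sequence versions of the same design.

    Each version gets a ``sequence_version`` column (1-based).  Duplicate
    orderings across versions (astronomically unlikely at full size) are
    rejected and redrawn.
    """
    ss = np.random.SeedSequence(seed)
    base = build_trial_list(n_exemplars, reps)
    versions: list[pd.DataFrame] = []
    seen: set[tuple] = set()
    rng = np.random.default_rng(ss)
    while len(versions) < n_versions:
        plan = pseudorandomize(base, max_run=max_run, seed=rng, max_attempts=max_attempts)
        key = tuple(zip(plan["exemplar_id"], plan["stim_type"], plan["isi_ms"], plan["repetition"]))
        if key in seen:
            continue
        seen.add(key)
        plan.insert(0, "sequence_version", len(versions) + 1)
        versions.append(plan)
    return versions


def assign_version(participant_index: int, n_versions: int = 4) -> int:
    """Cyclic version assignment: participants 1..8 get versions 1,2,3,4,1,2,3,4."""
    if participant_index < 1:
        raise ValueError("participant_index is 1-based")
    return (participant_index - 1) % n_versions + 1
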