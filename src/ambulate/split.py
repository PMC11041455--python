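"""Participant-level train/test splitting.

Splits are always at the participant level: every participant's epochs
land wholly on one side, which is what makes held-out metrics honest for
within-person correlated data. Two methods:

* ``stratified_by_steps`` — participants sorted by mean daily step count,
  consecutive pairs split one-to-each-side with random orientation. This
  balances activity levels between halves, mitigating bias from training
  mostly on very low- or very high-activity participants.
* ``random`` — a uniformly random split with a configurable train fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SplitAssignment:
    """A participant -> {train, test} mapping with provenance."""

    assignment: dict[str, str]
    method: str  # {stratified_by_steps, random}
    seed: int
    balance_stat: float | None = None  # |mean daily steps(train) - (test)|

    def train_ids(self) -> list[str]:
        return sorted(p for p, a in self.assignment.items() if a == "train")

    def test_ids(self) -> list[str]:
        return sorted(p for p, a in self.assignment.items() if a == "test")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": list(self.assignment),
            "assignment": list(self.assignment.values()),
            "method": self.method,
            "seed": self.seed,
        })


def split_stratified_by_steps(daily_steps: dict[str, float] | pd.Series,
                              seed: int) -> SplitAssignment:
    """Pairwise activity-stratified 50-50 split.

    Participants are sorted by mean daily step count; each consecutive
    pair contributes one participant to each half, with the within-pair
    orientation randomized. With an odd count the median participant is
    left unpaired and assigned by coin flip, so half sizes differ by at
    most one. ``balance_stat`` is the absolute difference in mean daily
    step count between halves.
    """
    if isinstance(daily_steps, pd.Series):
        daily_steps = daily_steps.to_dict()
    items = [(str(p), float(v)) for p, v in daily_steps.items()]
    if len(items) < 2:
        raise ValueError("stratified split requires at least 2 participants")
    if not all(np.isfinite(v) for _, v in items):
        raise ValueError("non-finite mean daily step count")

    rng = np.random.default_rng(seed)
    items.sort(key=lambda pv: (pv[1], pv[0]))
    assignment: dict[str, str] = {}
    if len(items) % 2 == 1:
        median = items.pop(len(items) // 2)
        assignment[median[0]] = "train" if rng.random() < 0.5 else "test"
    for i in range(0, len(items), 2):
        a, b = items[i], items[i + 1]
        if rng.random() < 0.5:
            a, b = b, a
        assignment[a[0]] = "train"
        assignment[b[0]] = "test"

    means = {s: np.mean([daily_steps[p] for p, side in assignment.items()
                         if side == s]) for s in ("train", "test")}
    return SplitAssignment(assignment=assignment, method="stratified_by_steps",
                           seed=seed,
                           balance_stat=abs(float(means["train"] - means["test"])))


def split_random(participant_ids, fraction_train: float,
                 seed: int) -> SplitAssignment:
    """Uniformly random participant-level split (deterministic per seed)."""
    ids = [str(p) for p in participant_ids]
    if not ids:
        raise ValueError("no participants to split")
    if not 0 < fraction_train < 1:
        raise ValueError(f"fraction_train must be in (0, 1), got {fraction_train}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    n_train = int(round(len(order) * fraction_train))
    assignment = {p: ("train" if i < n_train else "test")
                  for i, p in enumerate(order)}
    return SplitAssignment(assignment=assignment, method="random", seed=seed)


def mean_daily_steps(steps: pd.DataFrame) -> pd.Series:
    """Per-participant mean of daily total single-leg step counts."""
    from .simulate import DAY_MS

    df = steps.copy()
    df["day"] = df["window_start_ms"] // DAY_MS
    daily = df.groupby(["participant_id", "day"])["steps"].sum()
    return daily.groupby("participant_id").mean()


def assert_no_leakage(train_ids, test_ids) -> None:
    """Raise if any participant appears on both sides of a split."""
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(f"participant leakage across split: {sorted(overlap)}")
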