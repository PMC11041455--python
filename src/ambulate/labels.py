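"""Reference labels, tag quality control and evaluable-day selection.

Two ground-truth modalities produce binary per-epoch labels:

* **device labels** — a 10-second window is *ambulatory* iff the ankle
  reference device counted >= 3 steps on the wearing foot, else
  *nonambulatory*;
* **self-report labels** — an epoch fully covered by a ``walk_run`` tag is
  *ambulatory*; fully covered by ``still`` or ``other`` is *nonambulatory*
  (the two are grouped); partially covered or conflictingly covered epochs
  receive no label.

Self-report tags pass through one of two quality-control strata first:
``qc_minimal`` removes only gross user errors (tags longer than a full
day, non-positive duration) and clips tags to wear time; ``qc_high``
additionally enforces a duration window, eliminates mutually overlapping
tags, and trims a guard interval off both ends of every survivor.

A participant-day is *evaluable* when (both) devices were worn
synchronously for at least 8 hours within the calendar day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DAY_MS, EPOCH_MS

AMBULATORY = "ambulatory"
NONAMBULATORY = "nonambulatory"

#: device rule: single-leg steps per 10 s window at/above which an epoch
#: is labeled ambulatory
STEP_THRESHOLD = 3

#: minimum synchronous wear per calendar day for evaluability, hours
MIN_EVALUABLE_HOURS = 8.0

QC_MAX_TAG_MS = DAY_MS  # qc_minimal: anything longer is a gross error
QC_HIGH_MIN_TAG_MS = 60_000  # qc_high duration window
QC_HIGH_MAX_TAG_MS = 4 * 3600 * 1000
QC_HIGH_GUARD_MS = 10_000  # trimmed off both ends of every survivor


@dataclass
class QcReport:
    """Tally of quality-control actions on one batch of tags."""

    n_tags_in: int = 0
    n_eliminated: int = 0
    n_truncated: int = 0
    seconds_removed: float = 0.0

    @property
    def n_retained(self) -> int:
        return self.n_tags_in - self.n_eliminated


def device_labels(steps: pd.DataFrame) -> pd.DataFrame:
    """Label every step window by the >= 3 single-leg-steps rule.

    Returns one label row per input window with columns ``participant_id``,
    ``epoch_start_ms``, ``label``, ``source`` (``device``) and
    ``qc_stratum`` (``none``).
    """
    counts = steps["steps"].to_numpy()
    if (counts < 0).any():
        bad = steps.iloc[int(np.flatnonzero(counts < 0)[0])]
        raise ValueError(
            f"negative step count {bad['steps']} for participant "
            f"{bad['participant_id']} at {bad['window_start_ms']}")
    return pd.DataFrame({
        "participant_id": steps["participant_id"].to_numpy(),
        "epoch_start_ms": steps["window_start_ms"].to_numpy(np.int64),
        "label": np.where(counts >= STEP_THRESHOLD, AMBULATORY, NONAMBULATORY),
        "source": "device",
        "qc_stratum": "none",
    })


def _intersect_with_wear(start: int, end: int,
                         wear_sorted: np.ndarray) -> list[tuple[int, int]]:
    """Pieces of [start, end) that fall inside the given wear intervals."""
    pieces = []
    for ws, we in wear_sorted:
        s, e = max(start, ws), min(end, we)
        if e > s:
            pieces.append((int(s), int(e)))
    return pieces


def apply_qc(tags: pd.DataFrame, stratum: str,
             wear: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Filter self-report tags through a quality-control stratum.

    ``qc_minimal`` eliminates tags with non-positive duration or duration
    > 24 h and truncates the rest to their intersection with watch wear.
    ``qc_high`` starts from the minimal result, additionally eliminates
    tags outside the [60 s, 4 h] duration window and tags overlapping
    another tag of the same participant, then trims a 10-second guard off
    both ends of every survivor (so every surviving tag is truncated).

    Returns the surviving tags (a tag clipped against a gap in wear may
    yield several pieces) and a :class:`QcReport`; ``seconds_removed`` is
    exactly input tag seconds minus output tag seconds.
    """
    if stratum not in ("qc_minimal", "qc_high"):
        raise ValueError(f"unknown QC stratum {stratum!r}")

    report = QcReport(n_tags_in=len(tags))
    in_seconds = float(
        np.maximum(tags["end_ms"] - tags["start_ms"], 0).sum()) / 1000.0 if len(tags) else 0.0

    watch_wear = wear[wear["device"] == "watch"]
    wear_by_pid = {
        pid: grp[["start_ms", "end_ms"]].sort_values("start_ms").to_numpy(np.int64)
        for pid, grp in watch_wear.groupby("participant_id")
    }

    kept_rows: list[tuple] = []  # (pid, start, end, category, tag_index)
    for i, row in enumerate(tags.itertuples(index=False)):
        dur = row.end_ms - row.start_ms
        if dur <= 0 or dur > QC_MAX_TAG_MS:
            report.n_eliminated += 1
            continue
        pieces = _intersect_with_wear(
            row.start_ms, row.end_ms,
            wear_by_pid.get(row.participant_id, np.empty((0, 2), np.int64)))
        if not pieces:
            report.n_eliminated += 1
            continue
        if sum(e - s for s, e in pieces) < dur:
            report.n_truncated += 1
        for s, e in pieces:
            kept_rows.append((row.participant_id, s, e, row.category, i))

    if stratum == "qc_high":
        df = pd.DataFrame(kept_rows, columns=["participant_id", "start_ms",
                                              "end_ms", "category", "tag_idx"])
        kept_rows = []
        for pid, grp in df.groupby("participant_id", sort=True):
            grp = grp.sort_values("start_ms", kind="stable")
            starts = grp["start_ms"].to_numpy()
            ends = grp["end_ms"].to_numpy()
            n = len(grp)
            overlapping = np.zeros(n, dtype=bool)
            for j in range(n - 1):
                if ends[j] > starts[j + 1]:
                    overlapping[j] = overlapping[j + 1] = True
            for j, row in enumerate(grp.itertuples(index=False)):
                dur = row.end_ms - row.start_ms
                if dur < QC_HIGH_MIN_TAG_MS or dur > QC_HIGH_MAX_TAG_MS or overlapping[j]:
                    continue
                s = row.start_ms + QC_HIGH_GUARD_MS
                e = row.end_ms - QC_HIGH_GUARD_MS
                if e <= s:
                    continue
                kept_rows.append((pid, s, e, row.category, row.tag_idx))
        surviving = {r[4] for r in kept_rows}
        # every surviving tag was guard-trimmed, hence truncated
        report.n_truncated = len(surviving)
        report.n_eliminated = report.n_tags_in - len(surviving)

    out = pd.DataFrame([r[:4] for r in kept_rows],
                       columns=["participant_id", "start_ms", "end_ms", "category"])
    out = out.sort_values(["participant_id", "start_ms"],
                          kind="stable").reset_index(drop=True)
    out_seconds = float((out["end_ms"] - out["start_ms"]).sum()) / 1000.0 if len(out) else 0.0
    report.seconds_removed = in_seconds - out_seconds
    return out, report


def self_report_labels(tags: pd.DataFrame, epoch_grid: pd.DataFrame,
                       qc_stratum: str = "none") -> pd.DataFrame:
    """Label epochs from QC'd tags (full-coverage assignment).

    ``epoch_grid`` holds candidate epochs (``participant_id``,
    ``epoch_start_ms``). An epoch is labeled only when its full 10 seconds
    lie inside tags of a single effective class; epochs partially covered,
    uncovered, or covered by conflicting classes emit no label.
    """
    out_parts = []
    grid_by_pid = dict(iter(epoch_grid.groupby("participant_id", sort=True)))
    for pid, ptags in tags.groupby("participant_id", sort=True):
        grid = grid_by_pid.get(pid)
        if grid is None or grid.empty:
            continue
        starts = grid["epoch_start_ms"].to_numpy(np.int64)
        amb_cover = np.zeros(len(starts), dtype=np.int32)
        non_cover = np.zeros(len(starts), dtype=np.int32)
        for row in ptags.itertuples(index=False):
            covered = (starts >= row.start_ms) & (starts + EPOCH_MS <= row.end_ms)
            if row.category == "walk_run":
                amb_cover += covered
            else:  # still / other -> nonambulatory
                non_cover += covered
        labeled_amb = (amb_cover > 0) & (non_cover == 0)
        labeled_non = (non_cover > 0) & (amb_cover == 0)
        any_label = labeled_amb | labeled_non
        if not any_label.any():
            continue
        out_parts.append(pd.DataFrame({
            "participant_id": pid,
            "epoch_start_ms": starts[any_label],
            "label": np.where(labeled_amb[any_label], AMBULATORY, NONAMBULATORY),
            "source": "self_report",
            "qc_stratum": qc_stratum,
        }))
    if not out_parts:
        return pd.DataFrame(columns=["participant_id", "epoch_start_ms",
                                     "label", "source", "qc_stratum"])
    return pd.concat(out_parts, ignore_index=True)


def _day_of(ms: np.ndarray | int) -> np.ndarray | int:
    return ms // DAY_MS


def evaluable_days(wear: pd.DataFrame,
                   require_both_devices: bool = True) -> set[tuple[str, int]]:
    """Participant-days with >= 8 h of (synchronous) wear.

    With ``require_both_devices``, the watch and reference wear intervals
    are intersected and the overlap within each calendar day must total at
    least 8 hours; otherwise watch wear alone is summed. Day boundaries
    are midnights of the epoch-millisecond clock.
    """
    min_ms = int(MIN_EVALUABLE_HOURS * 3600 * 1000)
    result: set[tuple[str, int]] = set()
    for pid, grp in wear.groupby("participant_id", sort=True):
        watch = grp[grp["device"] == "watch"][["start_ms", "end_ms"]].to_numpy(np.int64)
        if require_both_devices:
            ref = grp[grp["device"] == "reference"][["start_ms", "end_ms"]].to_numpy(np.int64)
            pieces = []
            for ws, we in watch:
                for rs, re_ in ref:
                    s, e = max(ws, rs), min(we, re_)
                    if e > s:
                        pieces.append((s, e))
        else:
            pieces = [tuple(r) for r in watch]
        per_day: dict[int, int] = {}
        for s, e in pieces:
            d = s // DAY_MS
            while d * DAY_MS < e:
                lo = max(s, d * DAY_MS)
                hi = min(e, (d + 1) * DAY_MS)
                per_day[d] = per_day.get(d, 0) + int(hi - lo)
                d += 1
        for d, total in per_day.items():
            if total >= min_ms:
                result.add((str(pid), int(d)))
    return result
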