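"""Synthetic cohort simulator for wrist-accelerometer validation studies.

Generates simulated participants with the statistical structure of two
study designs:

* ``pilot_like`` — a small, demographically homogeneous cohort whose
  reference labels come from an ankle-worn step counter reporting
  single-leg step counts in 10-second windows.
* ``pbhs_like`` — a larger, demographically diverse cohort whose reference
  labels come from noisy on-watch self-report tags (``walk_run`` /
  ``still`` / ``other``).

Each participant-day consists of a contiguous daytime wear interval filled
with alternating rest, walking bouts and non-gait "distractor" arm-movement
segments. The raw 30 Hz tri-axial signal is regenerated deterministically
on demand from the cohort seed, so cohorts of arbitrary size fit in memory:
only step windows, tags, wear intervals, demographics and the hidden
per-epoch walking truth are stored.

Signal model (test scaffolding, not biomechanics): rest is the gravity
vector plus white noise; a walking bout is a cadence-locked sum of
sinusoids at the participant's cadence and its first two harmonics with
participant-specific amplitudes, plus noise; distractor segments are
band-limited noise bursts with broadband energy so that classification is
non-trivial.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 30
EPOCH_MS = 10_000
DAY_MS = 86_400_000
SAMPLES_PER_EPOCH = SAMPLE_RATE_HZ * EPOCH_MS // 1000  # 300

#: physiological ceiling for single-leg steps in a 10-second window
MAX_STEPS_PER_WINDOW = 40

TAG_CATEGORIES = ("walk_run", "still", "other")
RACE_LEVELS = ("white", "black", "asian", "hispanic", "other")


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary parts (independent of hash randomization).

    Used to give every participant (and every participant-day) its own
    random substream, so cohorts are reproducible under participant
    reordering. Result is < 2**31.
    """
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagNoiseConfig:
    """Error channels corrupting self-reported activity tags."""

    start_latency_sd: float = 20.0  # seconds
    end_latency_sd: float = 30.0  # seconds
    missing_tag_prob: float = 0.10
    overlong_tag_prob: float = 0.02
    mislabel_prob: float = 0.03

    def __post_init__(self):
        for name in ("missing_tag_prob", "overlong_tag_prob", "mislabel_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.start_latency_sd < 0 or self.end_latency_sd < 0:
            raise ValueError("latency standard deviations must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.start_latency_sd == 0
            and self.end_latency_sd == 0
            and self.missing_tag_prob == 0
            and self.overlong_tag_prob == 0
            and self.mislabel_prob == 0
        )


#: an all-zero noise configuration (corruption is the identity)
NO_TAG_NOISE = TagNoiseConfig(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters for one simulated participant.

    ``race`` and ``tag_noise`` are ``None`` for pilot-like participants:
    the pilot design collected no race data and its labels come from the
    reference device, not from self-report.
    """

    participant_id: str
    gender: str  # {female, male}
    age_years: int
    mean_daily_walk_minutes: float
    cadence_hz: float  # both-feet step frequency
    wear_hours_per_day: float
    race: str | None = None
    tag_noise: TagNoiseConfig | None = None
    mean_daily_other_minutes: float = 60.0  # non-gait distractor activity

    def __post_init__(self):
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be female/male, got {self.gender!r}")
        if self.age_years < 18:
            raise ValueError(f"age_years must be >= 18, got {self.age_years}")
        if not 0.5 < self.cadence_hz < 4.0:
            raise ValueError(f"cadence_hz must be in (0.5, 4.0), got {self.cadence_hz}")
        if not 0 < self.mean_daily_walk_minutes < 24 * 60:
            raise ValueError(
                f"mean_daily_walk_minutes must be in (0, 1440), "
                f"got {self.mean_daily_walk_minutes}"
            )
        if not 0 <= self.wear_hours_per_day <= 24:
            raise ValueError(
                f"wear_hours_per_day must be in [0, 24], got {self.wear_hours_per_day}"
            )


@dataclass
class AccelStream:
    """Uniform 30 Hz tri-axial acceleration for one contiguous wear block."""

    participant_id: str
    t0: int  # epoch-milliseconds of the first sample
    samples: np.ndarray  # (n, 3) in units of g
    sample_rate_hz: int = SAMPLE_RATE_HZ
    timestamps: np.ndarray | None = None  # explicit per-sample times (file input)

    def __len__(self) -> int:
        return len(self.samples)

    def t_ms(self) -> np.ndarray:
        """Timestamps of every sample, in milliseconds."""
        if self.timestamps is not None:
            return np.asarray(self.timestamps, dtype=np.int64)
        return self.t0 + (np.arange(len(self.samples)) * 1000) // self.sample_rate_hz


@dataclass
class ParticipantDay:
    """Everything the simulator generates for one participant-day."""

    stream: AccelStream
    steps: pd.DataFrame  # participant_id, window_start_ms, steps
    tags: pd.DataFrame  # participant_id, start_ms, end_ms, category (clean)
    wear: pd.DataFrame  # participant_id, device, start_ms, end_ms
    truth: pd.DataFrame  # participant_id, epoch_start_ms, walking (bool)


def _empty_steps() -> pd.DataFrame:
    return pd.DataFrame({"participant_id": pd.Series(dtype=str),
                         "window_start_ms": pd.Series(dtype=np.int64),
                         "steps": pd.Series(dtype=np.int64)})


def _empty_tags() -> pd.DataFrame:
    return pd.DataFrame({"participant_id": pd.Series(dtype=str),
                         "start_ms": pd.Series(dtype=np.int64),
                         "end_ms": pd.Series(dtype=np.int64),
                         "category": pd.Series(dtype=str)})


def _empty_wear() -> pd.DataFrame:
    return pd.DataFrame({"participant_id": pd.Series(dtype=str),
                         "device": pd.Series(dtype=str),
                         "start_ms": pd.Series(dtype=np.int64),
                         "end_ms": pd.Series(dtype=np.int64)})


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame({"participant_id": pd.Series(dtype=str),
                         "epoch_start_ms": pd.Series(dtype=np.int64),
                         "walking": pd.Series(dtype=bool)})


# ---------------------------------------------------------------------------
# single participant-day generation
# ---------------------------------------------------------------------------


def _participant_rng(profile_id: str, master_seed: int, *extra) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, profile_id, *extra))


def _draw_bout_epochs(rng, total_epochs: int, target_epochs: int,
                      median_epochs: float, sigma: float) -> list[int]:
    """Bout lengths (in 10-s epochs) summing to ~target, log-normal mix."""
    lengths: list[int] = []
    remaining = target_epochs
    while remaining > 0:
        ln = int(round(float(rng.lognormal(np.log(median_epochs), sigma))))
        ln = max(3, ln)  # at least 30 s per bout
        ln = min(ln, remaining) if remaining >= 3 else remaining
        lengths.append(ln)
        remaining -= ln
    return [l for l in lengths if l > 0]


def _place_segments(rng, n_epochs: int, lengths: list[int],
                    occupied: np.ndarray) -> list[tuple[int, int]]:
    """Place segments of the given epoch-lengths into unoccupied grid space.

    Greedy random placement: for each length (longest first), pick a start
    uniformly among positions where the whole segment is free. Returns
    (start_epoch, length) pairs; segments that no longer fit are dropped.
    """
    placed = []
    for ln in sorted(lengths, reverse=True):
        free = ~occupied
        # positions where a run of `ln` consecutive epochs is free
        ok = np.convolve(free.astype(int), np.ones(ln, dtype=int), "valid") == ln
        candidates = np.flatnonzero(ok)
        if len(candidates) == 0:
            continue
        start = int(rng.choice(candidates))
        occupied[start:start + ln] = True
        placed.append((start, ln))
    return sorted(placed)


def simulate_participant_day(
    profile: ParticipantProfile, day_index: int, seed: int,
    with_signal: bool = True,
) -> ParticipantDay:
    """Simulate one participant-day: signal, step windows, tags, wear, truth.

    The day occupies ``[day_index * 24 h, (day_index + 1) * 24 h)`` in
    epoch-milliseconds. Wear is one contiguous daytime block aligned to the
    10-second grid; everything outside it is non-wear (no samples). Walking
    bouts and distractor segments are aligned to the grid so that clean
    tags cover bouts exactly and each epoch is unambiguously walking or
    not. Fully deterministic given ``(profile, day_index, seed)``.

    Day layout and raw-signal synthesis use independent random substreams,
    so ``with_signal=False`` returns identical step windows, tags, wear
    and truth while skipping the (comparatively expensive) 30 Hz signal;
    the stream can be regenerated later from the same seed.
    """
    rng = np.random.default_rng(derive_seed(seed, profile.participant_id, day_index))
    day_origin = day_index * DAY_MS

    wear_s = int(round(profile.wear_hours_per_day * 3600 / 10.0)) * 10
    if wear_s <= 0:
        empty = AccelStream(profile.participant_id, day_origin, np.empty((0, 3)))
        return ParticipantDay(empty, _empty_steps(), _empty_tags(),
                              _empty_wear(), _empty_truth())

    # wear starts in the morning, jittered, snapped to the 10 s grid
    latest_start_s = max(0, 24 * 3600 - wear_s)
    start_s = min(int(rng.integers(7 * 360, 10 * 360)) * 10, latest_start_s)
    wear_start = day_origin + start_s * 1000
    n_epochs = wear_s // 10

    # --- lay out walking bouts and distractor segments on the epoch grid
    target_walk_min = profile.mean_daily_walk_minutes * float(
        np.clip(rng.normal(1.0, 0.1), 0.5, 1.5))
    target_walk_epochs = min(int(round(target_walk_min * 6)), n_epochs)
    bout_lengths = _draw_bout_epochs(rng, n_epochs, target_walk_epochs,
                                     median_epochs=18.0, sigma=0.7)  # median 3 min
    occupied = np.zeros(n_epochs, dtype=bool)
    bouts = _place_segments(rng, n_epochs, bout_lengths, occupied)

    target_other_epochs = min(int(round(profile.mean_daily_other_minutes * 6)),
                              max(0, n_epochs - int(occupied.sum())))
    other_lengths = _draw_bout_epochs(rng, n_epochs, target_other_epochs,
                                      median_epochs=12.0, sigma=0.6)
    others = _place_segments(rng, n_epochs, other_lengths, occupied)

    walking = np.zeros(n_epochs, dtype=bool)
    for s, ln in bouts:
        walking[s:s + ln] = True
    other_mask = np.zeros(n_epochs, dtype=bool)
    for s, ln in others:
        other_mask[s:s + ln] = True

    # --- raw signal (its own substream; see docstring) --------------------
    n_samples = wear_s * SAMPLE_RATE_HZ
    if with_signal:
        sig_rng = np.random.default_rng(
            derive_seed(seed, profile.participant_id, day_index, "signal"))
        sig = sig_rng.normal(0.0, 0.03, size=(n_samples, 3))
        sig[:, 2] += 1.0  # gravity on z at rest (device orientation is
        # arbitrary but fixed; magnitude-based features do not depend on it)

        # participant-specific harmonic amplitudes in [0.1, 0.5] g
        prng = _participant_rng(profile.participant_id, seed, "gait-amps")
        amps = prng.uniform(0.1, 0.5, size=(3, 3))  # (axis, harmonic)
        amps[:, 1] *= 0.5
        amps[:, 2] *= 0.25

        t = np.arange(n_samples) / SAMPLE_RATE_HZ
        for s, ln in bouts:
            i0, i1 = s * SAMPLES_PER_EPOCH, (s + ln) * SAMPLES_PER_EPOCH
            tt = t[i0:i1]
            phases = sig_rng.uniform(0, 2 * np.pi, size=(3, 3))
            for axis in range(3):
                wave = np.zeros(i1 - i0)
                for k in range(3):
                    wave += amps[axis, k] * np.sin(
                        2 * np.pi * (k + 1) * profile.cadence_hz * tt
                        + phases[axis, k])
                sig[i0:i1, axis] += wave

        for s, ln in others:
            i0, i1 = s * SAMPLES_PER_EPOCH, (s + ln) * SAMPLES_PER_EPOCH
            burst = sig_rng.normal(0.0, 0.15, size=(i1 - i0, 3))
            # 3-tap moving average: band-limits the burst below ~8 Hz
            kernel = np.ones(3) / 3.0
            for axis in range(3):
                burst[:, axis] = np.convolve(burst[:, axis], kernel, "same")
            sig[i0:i1] += burst
    else:
        sig = np.empty((0, 3))

    stream = AccelStream(profile.participant_id, wear_start, sig)

    # --- reference step windows (single-leg counts) -----------------------
    window_starts = wear_start + np.arange(n_epochs, dtype=np.int64) * EPOCH_MS
    base = profile.cadence_hz * 10.0 / 2.0  # single-leg steps per full window
    step_counts = np.zeros(n_epochs, dtype=np.int64)
    jitter = np.round(rng.normal(0.0, 0.5, size=n_epochs)).astype(np.int64)
    step_counts[walking] = np.clip(
        np.round(base).astype(np.int64) + jitter[walking], 0, MAX_STEPS_PER_WINDOW)
    # incidental shuffling steps outside bouts, always < 3
    incidental = rng.random(n_epochs) < 0.04
    step_counts[~walking & incidental] = rng.integers(
        1, 3, size=int((~walking & incidental).sum()))
    steps = pd.DataFrame({
        "participant_id": profile.participant_id,
        "window_start_ms": window_starts,
        "steps": step_counts,
    })

    # --- clean tags: bouts -> walk_run, distractors -> other, some still --
    tag_rows = []
    for s, ln in bouts:
        tag_rows.append((wear_start + s * EPOCH_MS,
                         wear_start + (s + ln) * EPOCH_MS, "walk_run"))
    for s, ln in others:
        tag_rows.append((wear_start + s * EPOCH_MS,
                         wear_start + (s + ln) * EPOCH_MS, "other"))
    # still tags over a sample of the remaining rest runs
    rest = ~walking & ~other_mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], rest.view(np.int8), [0]))))
    for r0, r1 in zip(edges[::2], edges[1::2]):
        if r1 - r0 >= 6 and rng.random() < 0.6:  # tag rest runs >= 1 min
            tag_rows.append((wear_start + int(r0) * EPOCH_MS,
                             wear_start + int(r1) * EPOCH_MS, "still"))
    tags = pd.DataFrame(tag_rows, columns=["start_ms", "end_ms", "category"])
    tags.insert(0, "participant_id", profile.participant_id)
    tags = tags.sort_values("start_ms", kind="stable").reset_index(drop=True)

    wear_end = wear_start + wear_s * 1000
    wear = pd.DataFrame({
        "participant_id": [profile.participant_id] * 2,
        "device": ["watch", "reference"],
        "start_ms": np.int64(wear_start),
        "end_ms": np.int64(wear_end),
    })

    truth = pd.DataFrame({
        "participant_id": profile.participant_id,
        "epoch_start_ms": window_starts,
        "walking": walking,
    })
    return ParticipantDay(stream, steps, tags, wear, truth)


# ---------------------------------------------------------------------------
# tag corruption
# ---------------------------------------------------------------------------


def corrupt_tags(tags: pd.DataFrame, noise: TagNoiseConfig, seed: int) -> pd.DataFrame:
    """Apply self-report error channels to clean tags.

    Start/end times get Gaussian latencies; a fraction of tags is dropped
    entirely (the user forgot to tag); a fraction is stretched past a full
    day (the user forgot to close the tag); a fraction is recategorized.
    An all-zero config returns the input unchanged. Output sorted by
    (participant_id, start_ms).
    """
    if noise.is_identity or tags.empty:
        return tags.copy()
    rng = np.random.default_rng(seed)
    out = tags.copy().reset_index(drop=True)
    n = len(out)

    keep = rng.random(n) >= noise.missing_tag_prob
    start_shift = np.round(rng.normal(0, noise.start_latency_sd * 1000, n)).astype(np.int64)
    end_shift = np.round(rng.normal(0, noise.end_latency_sd * 1000, n)).astype(np.int64)
    out["start_ms"] = out["start_ms"] + start_shift
    out["end_ms"] = out["end_ms"] + end_shift

    overlong = rng.random(n) < noise.overlong_tag_prob
    out.loc[overlong, "end_ms"] = (
        out.loc[overlong, "start_ms"] + DAY_MS
        + rng.integers(1, 12 * 3600 * 1000, size=int(overlong.sum()))
    )

    mislabel = rng.random(n) < noise.mislabel_prob
    if mislabel.any():
        cats = np.asarray(TAG_CATEGORIES)
        current = out.loc[mislabel, "category"].to_numpy()
        newcat = np.array([
            rng.choice(cats[cats != c]) for c in current])
        out.loc[mislabel, "category"] = newcat

    # keep tags positive-length after latency jitter (degenerate ones are
    # exactly the gross errors QC exists to remove, so leave a few in)
    out = out[keep].sort_values(["participant_id", "start_ms"],
                                kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    Defaults encode the two study styles: ``pilot_like`` cohorts carry
    device step counts, a mostly-male demographic mix and no race field;
    ``pbhs_like`` cohorts carry corrupted self-report tags, a diverse mix
    and demographics including race.
    """

    style: str  # {pilot_like, pbhs_like}
    n_participants: int
    n_days: int = 7
    wear_hours_range: tuple[float, float] = (8.5, 11.5)
    walk_minutes_median: float = 60.0
    walk_minutes_sigma: float = 0.5  # log-normal spread across participants
    cadence_range: tuple[float, float] = (1.4, 2.2)
    male_fraction: float | None = None  # default per style
    age_mean_sd: tuple[float, float] | None = None  # default per style
    tag_noise: TagNoiseConfig = field(default_factory=TagNoiseConfig)

    def __post_init__(self):
        if self.style not in ("pilot_like", "pbhs_like"):
            raise ValueError(f"unknown cohort style {self.style!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass
class SyntheticCohort:
    """A simulated cohort; raw streams are regenerated lazily on demand."""

    config: CohortConfig
    seed: int
    profiles: list[ParticipantProfile]
    steps: pd.DataFrame
    tags: pd.DataFrame  # post tag-noise for pbhs_like; empty for pilot_like
    clean_tags: pd.DataFrame  # pre-noise tags (testing aid)
    wear: pd.DataFrame
    truth: pd.DataFrame  # hidden generative per-epoch walking flag

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.profiles]

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def stream(self, participant_id: str, day_index: int) -> AccelStream:
        """Regenerate the raw 30 Hz stream for one participant-day."""
        return simulate_participant_day(
            self.profile(participant_id), day_index, self.seed).stream

    def iter_days(self):
        """Yield (participant_id, day_index) over the whole cohort."""
        for p in self.profiles:
            for d in range(self.config.n_days):
                yield p.participant_id, d


def _make_profile(config: CohortConfig, idx: int, seed: int) -> ParticipantProfile:
    pid = f"{'PIL' if config.style == 'pilot_like' else 'PBH'}{idx:04d}"
    rng = np.random.default_rng(derive_seed(seed, pid, "profile"))

    if config.style == "pilot_like":
        male_frac = 0.64 if config.male_fraction is None else config.male_fraction
        age_mean, age_sd = config.age_mean_sd or (33.0, 8.5)
        race = None
        tag_noise = None
    else:
        male_frac = 0.45 if config.male_fraction is None else config.male_fraction
        age_mean, age_sd = config.age_mean_sd or (54.0, 17.0)
        race = str(rng.choice(RACE_LEVELS, p=[0.55, 0.15, 0.12, 0.12, 0.06]))
        tag_noise = config.tag_noise

    gender = "male" if rng.random() < male_frac else "female"
    age = int(np.clip(round(rng.normal(age_mean, age_sd)), 18, 95))
    walk_min = float(np.clip(
        rng.lognormal(np.log(config.walk_minutes_median), config.walk_minutes_sigma),
        5.0, 300.0))
    cadence = float(rng.uniform(*config.cadence_range))
    wear_h = round(float(rng.uniform(*config.wear_hours_range)), 1)
    return ParticipantProfile(
        participant_id=pid, gender=gender, age_years=age,
        mean_daily_walk_minutes=walk_min, cadence_hz=cadence,
        wear_hours_per_day=wear_h, race=race, tag_noise=tag_noise)


def simulate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Generate a full cohort (without materializing raw streams).

    ``pilot_like``: device step records present, no tags, no race.
    ``pbhs_like``: noise-corrupted tags present, step records withheld
    (the hidden truth flags remain available for testing). Deterministic
    under a fixed ``(config, seed)``.
    """
    profiles = [_make_profile(config, i, seed) for i in range(config.n_participants)]

    steps_parts, tags_parts, wear_parts, truth_parts = [], [], [], []
    for p in profiles:
        for d in range(config.n_days):
            day = simulate_participant_day(p, d, seed, with_signal=False)
            steps_parts.append(day.steps)
            tags_parts.append(day.tags)
            wear_parts.append(day.wear)
            truth_parts.append(day.truth)

    steps = pd.concat(steps_parts, ignore_index=True) if steps_parts else _empty_steps()
    clean_tags = pd.concat(tags_parts, ignore_index=True) if tags_parts else _empty_tags()
    wear = pd.concat(wear_parts, ignore_index=True) if wear_parts else _empty_wear()
    truth = pd.concat(truth_parts, ignore_index=True) if truth_parts else _empty_truth()

    if config.style == "pilot_like":
        tags = _empty_tags()
    else:
        tags = corrupt_tags(clean_tags, config.tag_noise,
                            derive_seed(seed, "tag-noise"))
        steps = _empty_steps()  # withheld: labels come from self-report

    return SyntheticCohort(config=config, seed=seed, profiles=profiles,
                           steps=steps, tags=tags, clean_tags=clean_tags,
                           wear=wear, truth=truth)


# ---------------------------------------------------------------------------
# CSV writers (the on-disk interchange formats)
# ---------------------------------------------------------------------------


def write_cohort_csvs(cohort: SyntheticCohort, outdir, include_accel: bool = True) -> None:
    """Write the five interchange CSVs (accel/steps/tags/wear/demographics).

    ``accel.csv`` streams raw samples per participant-day and can be large;
    pass ``include_accel=False`` to skip it. Missing race is written as an
    empty field.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort.steps.to_csv(outdir / "steps.csv", index=False)
    cohort.tags.to_csv(outdir / "tags.csv", index=False)
    cohort.wear.to_csv(outdir / "wear.csv", index=False)

    demo = pd.DataFrame({
        "participant_id": [p.participant_id for p in cohort.profiles],
        "gender": [p.gender for p in cohort.profiles],
        "age_years": [p.age_years for p in cohort.profiles],
        "race": [p.race if p.race is not None else "" for p in cohort.profiles],
    })
    demo.to_csv(outdir / "demographics.csv", index=False)

    if include_accel:
        first = True
        with open(outdir / "accel.csv", "w", encoding="utf-8") as fh:
            for pid, d in cohort.iter_days():
                stream = cohort.stream(pid, d)
                if len(stream) == 0:
                    continue
                df = pd.DataFrame({
                    "participant_id": pid,
                    "t_ms": stream.t_ms(),
                    "x_g": stream.samples[:, 0],
                    "y_g": stream.samples[:, 1],
                    "z_g": stream.samples[:, 2],
                })
                df.to_csv(fh, index=False, header=first)
                first = False
            if first:
                fh.write("participant_id,t_ms,x_g,y_g,z_g\n")
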