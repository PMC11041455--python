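"""Epoch segmentation and the 14-dimensional accelerometer feature vector.

The classifier consumes non-overlapping 10-second epochs (300 samples at
30 Hz). Each epoch is summarized by 14 features in four families:

* 3 signal-deviation features — per-axis standard deviation (``dev_x/y/z``);
* 5 locomotor band energies — integrated Welch power spectral density of
  the gravity-removed vector-magnitude signal over bands bracketing human
  cadence and its harmonics: [0.6, 1.0), [1.0, 1.5), [1.5, 2.5),
  [2.5, 4.0), [4.0, 8.0) Hz (``band_e1..band_e5``);
* 2 signal percentiles — 95th percentile of the gravity-removed magnitude
  and of the jerk magnitude |Δmag| × fs (``p95_mag``, ``p95_jerk``);
* 4 percentile differences — IQR per axis and of the magnitude
  (``iqr_x/y/z``, ``iqr_mag``).

Gravity removal is per-epoch (subtract the epoch-mean magnitude), which
keeps feature extraction a pure function of a single epoch. The PSD uses
Welch's method with a Hann window, 150-sample segments and 50% overlap;
band energies are trapezoidal integrals of the PSD clipped exactly to the
band edges, so the bands are disjoint sub-intervals of [0, 15] Hz and
their sum never exceeds the total signal power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .simulate import (AccelStream, EPOCH_MS, SAMPLE_RATE_HZ,
                       SAMPLES_PER_EPOCH)

FEATURE_NAMES = (
    "dev_x", "dev_y", "dev_z",
    "band_e1", "band_e2", "band_e3", "band_e4", "band_e5",
    "p95_mag", "p95_jerk",
    "iqr_x", "iqr_y", "iqr_z", "iqr_mag",
)

#: locomotor PSD bands in Hz (half-open, disjoint)
BAND_EDGES_HZ = ((0.6, 1.0), (1.0, 1.5), (1.5, 2.5), (2.5, 4.0), (4.0, 8.0))

_WELCH_KW = dict(fs=SAMPLE_RATE_HZ, window="hann", nperseg=150,
                 noverlap=75, detrend=False, scaling="density")


@dataclass(frozen=True)
class Epoch:
    """One grid-aligned 10-second window of tri-axial acceleration."""

    participant_id: str
    start_ms: int
    samples: np.ndarray  # (300, 3) in g

    def __post_init__(self):
        if self.samples.shape != (SAMPLES_PER_EPOCH, 3):
            raise ValueError(
                f"epoch requires exactly {SAMPLES_PER_EPOCH}x3 samples, "
                f"got {self.samples.shape}")


def _band_weight_matrix() -> np.ndarray:
    """Exact trapezoidal-integration weights per PSD bin for each band.

    The PSD is treated as piecewise linear between Welch frequency bins;
    integrating it over a band clipped to the band edges is then a fixed
    linear functional of the bin values. Weights are computed by pushing
    unit vectors through that integral on a knot-union grid (bins plus
    edges), which makes the trapezoid rule exact for piecewise-linear
    integrands.
    """
    freqs = np.fft.rfftfreq(150, d=1.0 / SAMPLE_RATE_HZ)
    nf = len(freqs)
    W = np.zeros((nf, len(BAND_EDGES_HZ)))
    for b, (lo, hi) in enumerate(BAND_EDGES_HZ):
        knots = np.unique(np.concatenate(
            [freqs[(freqs > lo) & (freqs < hi)], [lo, hi]]))
        for i in range(nf):
            unit = np.zeros(nf)
            unit[i] = 1.0
            vals = np.interp(knots, freqs, unit)
            W[i, b] = np.trapezoid(vals, knots)
    return W


_BAND_W = _band_weight_matrix()


def featurize_epoch_array(samples: np.ndarray) -> np.ndarray:
    """Vectorized feature extraction for a batch of epochs.

    Parameters
    ----------
    samples
        Array of shape ``(n_epochs, 300, 3)`` in units of g.

    Returns
    -------
    Array of shape ``(n_epochs, 14)`` ordered as :data:`FEATURE_NAMES`.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[1:] != (SAMPLES_PER_EPOCH, 3):
        raise ValueError(f"expected (n, {SAMPLES_PER_EPOCH}, 3), got {samples.shape}")
    if not np.isfinite(samples).all():
        bad = int(np.flatnonzero(~np.isfinite(samples).all(axis=(1, 2)))[0])
        raise ValueError(f"non-finite samples in epoch index {bad}")
    n = samples.shape[0]
    if n == 0:
        return np.empty((0, len(FEATURE_NAMES)))

    mag = np.sqrt(np.einsum("ijk,ijk->ij", samples, samples))  # (n, 300)
    mag0 = mag - mag.mean(axis=1, keepdims=True)  # gravity removed

    # per-axis SD via E[x^2] - E[x]^2 (cheaper than ndarray.std here)
    ax_mean = samples.mean(axis=1)
    ax_sq = np.einsum("ijk,ijk->ik", samples, samples) / samples.shape[1]
    dev = np.sqrt(np.maximum(ax_sq - ax_mean**2, 0.0))  # (n, 3)

    _, psd = welch(mag0, axis=-1, **_WELCH_KW)
    band_e = psd @ _BAND_W  # (n, 5)

    q25m, q75m, p95_mag = np.percentile(mag0, [25, 75, 95], axis=1)
    jerk = np.abs(np.diff(mag0, axis=1)) * SAMPLE_RATE_HZ
    p95_jerk = np.percentile(jerk, 95, axis=1)

    q75, q25 = np.percentile(samples, [75, 25], axis=1)  # (n, 3) each
    iqr_axes = q75 - q25
    iqr_mag = q75m - q25m

    return np.column_stack([dev, band_e, p95_mag, p95_jerk, iqr_axes, iqr_mag])


def extract_features(epoch: Epoch) -> np.ndarray:
    """The 14-feature vector of one epoch (pure, deterministic)."""
    try:
        return featurize_epoch_array(epoch.samples[None, :, :])[0]
    except ValueError as exc:
        raise ValueError(
            f"epoch {epoch.participant_id}@{epoch.start_ms}: {exc}") from exc


def epoch_stream(stream: AccelStream, day_origin_ms: int = 0) -> list[Epoch]:
    """Cut a stream into grid-aligned, non-overlapping 10-second epochs.

    Epochs are aligned to ``day_origin_ms`` modulo 10 s. Windows with fewer
    than 300 samples (stream edges, non-wear gaps) are dropped.
    """
    t = np.asarray(stream.t_ms(), dtype=np.int64)
    samples = np.asarray(stream.samples, dtype=float)
    if len(t) == 0:
        return []
    inv = np.flatnonzero(np.diff(t) < 0)
    if len(inv):
        raise ValueError(
            f"stream not sorted by time: inversion at sample {int(inv[0]) + 1} "
            f"(t={int(t[inv[0] + 1])} after t={int(t[inv[0]])})")

    idx = (t - day_origin_ms) // EPOCH_MS
    epochs: list[Epoch] = []
    boundaries = np.flatnonzero(np.diff(idx)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(t)]))
    for s, e in zip(starts, ends):
        if e - s == SAMPLES_PER_EPOCH:
            epochs.append(Epoch(stream.participant_id,
                                int(day_origin_ms + idx[s] * EPOCH_MS),
                                samples[s:e]))
    return epochs


def featurize_stream(stream: AccelStream, day_origin_ms: int = 0) -> pd.DataFrame:
    """Epoch a stream and extract features; one row per complete epoch."""
    epochs = epoch_stream(stream, day_origin_ms)
    if not epochs:
        return pd.DataFrame(columns=["participant_id", "epoch_start_ms",
                                     *FEATURE_NAMES])
    X = featurize_epoch_array(np.stack([e.samples for e in epochs]))
    out = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    out.insert(0, "epoch_start_ms", np.array([e.start_ms for e in epochs],
                                             dtype=np.int64))
    out.insert(0, "participant_id", stream.participant_id)
    return out


def featurize_accel_frame(accel: pd.DataFrame) -> pd.DataFrame:
    """Featurize an ``accel.csv``-shaped frame (may contain many streams).

    Rows are grouped by participant; non-wear gaps break contiguity via the
    grid-count rule (incomplete windows are dropped).
    """
    parts = []
    for pid, grp in accel.groupby("participant_id", sort=True):
        grp = grp.sort_values("t_ms", kind="stable")
        stream = AccelStream(
            participant_id=str(pid),
            t0=int(grp["t_ms"].iloc[0]),
            samples=grp[["x_g", "y_g", "z_g"]].to_numpy(float),
            timestamps=grp["t_ms"].to_numpy(np.int64),
        )
        parts.append(featurize_stream(stream))
    if not parts:
        return pd.DataFrame(columns=["participant_id", "epoch_start_ms",
                                     *FEATURE_NAMES])
    return pd.concat(parts, ignore_index=True)
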