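"""Epoching and filtering of continuous multichannel recordings.

Implements the segmentation rules of the two evaluation protocols:

* **Target epochs** — a fixed window relative to each response marker
  (default -1300 ms to +200 ms), baseline-corrected against the mean of the
  segment's first 100 ms.  By default the baseline span is discarded after
  correction, so a 1500 ms window at 200 Hz yields 280 time points; keeping
  it yields 300.
* **Nontarget epochs** — a sliding window (default 1500 ms length, 500 ms
  step) over stretches of the record at least 3000 ms away from every
  marker, with the same baseline/channel treatment, optionally subsampled
  (seeded) to match the target count.
* **Trialwise epochs** — the full duration of each cued trial from its
  onset (e.g. 4 s at 250 Hz -> 1000 time points).
* **Bandpass + downsample** — zero-phase Butterworth bandpass (order 4,
  applied forward-backward) followed by polyphase resampling.

Channel exclusion is by name and preserves the order of the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .montage import EpochSet
from .synthetic import ContinuousRecord

__all__ = [
    "EpochingConfig",
    "epoch_targets",
    "epoch_nontargets",
    "epoch_trialwise",
    "bandpass_downsample",
]

TARGET_LABEL = 1
NONTARGET_LABEL = 0


@dataclass(frozen=True)
class EpochingConfig:
    """Windowing, baseline and channel-exclusion rules for epoching.

    All durations are in milliseconds.  ``target_window`` is (start, end)
    relative to the response marker; ``nontarget_exclusion_ms`` is the
    minimum distance a nontarget window must keep from *any* marker, on
    both sides.
    """

    target_window: tuple[float, float] = (-1300.0, 200.0)
    baseline_ms: float = 100.0
    discard_baseline: bool = True
    nontarget_window_ms: float = 1500.0
    nontarget_step_ms: float = 500.0
    nontarget_exclusion_ms: float = 3000.0
    excluded_channels: tuple[str, ...] = ()
    balance_classes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_window[1] <= self.target_window[0]:
            raise ValueError("target window must have positive length")
        if self.nontarget_window_ms <= 0 or self.nontarget_step_ms <= 0:
            raise ValueError("nontarget window and step must be positive")
        if self.baseline_ms < 0 or self.nontarget_exclusion_ms < 0:
            raise ValueError("baseline and exclusion spans must be >= 0")
        excl = tuple(self.excluded_channels)
        if len(set(excl)) != len(excl):
            raise ValueError("excluded channels must be distinct")
        object.__setattr__(self, "excluded_channels", excl)


def _keep_channels(record: ContinuousRecord, excluded: tuple[str, ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    unknown = [ch for ch in excluded if ch not in record.channel_names]
    if unknown:
        warnings.warn(f"excluded channels not in record: {unknown}", stacklevel=3)
    keep = [i for i, ch in enumerate(record.channel_names) if ch not in excluded]
    return np.array(keep, dtype=int), tuple(record.channel_names[i] for i in keep)


def _baseline_correct(segments: np.ndarray, n_baseline: int, discard: bool) -> np.ndarray:
    """Subtract the mean of the first ``n_baseline`` samples per channel,
    then optionally drop that span.  With n_baseline == 0, a no-op."""
    if n_baseline > 0:
        segments = segments - segments[..., :n_baseline].mean(axis=-1, keepdims=True)
        if discard:
            segments = segments[..., n_baseline:]
    return segments


def _cut(record: ContinuousRecord, start_indices: np.ndarray, n_samples: int,
         what: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack [start, start+n) slices, skipping (with a warning) any that
    fall outside the record.  Returns (segments, kept_start_indices)."""
    total = record.data.shape[1]
    keep = (start_indices >= 0) & (start_indices + n_samples <= total)
    if not keep.all():
        warnings.warn(
            f"skipped {int((~keep).sum())} {what} segment(s) too close to the "
            "record edge",
            stacklevel=3,
        )
    starts = start_indices[keep]
    segs = np.stack([record.data[:, s:s + n_samples] for s in starts]) if len(starts) \
        else np.empty((0, record.data.shape[0], n_samples))
    return segs, starts


def epoch_targets(
    record: ContinuousRecord,
    config: EpochingConfig = EpochingConfig(),
    markers: np.ndarray | None = None,
) -> EpochSet:
    """One baseline-corrected segment per response marker (label 1)."""
    fs = record.sampling_rate
    if markers is None:
        markers = record.markers.get("response", np.empty(0))
    markers = np.asarray(markers, dtype=np.float64)
    w0, w1 = config.target_window
    n_samples = int(round((w1 - w0) / 1000.0 * fs))
    starts = np.round((markers + w0 / 1000.0) * fs).astype(int)
    segs, _ = _cut(record, starts, n_samples, "target")
    n_base = int(round(config.baseline_ms / 1000.0 * fs))
    segs = _baseline_correct(segs, n_base, config.discard_baseline)
    keep_idx, names = _keep_channels(record, config.excluded_channels)
    segs = segs[:, keep_idx, :]
    return EpochSet(segs, np.full(len(segs), TARGET_LABEL), fs, names)


def admissible_nontarget_starts(
    record: ContinuousRecord,
    config: EpochingConfig,
    marker_times: np.ndarray | None = None,
) -> np.ndarray:
    """Start indices (samples) of all admissible nontarget sliding windows.

    A window is admissible when it lies fully inside the record and its time
    interval keeps at least ``nontarget_exclusion_ms`` distance from every
    marker time (stimulus and response alike).
    """
    fs = record.sampling_rate
    if marker_times is None:
        marker_times = record.all_marker_times()
    marker_times = np.asarray(marker_times, dtype=np.float64)
    win_n = int(round(config.nontarget_window_ms / 1000.0 * fs))
    step_n = max(int(round(config.nontarget_step_ms / 1000.0 * fs)), 1)
    excl = config.nontarget_exclusion_ms / 1000.0
    total = record.data.shape[1]
    starts = np.arange(0, total - win_n + 1, step_n)
    ts = starts / fs
    te = (starts + win_n) / fs
    ok = np.ones(len(starts), dtype=bool)
    for m in marker_times:
        ok &= (te <= m - excl) | (ts >= m + excl)
    return starts[ok]


def epoch_nontargets(
    record: ContinuousRecord,
    config: EpochingConfig = EpochingConfig(),
    marker_times: np.ndarray | None = None,
    n_keep: int | None = None,
) -> EpochSet:
    """Sliding-window segments away from all markers (label 0).

    With ``config.balance_classes`` and ``n_keep`` given, a seeded uniform
    subsample of exactly ``n_keep`` windows is returned (all of them when
    fewer are admissible).
    """
    fs = record.sampling_rate
    starts = admissible_nontarget_starts(record, config, marker_times)
    if len(starts) == 0:
        warnings.warn("no admissible nontarget windows", stacklevel=2)
    win_n = int(round(config.nontarget_window_ms / 1000.0 * fs))
    segs, _ = _cut(record, starts, win_n, "nontarget")
    if config.balance_classes and n_keep is not None and len(segs) > n_keep:
        rng = np.random.default_rng(config.seed)
        pick = np.sort(rng.choice(len(segs), size=n_keep, replace=False))
        segs = segs[pick]
    n_base = int(round(config.baseline_ms / 1000.0 * fs))
    segs = _baseline_correct(segs, n_base, config.discard_baseline)
    keep_idx, names = _keep_channels(record, config.excluded_channels)
    segs = segs[:, keep_idx, :]
    return EpochSet(segs, np.full(len(segs), NONTARGET_LABEL), fs, names)


def epoch_trialwise(
    record: ContinuousRecord,
    trial_onsets: np.ndarray,
    duration_s: float,
    config: EpochingConfig = EpochingConfig(),
    labels: np.ndarray | None = None,
) -> EpochSet:
    """Fixed-duration segments from each trial onset, no baseline handling.

    The whole cued trial is the epoch: 4 s at 250 Hz gives 1000 time points.
    """
    if duration_s <= 0:
        raise ValueError("trial duration must be positive")
    fs = record.sampling_rate
    onsets = np.asarray(trial_onsets, dtype=np.float64)
    n_samples = int(round(duration_s * fs))
    starts = np.round(onsets * fs).astype(int)
    keep_mask = (starts >= 0) & (starts + n_samples <= record.data.shape[1])
    segs, kept = _cut(record, starts, n_samples, "trial")
    if labels is None:
        out_labels = np.zeros(len(segs), dtype=int)
    else:
        labels = np.asarray(labels)
        if len(labels) != len(onsets):
            raise ValueError("labels must match trial_onsets in length")
        out_labels = labels[keep_mask]
    keep_idx, names = _keep_channels(record, config.excluded_channels)
    return EpochSet(segs[:, keep_idx, :], out_labels, fs, names)


def bandpass_downsample(
    record: ContinuousRecord,
    low_hz: float,
    high_hz: float,
    target_rate: float | None = None,
    *,
    order: int = 4,
) -> ContinuousRecord:
    """Zero-phase Butterworth bandpass, then polyphase resampling.

    The filter is applied forward-backward (no latency shift).  Marker times
    are in seconds and therefore untouched by resampling.
    """
    fs = record.sampling_rate
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"high edge {high_hz} Hz exceeds the Nyquist rate {fs / 2} Hz")
    out_rate = target_rate if target_rate is not None else fs
    if high_hz > out_rate / 2:  # an edge exactly at Nyquist is allowed
        raise ValueError(
            f"band edge {high_hz} Hz exceeds the Nyquist rate after resampling "
            f"to {out_rate} Hz"
        )
    if low_hz > 0:
        sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    else:
        sos = sps.butter(order, high_hz, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.data, axis=1)
    if out_rate != fs:
        frac = Fraction(out_rate / fs).limit_denominator(1000)
        filtered = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return ContinuousRecord(
        np.ascontiguousarray(filtered),
        record.channel_names,
        out_rate,
        markers={k: v.copy() for k, v in record.markers.items()},
    )
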