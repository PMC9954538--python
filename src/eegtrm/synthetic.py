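"""Synthetic EEG with class-dependent spatial topographies.

Generates labeled epochs in which each class carries a band-limited
oscillatory burst focused at a fixed grid cell, its amplitude decaying with
grid distance from that focus (Gaussian profile), superposed on 1/f-shaped
plus white noise.  Because the discriminative information is purely
*spatial* — classes differ only in where on the scalp grid the oscillation
lives — these data exercise exactly the structure a topographic front-end is
meant to exploit, with no external downloads.

Also provides a continuous event-stream generator (background noise plus
stimulus/response marker pairs at random spacings) as a fixture for the
epoching operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isinf

import numpy as np

from .montage import EpochSet, MontageGrid

__all__ = [
    "SimConfig",
    "EventStreamConfig",
    "ContinuousRecord",
    "simulate_epochs",
    "make_event_stream",
    "class_foci",
    "pink_noise",
]

# Fraction of total noise amplitude carried by the shared (common-mode)
# 1/f-shaped component; the remainder is independent white noise per channel.
COMMON_MODE_FRACTION = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the class-conditioned oscillatory-burst simulation.

    snr is the linear ratio of mean signal power to mean noise power per
    trial (``math.inf`` means noiseless); spatial_spread is the Gaussian
    decay scale of burst amplitude, in grid-cell units.
    """

    montage: MontageGrid
    n_classes: int = 2
    trials_per_class: int = 40
    n_timepoints: int = 280
    sampling_rate: float = 200.0
    oscillation_band: tuple[float, float] = (8.0, 13.0)
    snr: float = 5.0
    spatial_spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.trials_per_class, self.n_timepoints) < 1:
            raise ValueError("counts must be positive")
        if self.sampling_rate <= 0 or self.spatial_spread <= 0:
            raise ValueError("sampling_rate and spatial_spread must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be > 0 (math.inf for noiseless)")
        lo, hi = self.oscillation_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError(
                f"oscillation band {self.oscillation_band} must lie within "
                f"(0, {self.sampling_rate / 2}) Hz"
            )
        if self.n_classes > self.montage.n_channels:
            raise ValueError(
                f"montage has only {self.montage.n_channels} assigned cells for "
                f"{self.n_classes} class foci"
            )


def class_foci(montage: MontageGrid, n_classes: int) -> list[tuple[int, int]]:
    """Deterministic, maximally spread focus cells, one per class.

    Greedy max-min placement over the montage's assigned cells: the first
    focus is the assigned cell farthest from the grid centroid, each
    subsequent focus maximizes its minimum distance to those already chosen.
    Ties break by (row, col) order.
    """
    cells = sorted(montage.assignments[ch] for ch in montage.channel_names)
    if n_classes > len(cells):
        raise ValueError("more classes than assigned cells")
    cr, cc = (montage.height - 1) / 2, (montage.width - 1) / 2
    first = max(cells, key=lambda rc: ((rc[0] - cr) ** 2 + (rc[1] - cc) ** 2, -rc[0], -rc[1]))
    foci = [first]
    while len(foci) < n_classes:
        best = max(
            (c for c in cells if c not in foci),
            key=lambda rc: (min((rc[0] - r) ** 2 + (rc[1] - g) ** 2 for r, g in foci),
                            -rc[0], -rc[1]),
        )
        foci.append(best)
    return foci


def pink_noise(rng: np.random.Generator, n_samples: int, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent (DC removed)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _channel_gains(montage: MontageGrid, focus: tuple[int, int], spread: float) -> np.ndarray:
    rows, cols = montage.grid_indices()
    d2 = (rows - focus[0]) ** 2.0 + (cols - focus[1]) ** 2.0
    return np.exp(-d2 / (2.0 * spread**2))


def _make_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    common = pink_noise(rng, n_samples)
    white = rng.standard_normal((n_channels, n_samples))
    return COMMON_MODE_FRACTION * common[None, :] + (1 - COMMON_MODE_FRACTION) * white


def simulate_epochs(config: SimConfig) -> EpochSet:
    """Generate a balanced, labeled, fully seed-reproducible EpochSet.

    Per trial: an oscillatory burst at a frequency drawn uniformly from the
    oscillation band, with uniform random phase and a Hann envelope, is
    projected onto channels with Gaussian spatial decay from the trial's
    class focus, then noise is added and scaled so that the per-trial mean
    signal-to-noise power ratio equals ``config.snr``.
    """
    m = config.montage
    rng = np.random.default_rng(config.seed)
    foci = class_foci(m, config.n_classes)
    gains = [_channel_gains(m, f, config.spatial_spread) for f in foci]
    tp, fs = config.n_timepoints, config.sampling_rate
    t = np.arange(tp) / fs
    envelope = np.hanning(tp)
    n_trials = config.n_classes * config.trials_per_class
    data = np.empty((n_trials, m.n_channels, tp))
    labels = np.repeat(np.arange(config.n_classes), config.trials_per_class)
    lo, hi = config.oscillation_band
    for i, lab in enumerate(labels):
        freq = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        burst = np.sin(2 * np.pi * freq * t + phase) * envelope
        signal = gains[lab][:, None] * burst[None, :]
        noise = _make_noise(rng, m.n_channels, tp)
        if isinf(config.snr):
            data[i] = signal
        else:
            p_sig = np.mean(signal**2)
            p_noise = np.mean(noise**2)
            data[i] = signal + noise * np.sqrt(p_sig / (config.snr * p_noise))
    # shuffle trial order (labels travel with trials; balance is unchanged)
    perm = rng.permutation(n_trials)
    return EpochSet(data[perm], labels[perm], fs, m.channel_names)


@dataclass
class ContinuousRecord:
    """A continuous multichannel recording with named event markers.

    data is channels x samples; markers maps a marker name (e.g. "stimulus",
    "response") to an array of event times in seconds.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate: float
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.markers = {k: np.asarray(v, dtype=np.float64) for k, v in self.markers.items()}

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    def all_marker_times(self) -> np.ndarray:
        if not self.markers:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.markers.values())))


@dataclass(frozen=True)
class EventStreamConfig:
    """Parameters of the continuous record + marker-stream fixture.

    Events are stimulus/response pairs: gaps between consecutive stimuli are
    drawn uniformly from ``gap_range_s`` and the response follows its
    stimulus by a uniform ``reaction_range_s`` delay.  ``window_s``, if
    given, is the epoching window the stream is destined for; gap ranges
    shorter than it are rejected.
    """

    montage: MontageGrid
    n_events: int = 10
    sampling_rate: float = 200.0
    gap_range_s: tuple[float, float] = (20.0, 40.0)
    reaction_range_s: tuple[float, float] = (0.3, 0.8)
    window_s: float | None = None
    padding_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        lo, hi = self.gap_range_s
        if not 0 < lo <= hi:
            raise ValueError("gap range must satisfy 0 < low <= high")
        if self.window_s is not None and lo < self.window_s:
            raise ValueError(
                f"event spacing range {self.gap_range_s} is shorter than the "
                f"epoching window ({self.window_s} s)"
            )


def make_event_stream(config: EventStreamConfig) -> ContinuousRecord:
    """Continuous noise record with embedded stimulus/response marker pairs."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gap_range_s
    gaps = rng.uniform(lo, hi, size=config.n_events)
    stim = config.padding_s + np.cumsum(gaps)
    react = rng.uniform(*config.reaction_range_s, size=config.n_events)
    resp = stim + react
    total_s = (resp[-1] if config.n_events else 0.0) + config.padding_s + (
        config.window_s or 2.0
    )
    n_samples = int(np.ceil(total_s * config.sampling_rate))
    data = _make_noise(rng, config.montage.n_channels, n_samples)
    return ContinuousRecord(
        data,
        config.montage.channel_names,
        config.sampling_rate,
        markers={"stimulus": stim, "response": resp},
    )
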