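"""Electrode-to-grid montages and the raw-signal -> topographic-map transform.

An EEG montage here is an assignment of each channel name to one cell of an
H x W scalp grid (row 0 = frontal, column 0 = left hemisphere, 0-based,
row-major).  Mapping an epoch onto the grid produces a 3-D topographic stack
(H x W x TP per trial) in which each assigned cell carries the raw potential
of its channel, untouched, and every unassigned cell is exactly zero.  No
interpolation is performed: zero-fill of empty cells is the defining choice
of this representation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "MontageGrid",
    "EpochSet",
    "MontageError",
    "load_montage",
    "load_layout",
    "available_layouts",
    "map_to_topomap",
    "unmap_topomap",
]


class MontageError(ValueError):
    """Invalid montage configuration or montage/epoch mismatch."""


@dataclass(frozen=True)
class MontageGrid:
    """Injective assignment of C channel names to cells of an H x W grid.

    Parameters
    ----------
    channel_names : ordered channel identifiers (defines the canonical
        channel axis order of every array this montage touches).
    height, width : grid dimensions H (rows) and W (columns).
    assignments : mapping channel name -> (row, col), 0-based.
    name : optional human-readable layout identifier.
    """

    channel_names: tuple[str, ...]
    height: int
    width: int
    assignments: Mapping[str, tuple[int, int]]
    name: str = ""

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise MontageError(
                f"grid dimensions must be >= 1, got {self.height}x{self.width}"
            )
        names = list(self.channel_names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MontageError(f"duplicate channel name(s): {dupes}")
        if set(names) != set(self.assignments):
            raise MontageError(
                "channel_names and assignment keys differ: "
                f"missing={sorted(set(names) - set(self.assignments))}, "
                f"extra={sorted(set(self.assignments) - set(names))}"
            )
        seen: dict[tuple[int, int], str] = {}
        for ch in names:
            r, c = self.assignments[ch]
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise MontageError(
                    f"channel {ch!r} assigned to ({r}, {c}), outside the "
                    f"{self.height}x{self.width} grid"
                )
            if (r, c) in seen:
                raise MontageError(
                    f"cell ({r}, {c}) assigned to both {seen[(r, c)]!r} and {ch!r}"
                )
            seen[(r, c)] = ch
        object.__setattr__(self, "channel_names", tuple(names))
        object.__setattr__(
            self, "assignments", {ch: tuple(self.assignments[ch]) for ch in names}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def grid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays aligned with ``channel_names``."""
        rows = np.array([self.assignments[ch][0] for ch in self.channel_names])
        cols = np.array([self.assignments[ch][1] for ch in self.channel_names])
        return rows, cols

    def cell_of(self, channel: str) -> tuple[int, int]:
        return self.assignments[channel]

    def reorder(self, channel_names: Iterable[str]) -> "MontageGrid":
        """Same montage with a different canonical channel order."""
        names = tuple(channel_names)
        if set(names) != set(self.channel_names):
            raise MontageError("reorder must use exactly the montage's channels")
        return MontageGrid(names, self.height, self.width, dict(self.assignments), self.name)


@dataclass
class EpochSet:
    """Labeled EEG trials: data is trials x C x TP, labels one per trial."""

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(f"data must be trials x C x TP, got ndim={self.data.ndim}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        self.channel_names = tuple(self.channel_names)
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def _parse_montage_mapping(cfg: dict, name: str = "") -> MontageGrid:
    try:
        height = int(cfg["height"])
        width = int(cfg["width"])
        entries = cfg["channels"]
    except KeyError as exc:
        raise MontageError(f"montage config missing key: {exc}") from exc
    names: list[str] = []
    assignments: dict[str, tuple[int, int]] = {}
    for entry in entries:
        ch = str(entry["name"])
        if ch in assignments:
            raise MontageError(f"duplicate channel name: {ch!r}")
        names.append(ch)
        assignments[ch] = (int(entry["row"]), int(entry["col"]))
    return MontageGrid(
        tuple(names), height, width, assignments, name=str(cfg.get("name", name))
    )


def load_montage(source: str | Path) -> MontageGrid:
    """Load a montage from a YAML config file.

    The config declares ``height``, ``width`` and a ``channels`` list of
    ``{name, row, col}`` entries; channel order in the file is preserved as
    the canonical order.  Duplicate channels, duplicate cells and
    out-of-bounds cells are rejected.
    """
    path = Path(source)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _parse_montage_mapping(cfg, name=path.stem)


_LAYOUT_PKG = "eegtrm.layouts"


def available_layouts() -> list[str]:
    root = importlib.resources.files(_LAYOUT_PKG)
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_layout(name: str) -> MontageGrid:
    """Load one of the shipped example layouts (e.g. ``ebdsdd-7x9``, ``hgd-7x7``)."""
    root = importlib.resources.files(_LAYOUT_PKG)
    res = root / f"{name}.yaml"
    if not res.is_file():
        raise MontageError(
            f"unknown layout {name!r}; available: {available_layouts()}"
        )
    cfg = yaml.safe_load(res.read_text())
    return _parse_montage_mapping(cfg, name=name)


def _resolve_channel_order(epochs: EpochSet, montage: MontageGrid) -> np.ndarray:
    """Index array taking the epoch channel axis into montage order, by name."""
    if not epochs.channel_names:
        if epochs.n_channels != montage.n_channels:
            raise MontageError(
                f"epochs have {epochs.n_channels} channels, montage has "
                f"{montage.n_channels}, and epochs carry no channel names"
            )
        return np.arange(montage.n_channels)
    eset, mset = set(epochs.channel_names), set(montage.channel_names)
    if eset != mset:
        raise MontageError(
            "channel sets differ: "
            f"missing from epochs={sorted(mset - eset)}, "
            f"extra in epochs={sorted(eset - mset)}"
        )
    pos = {ch: i for i, ch in enumerate(epochs.channel_names)}
    return np.array([pos[ch] for ch in montage.channel_names])


def map_to_topomap(epochs: EpochSet, montage: MontageGrid) -> np.ndarray:
    """Map raw epochs (trials x C x TP) onto the grid -> trials x H x W x TP.

    Each assigned cell holds the raw potential of its channel at each time
    point; all unassigned cells are exactly 0.  Channels are matched to grid
    cells by name, never by position.
    """
    order = _resolve_channel_order(epochs, montage)
    rows, cols = montage.grid_indices()
    n, _, tp = epochs.data.shape
    stack = np.zeros((n, montage.height, montage.width, tp), dtype=epochs.data.dtype)
    stack[:, rows, cols, :] = epochs.data[:, order, :]
    return stack


def unmap_topomap(stack: np.ndarray, montage: MontageGrid) -> np.ndarray:
    """Read assigned cells back out of a topographic stack, in channel order.

    Exact inverse of :func:`map_to_topomap`: ``unmap(map(x)) == x`` bit for bit.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != montage.height or stack.shape[2] != montage.width:
        raise MontageError(
            f"stack shape {stack.shape} does not match montage grid "
            f"{montage.height}x{montage.width} (expected trials x H x W x TP)"
        )
    rows, cols = montage.grid_indices()
    return stack[:, rows, cols, :]
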