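import numpy as np
import pytest

from eegtrm.montage import EpochSet, MontageGrid
from eegtrm.synthetic import SimConfig, simulate_epochs


@pytest.fixture(scope="session")
def small_montage() -> MontageGrid:
    """6 channels on a 3x4 grid, two cells left empty."""
    names = ("A1", "A2", "B1", "B2", "C1", "C2")
    cells = {"A1": (0, 0), "A2": (0, 2), "B1": (1, 1), "B2": (1, 3),
             "C1": (2, 0), "C2": (2, 2)}
    return MontageGrid(names, 3, 4, cells, name="small-3x4")


@pytest.fixture(scope="session")
def random_montage_factory():
    """Build a random valid montage: C channels dropped onto an HxW grid."""

    def make(height: int, width: int, n_channels: int, seed: int) -> MontageGrid:
        rng = np.random.default_rng(seed)
        cells = [(r, c) for r in range(height) for c in range(width)]
        chosen = rng.choice(len(cells), size=n_channels, replace=False)
        names = tuple(f"ch{i}" for i in range(n_channels))
        assignments = {n: cells[j] for n, j in zip(names, chosen)}
        return MontageGrid(names, height, width, assignments)

    return make


@pytest.fixture(scope="session")
def random_epochs(small_montage) -> EpochSet:
    rng = np.random.default_rng(7)
    data = rng.normal(size=(5, small_montage.n_channels, 12))
    return EpochSet(data, np.zeros(5, dtype=int), 100.0, small_montage.channel_names)


@pytest.fixture(scope="session")
def easy_small_epochs(small_montage) -> EpochSet:
    """Easily separable 2-class data on the small montage, for fast training."""
    cfg = SimConfig(small_montage, n_classes=2, trials_per_class=16,
                    n_timepoints=100, sampling_rate=100.0,
                    oscillation_band=(8.0, 13.0), snr=10.0,
                    spatial_spread=0.8, seed=11)
    return simulate_epochs(cfg)
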