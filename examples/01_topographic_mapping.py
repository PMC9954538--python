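"""Map raw epochs onto the scalp grid and read them back.

Builds the 55-channel 7x9 example layout, maps a random epoch set onto it,
and verifies the two defining properties of the representation: unassigned
cells are exactly zero (no interpolation), and unmapping recovers the raw
signals bit for bit.
"""

import numpy as np

from eegtrm import EpochSet, load_layout, map_to_topomap, unmap_topomap

montage = load_layout("ebdsdd-7x9")
print(f"layout {montage.name}: {montage.n_channels} channels on a "
      f"{montage.height}x{montage.width} grid")

rng = np.random.default_rng(0)
epochs = EpochSet(rng.normal(size=(4, 55, 280)), labels=np.zeros(4),
                  sampling_rate=200.0, channel_names=montage.channel_names)

stack = map_to_topomap(epochs, montage)
print(f"topographic stack shape: {stack.shape}  (trials x H x W x TP)")

occupied = np.zeros((7, 9), dtype=bool)
rows, cols = montage.grid_indices()
occupied[rows, cols] = True
print(f"occupied cells per time slice: {occupied.sum()} of {7 * 9} "
      f"(the other {63 - occupied.sum()} are zero-filled)")

back = unmap_topomap(stack, montage)
print(f"round trip exact: {np.array_equal(back, epochs.data)}")
# The mapping only rearranges values, so it is lossless: every analysis on
# the grid can be traced back to the raw channel x time representation.
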