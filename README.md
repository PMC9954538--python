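# eegtrm

A size-preserving **topographic representation module (TRM)** for EEG
classification networks, together with everything needed to exercise it:
montage handling, three reference backbone CNNs, an epoching/preprocessing
toolkit, a synthetic-EEG generator with class-dependent spatial structure,
and a per-subject training/evaluation protocol with paired significance
tests.

## The problem

Raw EEG epochs are usually fed to convolutional networks as a C × TP matrix
(channels × time points).  That layout discards the spatial arrangement of
the electrodes on the scalp: channels that are physically adjacent may sit
far apart on the channel axis, and a 2-D convolution over the matrix mixes
unrelated channels.  The TRM restores this information *without touching
the downstream network*:

1. **Mapping block.** Each epoch is mapped onto an H × W scalp grid, one 2-D
   topographic map per time point, giving an H × W × TP stack.  Assigned
   cells carry the raw potentials unchanged; the grid cells without an
   electrode are set to exactly 0 (no interpolation).
2. **Convolution block.** A stack of stride-1, no-padding 2-D convolutions
   reduces every map to a single value per channel.  With base kernel
   k ∈ {5, 3}: while the feature map exceeds k in some dimension, a
   (min(k, h), min(k, w)) kernel is used; once it is no larger than k × k, a
   kernel of exactly the feature-map size closes the stack at 1 × 1.  Every
   layer outputs C feature maps; the first layer sees one input channel.
3. Batch normalization over the C output channels, then a reshape back to
   C × TP.

Because output shape equals input shape for every batch size and epoch
length, `backbone ∘ trm` is a drop-in replacement for `backbone`, and the
backbone's own parameters are untouched.

Under the default policy (bias-free convolutions, a single affine channel
normalization after the stack) the number of trainable parameters is

&nbsp;&nbsp;&nbsp;&nbsp; C·k₁ₕ·k₁ᵥ  +  Σ_{l≥2} C²·kₗₕ·kₗᵥ  +  2C

For the two shipped example layouts this gives exactly **46,860** (7×9 grid,
55 channels, k = 5), **18,612** (7×7, 44 channels, k = 5), **64,130** (7×9,
k = 3) and **35,332** (7×7, k = 3) — verified in the test suite both in
closed form and by enumerating the assembled module's trainable arrays.

All trainable modules (convolutions, batch normalization, pooling, Adam,
cross-entropy, backpropagation) are implemented in `eegtrm.nn` on numpy,
with finite-difference gradient tests; whole training runs are
bit-reproducible from their seeds.

## Worked example

```python
import numpy as np
from eegtrm import (SimConfig, SplitScheme, TrainingConfig, build_from_registry,
                    load_layout, simulate_epochs, split, train_eval)

montage = load_layout("ebdsdd-7x9")          # 55 channels on a 7x9 grid
epochs = simulate_epochs(SimConfig(montage, n_classes=2, trials_per_class=40,
                                   n_timepoints=280, sampling_rate=200.0,
                                   snr=10.0, seed=1))
folds = split(epochs, SplitScheme("cv4", seed=0))[:1]   # 40/20/20 trials
net = lambda seed: build_from_registry("shallow+trm-5", montage, 280, 2, seed=seed)
result = train_eval(net, folds, epochs, TrainingConfig(max_epochs=30, seed=0))
print(result.parameter_count, result.fold_accuracies, result.best_epochs)
```

prints

```
137022 [100.0] [30]
```

137,022 trainable parameters are the shallow backbone's 90,162 plus exactly
the TRM-(5,5) module's 46,860; the single rotated 50/25/25 fold reaches
100% test accuracy on this easily separable synthetic 2-class set, with the
minimum-validation-loss checkpoint taken at the final (30th) epoch.  The
schedule behind that TRM:

```sh
$ eegtrm plan 7 9 -k 5
{"input_grid": [7, 9], "base_kernel": 5,
 "layers": [[5, 5], [3, 5]], "feature_maps": [[3, 5], [1, 1]]}
```

The `examples/` directory holds one short narrative script per capability:
topographic mapping, schedule/parameter accounting, synthetic data,
epoching, and a small train-and-compare experiment.  The `eegtrm` CLI
(`plan`, `count-params`, `simulate`, `preprocess`, `train`, `compare`,
`registry`) wraps the same functions for shell use.

## Montages

Montage tables are data, not code: YAML files declaring `height`, `width`
and one `{name, row, col}` entry per channel (0-based, row 0 = frontal,
column 0 = left hemisphere).  Two example layouts ship with the package —
`ebdsdd-7x9` (55 scalp electrodes, 10-20/10-10 names) and `hgd-7x7` (44
motor-cortex electrodes, Cz excluded as reference).  Grid size and channel
count are the contract; per-cell placements are editable approximations of
the usual scalp layout.

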