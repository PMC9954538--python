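"""Epoch a continuous record: target windows, nontarget sliding windows.

Builds a continuous noise record with stimulus/response marker pairs, cuts
baseline-corrected target segments around the responses, and fills the
marker-free stretches with sliding nontarget windows subsampled to match
the target count.
"""

import numpy as np

from eegtrm import (
    EpochingConfig,
    EventStreamConfig,
    bandpass_downsample,
    epoch_nontargets,
    epoch_targets,
    load_layout,
    make_event_stream,
)

montage = load_layout("ebdsdd-7x9")
stream_cfg = EventStreamConfig(montage, n_events=8, sampling_rate=200.0,
                               gap_range_s=(20.0, 40.0), window_s=1.5, seed=3)
record = make_event_stream(stream_cfg)
print(f"record: {record.data.shape[0]} channels, {record.duration:.0f} s, "
      f"{len(record.markers['response'])} response markers")

config = EpochingConfig()  # -1300..+200 ms window, 100 ms baseline discarded
targets = epoch_targets(record, config)
print(f"target segments: {targets.data.shape}  (trials x channels x samples)")

nontargets = epoch_nontargets(record, config, n_keep=targets.n_trials)
print(f"nontarget segments: {nontargets.data.shape} "
      f"(subsampled to match the {targets.n_trials} targets)")

# each segment's baseline span had mean zero before being discarded, so the
# segments are centered relative to their own pre-response activity
print(f"segment grand mean after baseline correction: "
      f"{targets.data.mean():+.4f}")

filtered = bandpass_downsample(record, 4.0, 45.0, 100.0)
print(f"after 4-45 Hz bandpass and downsampling: {filtered.data.shape[1]} "
      f"samples at {filtered.sampling_rate:.0f} Hz")
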