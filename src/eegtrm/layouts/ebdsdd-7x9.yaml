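# Example layout: 55 scalp electrodes (10-20/10-10 system, the 59-channel
# simulated-driving montage minus the ocular-artifact-prone FP1/FP2/AF3/AF4)
# on a 7x9 grid.  Row 0 is frontal, column 0 the left hemisphere.
# Per-cell placements are an editable approximation of the scalp layout;
# grid size and channel count are the contract.
name: ebdsdd-7x9
height: 7
width: 9
channels:
  - {name: F7, row: 0, col: 0}
  - {name: F5, row: 0, col: 1}
  - {name: F3, row: 0, col: 2}
  - {name: F1, row: 0, col: 3}
  - {name: Fz, row: 0, col: 4}
  - {name: F2, row: 0, col: 5}
  - {name: F4, row: 0, col: 6}
  - {name: F6, row: 0, col: 7}
  - {name: F8, row: 0, col: 8}
  - {name: FT7, row: 1, col: 0}
  - {name: FC5, row: 1, col: 1}
  - {name: FC3, row: 1, col: 2}
  - {name: FC1, row: 1, col: 3}
  - {name: FCz, row: 1, col: 4}
  - {name: FC2, row: 1, col: 5}
  - {name: FC4, row: 1, col: 6}
  - {name: FC6, row: 1, col: 7}
  - {name: FT8, row: 1, col: 8}
  - {name: T7, row: 2, col: 0}
  - {name: C5, row: 2, col: 1}
  - {name: C3, row: 2, col: 2}
  - {name: C1, row: 2, col: 3}
  - {name: Cz, row: 2, col: 4}
  - {name: C2, row: 2, col: 5}
  - {name: C4, row: 2, col: 6}
  - {name: C6, row: 2, col: 7}
  - {name: T8, row: 2, col: 8}
  - {name: TP7, row: 3, col: 0}
  - {name: CP5, row: 3, col: 1}
  - {name: CP3, row: 3, col: 2}
  - {name: CP1, row: 3, col: 3}
  - {name: CPz, row: 3, col: 4}
  - {name: CP2, row: 3, col: 5}
  - {name: CP4, row: 3, col: 6}
  - {name: CP6, row: 3, col: 7}
  - {name: TP8, row: 3, col: 8}
  - {name: P7, row: 4, col: 0}
  - {name: P5, row: 4, col: 1}
  - {name: P3, row: 4, col: 2}
  - {name: P1, row: 4, col: 3}
  - {name: Pz, row: 4, col: 4}
  - {name: P2, row: 4, col: 5}
  - {name: P4, row: 4, col: 6}
  - {name: P6, row: 4, col: 7}
  - {name: P8, row: 4, col: 8}
  - {name: PO7, row: 5, col: 1}
  - {name: PO5, row: 5, col: 2}
  - {name: PO3, row: 5, col: 3}
  - {name: POz, row: 5, col: 4}
  - {name: PO4, row: 5, col: 5}
  - {name: PO6, row: 5, col: 6}
  - {name: PO8, row: 5, col: 7}
  - {name: O1, row: 6, col: 3}
  - {name: Oz, row: 6, col: 4}
  - {name: O2, row: 6, col: 5}
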