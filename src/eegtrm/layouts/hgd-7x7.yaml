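# Example layout: 44 motor-cortex electrodes (all central 10-10 electrodes
# except Cz, which serves as the recording reference) on a 7x7 grid.
# Row 0 is frontal, column 0 the left hemisphere.  Per-cell placements are
# an editable approximation; grid size and channel count are the contract.
name: hgd-7x7
height: 7
width: 7
channels:
  - {name: FFC5h, row: 0, col: 0}
  - {name: FFC3h, row: 0, col: 1}
  - {name: FFC1h, row: 0, col: 2}
  - {name: FFC2h, row: 0, col: 4}
  - {name: FFC4h, row: 0, col: 5}
  - {name: FFC6h, row: 0, col: 6}
  - {name: FC5, row: 1, col: 0}
  - {name: FC3, row: 1, col: 1}
  - {name: FC1, row: 1, col: 2}
  - {name: FCz, row: 1, col: 3}
  - {name: FC2, row: 1, col: 4}
  - {name: FC4, row: 1, col: 5}
  - {name: FC6, row: 1, col: 6}
  - {name: FCC5h, row: 2, col: 0}
  - {name: FCC3h, row: 2, col: 1}
  - {name: FCC1h, row: 2, col: 2}
  - {name: FCC2h, row: 2, col: 4}
  - {name: FCC4h, row: 2, col: 5}
  - {name: FCC6h, row: 2, col: 6}
  - {name: C5, row: 3, col: 0}
  - {name: C3, row: 3, col: 1}
  - {name: C1, row: 3, col: 2}
  - {name: C2, row: 3, col: 4}
  - {name: C4, row: 3, col: 5}
  - {name: C6, row: 3, col: 6}
  - {name: CCP5h, row: 4, col: 0}
  - {name: CCP3h, row: 4, col: 1}
  - {name: CCP1h, row: 4, col: 2}
  - {name: CCP2h, row: 4, col: 4}
  - {name: CCP4h, row: 4, col: 5}
  - {name: CCP6h, row: 4, col: 6}
  - {name: CP5, row: 5, col: 0}
  - {name: CP3, row: 5, col: 1}
  - {name: CP1, row: 5, col: 2}
  - {name: CPz, row: 5, col: 3}
  - {name: CP2, row: 5, col: 4}
  - {name: CP4, row: 5, col: 5}
  - {name: CP6, row: 5, col: 6}
  - {name: CPP5h, row: 6, col: 0}
  - {name: CPP3h, row: 6, col: 1}
  - {name: CPP1h, row: 6, col: 2}
  - {name: CPP2h, row: 6, col: 4}
  - {name: CPP4h, row: 6, col: 5}
  - {name: CPP6h, row: 6, col: 6}
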