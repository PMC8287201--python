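# Group-level MNI coordinates used as comparison references for the
# individualized targets. The source studies report most of these in
# Talairach space or not at all; the MNI values below were recovered by
# least-squares trilateration from the per-subject (coordinate, distance)
# tables packaged with this module (rms residual <= 0.004 mm for every
# column used), and cross-check against the inverse Brett transform of the
# published Talairach coordinates where those are printed. Edit freely for
# other reference sets.
references:
  P3:       # 10-20 electrode position projected to cortex (parietal, DMN)
    mni_mm: [-38, -66, 51]
    note: recovered from the patient table, rms 0.003 mm
  IPL:      # group-mean inferior parietal lobule coordinate
    mni_mm: [-44, -54, 46]
    note: recovered, rms 0.003 mm; Brett inverse of Talairach (-44,-51,43)
  F3:       # 10-20 electrode position projected to cortex (frontal, FPN)
    mni_mm: [-38, 25, 48]
    note: recovered, rms 0.003 mm
  BA9:
    mni_mm: [-36, 38, 40]
    note: recovered, rms 0.002 mm
  BA46:
    mni_mm: [-44, 41, 25]
    note: recovered from the control table (the patient table's BA46 column
      is internally inconsistent and is excluded by the consistency check)
  5cm:      # "5-cm rule" DLPFC landmark
    mni_mm: [-41, 15, 52]
    note: recovered, rms 0.002 mm
  BA8/9:
    mni_mm: [-36, 22, 52]
    note: recovered, rms 0.002 mm; Brett inverse of Talairach (-35,24,48)
focality_thresholds_mm: [12, 20]
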