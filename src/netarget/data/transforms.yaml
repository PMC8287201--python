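# Talairach <-> MNI conversion matrices.
#
# lancaster_*: single affines (the icbm2tal family), one fitted against
# SPM-normalized and one against FSL-normalized templates; applied as
# homogeneous 4x4 maps MNI -> Talairach, inverted exactly for the reverse
# direction.
#
# brett: the classical piecewise-linear MNI -> Talairach map, one 3x3
# matrix for z >= 0 and one for z < 0 (no translation). The two branches
# agree on the y = 0 plane at z = 0 but are genuinely discontinuous across
# z = 0 elsewhere; the inverse picks the branch whose back-projected z sign
# is self-consistent.
lancaster_spm:
  mni_to_tal:
    - [0.9254, 0.0024, -0.0118, -1.0207]
    - [-0.0048, 0.9316, -0.0871, -1.7667]
    - [0.0152, 0.0883, 0.8924, 4.0926]
    - [0.0, 0.0, 0.0, 1.0]
lancaster_fsl:
  mni_to_tal:
    - [0.9464, 0.0034, -0.0026, -1.0680]
    - [-0.0083, 0.9479, -0.0580, -1.0239]
    - [0.0053, 0.0617, 0.9010, 3.1883]
    - [0.0, 0.0, 0.0, 1.0]
brett:
  mni_to_tal_zpos:
    - [0.99, 0.0, 0.0]
    - [0.0, 0.9688, 0.046]
    - [0.0, -0.0485, 0.9189]
  mni_to_tal_zneg:
    - [0.99, 0.0, 0.0]
    - [0.0, 0.9688, 0.042]
    - [0.0, -0.039, 0.919]
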