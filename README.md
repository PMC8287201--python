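# netarget

Individualized, network-based TMS target identification from resting-state
fMRI, with the evaluation statistics used to compare individualized targets
against traditional group-level coordinates, and a synthetic phantom that
makes the whole procedure testable end to end without patient data.

## The problem

Repetitive transcranial magnetic stimulation (rTMS) trials in Alzheimer's
disease have mostly localized their targets by coarse rules — the 5-cm
rule, 10–20 EEG electrode positions (P3, F3), group-averaged Talairach/MNI
coordinates, or anatomical landmarks. None of these account for the
functional reorganization of the two cognition-critical networks disrupted
in AD: the default mode network (DMN, parietal node in the left inferior
parietal lobule, IPL) and the fronto-parietal network (FPN, node in the
left dorsolateral prefrontal cortex, DLPFC). `netarget` implements a
tailored alternative: extract each subject's own DMN and FPN from their
resting-state fMRI and place the coil on the subject-specific network peak.

## The procedure

For a 4D BOLD series (the reference acquisition is multiband, TR = 1 s,
2.1 mm isotropic, 600 volumes):

1. **Preprocess** — drop the first 10 frames, rigid realignment, temporal
   high-pass at 0.01 Hz, 4 mm FWHM Gaussian smoothing
   (`netarget.preprocess`).
2. **Decompose** — spatial ICA (PCA whitening + fixed-point unmixing) of
   the frames × voxels matrix; component maps are z-scored over the
   analysis mask and sign-fixed to non-negative skewness
   (`netarget.network_ica`).
3. **Identify** — template matching: each network label goes to the
   component maximizing the goodness of fit
   `gof = mean(z inside template) − mean(z outside template)`.
4. **Stabilize** — the decomposition is repeated 10 times; the retained map
   is the medoid of the per-run assigned components (maximal median
   absolute spatial correlation with the other runs).
5. **Target** — the selected z-map is thresholded (default z > 3) and split
   into connected clusters; cluster local maxima are candidate targets, and
   the final target must (i) be specific to its network (not suprathreshold
   in the other network's map), (ii) fall in gray matter, and (iii) minimize
   the scalp-to-cortex distance among the survivors
   (`netarget.targeting`).
6. **Validate** — a 6 mm spherical seed at the selected coordinate produces
   a whole-brain correlation map that should match its own network's ICA
   map under the same goodness-of-fit score (`netarget.seed_validate`).

`netarget.coord_eval` provides the comparison statistics: Euclidean
distances to group-level reference coordinates, the **exact** one-sample
Wilcoxon signed-rank test (with ties) against assumed TMS focality
thresholds of 12 mm (conservative) and 20 mm (lenient), sensitivity /
selectivity of group coordinates with respect to individual network maps,
Brett and Lancaster Talairach↔MNI transforms, atlas labeling, and a
trilateration oracle that recovers an unprinted reference coordinate from
per-subject (coordinate, distance) pairs — and thereby audits published
distance tables for internal consistency.

`netarget.phantom` generates the deterministic synthetic ground truth: two
band-limited (0.01–0.08 Hz), mutually orthogonal network time courses drive
Gaussian nodes inside an ellipsoidal head with a gray-matter shell; one
node is planted in *both* networks so that selection criterion (i) is
exercised, and node depths are arranged so that criterion (iii) alone would
pick the wrong (shared) node.

## Worked example

`python examples/01_phantom_to_targets.py` runs the full procedure on the
default phantom (32×38×32 voxels at 4 mm, 200 frames, noise SD 0.5 = node
SNR 2) and prints:

```
label  x_mm  y_mm  z_mm  z_value  scalp_distance_mm  classification_frequency seed_match
  DMN -30.0 -38.0  22.0   15.466               5.66                       1.0        DMN
  FPN -30.0  42.0  18.0   15.498               5.66                       1.0        FPN

DMN: chosen (-30.0, -38.0, 22.0) mm, planted (-30.0, -38.0, 22.0) mm -> error 0.0 mm (0.0 voxels)
   rejected (-46.0, -2.0, 18.0): criterion_i_network_specificity
   rejected (-6.0, -38.0, 26.0): criterion_iii_deeper_than_chosen
FPN: chosen (-30.0, 42.0, 18.0) mm, planted (-30.0, 38.0, 18.0) mm -> error 4.0 mm (1.0 voxels)
   rejected (-46.0, 2.0, 22.0): criterion_i_network_specificity
   rejected (-18.0, -18.0, 30.0): criterion_iii_deeper_than_chosen
```

Both targets land within one voxel of the planted nodes; the candidate at
the node shared by both networks — although it is the most superficial and
would win on depth alone — is rejected by the network-specificity
criterion, and each seed-connectivity map matches its own network.

`python examples/02_table_statistics.py` reproduces the published
per-subject statistics from the packaged cohort tables: pairwise-distance
medians of 20.39 / 21.68 mm (13 AD patients, IPL / DLPFC) and 21.35 /
15.75 mm (8 controls), trilaterated reference coordinates (e.g. P3 at MNI
(−38, −66, 51) with 0.003 mm rms residual), the exact Wilcoxon p-values
(p = 0.0002 at 12 mm, p = 0.342 at 20 mm for the patient P3 column), an
automatically repaired control-table row whose printed coordinate
contradicts its own distance cells, and the automatic exclusion of the
patient BA46 column, which is internally inconsistent.

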