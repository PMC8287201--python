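# Methods

This note documents the models, numerical choices and open design
decisions behind `netarget`, and what the phantom-based tests do and do
not establish about real data.

## Coordinate conventions

Voxel indices are 0-based; world coordinates are mm in a RAS+ frame
(negative x = left), matching how MNI coordinates are reported in the TMS
literature. Affines map homogeneous voxel indices to world mm and must be
invertible with strictly positive column norms. Nonlinear spatial
transforms are consumed as precomputed displacement-field volumes
(three mm-offset components on a grid, sampled trilinearly); estimating
such warps is out of scope. Out-of-view resampling fills with 0, the
background value of masks and z-maps.

## Synthetic phantom

The phantom emulates a single-subject resting-state acquisition at desk
scale: 32×38×32 voxels at 4 mm isotropic, 200 frames at TR = 1 s (the
reference acquisition it stands in for is 2.1 mm / 600 volumes; the
full-size geometry is reachable through `PhantomSpec` but unnecessary for
testing). Components:

* **Head/gray matter** — an ellipsoidal head (radii 56×68×54 mm); the
  gray-matter shell is the set of voxels 4–20 mm below the scalp surface
  (Euclidean distance transform), and the analysis ("brain") mask is
  everything at least 4 mm deep.
* **Networks** — two networks of Gaussian nodes (FWHM 14 mm). Each network
  has one superficial specific node (≈9–10 mm deep; the intended target),
  one deep node (≈19–20 mm), and one node shared by both networks
  (≈8 mm, the most superficial). Because the shared node is the
  shallowest, depth minimization alone would select it — only the
  network-specificity criterion rejects it, which is exactly what the
  end-to-end tests verify.
* **Shared-node amplitude 0.6.** A shared blob as strong as the
  network-defining nodes (amplitude 1) makes the *sum* and *difference* of
  the two networks sparser than the networks themselves, and an
  independence-based decomposition then returns sum/difference components
  — the two "networks" are simply not identifiable. At 0.6 the networks
  separate cleanly (|r| > 0.99 against truth, noiseless) while the shared
  node remains far suprathreshold (z ≈ 8–9) in both estimated maps.
* **Time courses** — white noise band-passed to 0.01–0.08 Hz (the typical
  resting-state band; only the high-pass edge is externally specified),
  then QR-orthogonalized inside the band and scaled to unit variance, so
  planted time courses are exactly uncorrelated.
* **Noise and baseline** — i.i.d. Gaussian noise, default SD 0.5 (node
  SNR 2), plus a static anatomy-shaped baseline added to every frame.
  Real BOLD frames are dominated by a time-invariant image; without the
  baseline, frame-to-frame registration has nothing to lock onto and
  "motion correction" of the pure signal+noise movie injects large
  spurious shifts. A corollary: the noiseless data matrix has rank 2 only
  after per-voxel demeaning (the baseline contributes one more dimension).

Everything is deterministic given the seed.

What passing phantom tests shows: the pipeline's logic — decomposition,
matching, reliability, the three criteria, seed validation — behaves
correctly when its assumptions hold. What it does not show: robustness to
physiological noise, motion beyond small rigid shifts, susceptibility
distortion, inter-subject anatomical variability, or network structure
more entangled than two overlapping sparse maps.

## Preprocessing

* Frame trimming removes the initial non-equilibrium volumes (default 10).
* Realignment is a simplified intensity-based re-implementation:
  translation via phase cross-correlation (upsampled 20×, i.e. 0.05-voxel
  resolution), or full rigid-body by Powell search over 6 parameters
  seeded by the translation estimate, with mean-squared-error cost on the
  reference support. It is adequate for phantoms and small motions; it is
  not a production motion corrector. Default mode is `translation`.
* The temporal high-pass (default 0.01 Hz) is a zero-phase order-4
  Butterworth (`sosfiltfilt`), chosen so seed time courses are not phase
  distorted; a discrete-cosine drift-regression variant is available
  (`highpass_method="dct"`). Output is exactly demeaned per voxel.
* Smoothing (default 4 mm FWHM) converts FWHM to per-axis voxel sigmas
  (σ = FWHM / 2√(2 ln 2) / voxel size). Filter-then-smooth is the default
  order; the reverse is a flag, since the upstream tooling does both inside
  one step and does not document the order.

## Spatial ICA and template matching

The decomposition treats voxels as samples and frames as features: PCA
whitening to `n` dimensions followed by fixed-point ICA (logcosh contrast,
symmetric decorrelation, tol 1e-4, max 500 iterations; scikit-learn's
FastICA, seeded). Independent sources are therefore spatial maps with
paired mixing time courses. Maps are z-scored over the analysis mask
(mean 0, SD 1) and oriented so their skewness is non-negative. Note that
spatial whitening decorrelates the *maps*; the paired time courses of a
spatial ICA are in general correlated, and no constraint is placed on
them.

**Dimensionality.** `n_components="auto"` counts covariance eigenvalues
above the Marchenko–Pastur noise edge, with the noise level taken from the
median eigenvalue, bounded to [2, frames/10] and the numerical rank; on
noiseless data this reduces to the rank. A simpler cumulative-variance
rule (n such that the top components first reach 90%) is available but
saturates at the upper bound once noise dominates the spectrum, and the
resulting over-extraction makes the unmixing leak each network into the
other's map — which is why the noise-edge rule is the default. The
pipeline estimates `n` on trimmed/filtered but **unsmoothed** data:
the signal subspace is a temporal property, while smoothing correlates
voxels and breaks the i.i.d.-noise model behind the edge estimate.

**Template matching.** The score is `mean(z inside) − mean(z outside)`
over the analysis mask, with the template binarized at its threshold
(Pearson spatial correlation is a config alternative). The published
procedure names template matching but not its formula; the
inside-minus-outside mean is standard and robust to template size
imbalance. Label assignment is greedy over descending score with
deterministic tie-breaks (higher score, then lower component index); a
component may win at most one label.

**Reliability.** The decomposition is repeated 10 times (seeds derived as
`seed·1000 + run`). Among the per-run components assigned to a label, the
retained map is the **medoid** — maximal median absolute spatial
correlation with the other runs' assignments (absolute, because ICA signs
are indeterminate) — together with the classification frequency
(assigned runs / total runs). "Most frequently classified" is ambiguous
when distinct maps split the assignments; the medoid is our deterministic
resolution.

## Targeting

Clusters are connected components of {z > threshold} (default 3.0 — the
cluster-forming threshold is not externally specified and is recorded in
the selection audit) under configurable 6/18/26-connectivity (default 26,
matching common cluster tooling). Candidate targets are cluster local
maxima: voxels ≥ all 26 neighbors, greedily thinned to a minimum pairwise
separation (default 8 mm), higher z first, lexicographic voxel index on
ties (one survivor per flat plateau).

The selection criteria:

1. **Network specificity** — reject candidates whose location is
   suprathreshold in the other network's map (threshold defaults to the
   cluster-forming z; evaluated at the candidate's voxel, with an optional
   neighborhood-max radius for coarse grids, default off).
2. **Gray matter** — mask membership (or probability ≥ 0.5 for
   probabilistic maps).
3. **Depth** — minimal scalp-to-cortex distance among survivors, computed
   as the Euclidean distance to the nearest outer-scalp surface voxel
   (head voxels with a 6-neighbor outside the head). "Shortest
   perpendicular path" is operationalized as this nearest-surface
   distance — the foot of the perpendicular onto a locally planar scalp;
   a surface-normal path would differ on strongly curved scalp.

The original workflow picks "the largest cluster in the region of
interest" by eye; the reproducible stand-in is an explicit search region
(world-mm box or mask) restricting the suprathreshold set. If every
candidate is rejected, selection fails loudly with the per-candidate
reasons — there is no silent fallback.

## Evaluation statistics

* **Pairwise spread** — all C(n,2) Euclidean distances, median and
  linear-interpolation (type-7) quartiles; report rounding is 2 decimals,
  matching the source tables.
* **Exact Wilcoxon** — one-sample signed-rank against a focality threshold
  μ ∈ {12, 20} mm, one-sided "greater" by default (the question is whether
  distances *exceed* focality; one-sided exact p reproduces the published
  values where the table is internally consistent, two-sided does not).
  Zero differences are dropped; tied |differences| get average ranks. For
  n ≤ 25 the p-value is exact: the null distribution of W⁺ conditional on
  the observed |differences| is accumulated by a subset-sum count over
  doubled ranks (integer even with .5 average ranks) — equivalent to full
  2ⁿ sign enumeration, verified against it in tests. Above n = 25, normal
  approximation with tie-corrected variance (Σr²/4) and continuity
  correction. The hand-rolled exact path exists because the standard
  library implementation refuses exact computation under ties.
* **Sensitivity / selectivity** — for a group-level coordinate:
  sensitivity = fraction of subjects whose expected-network map contains
  the coordinate (value at its voxel > threshold); selectivity = among
  contained subjects, the fraction *not* also inside the other network's
  map (undefined, flagged None, when sensitivity is 0). Subjects whose
  field of view excludes the coordinate are dropped from denominators and
  reported.
* **Talairach↔MNI** — Lancaster (two affine variants, SPM- and FSL-fitted,
  inverted exactly) and Brett (piecewise 3×3, branching on the MNI z sign;
  the inverse picks the branch whose back-projected z sign is consistent).
  The Brett map is genuinely discontinuous across z = 0 except on the
  y = 0 plane; the continuity test checks it there.
* **Trilateration** — least squares for x in |x − cᵢ| = dᵢ by differencing
  the squared equations, polished by Gauss–Newton; requires ≥ 4
  non-coplanar points (singular-value check, ConditioningError otherwise).

## Packaged tables and the consistency/repair oracle

Two per-subject coordinate tables (13 patients, 8 elderly controls) ship
as TSV fixtures, along with a reference-coordinate config recovered by
trilateration (P3 (−38,−66,51), IPL (−44,−54,46), F3 (−38,25,48),
BA9 (−36,38,40), 5-cm (−41,15,52), BA8/9 (−36,22,52), BA46 (−44,41,25);
rms ≤ 0.004 mm on every column used). Two of these cross-check against the
inverse Brett transform of published group Talairach coordinates.

The trilateration residual doubles as an integrity audit of the printed
tables:

* a column consistent over all rows (rms ≤ 0.02 mm) is accepted;
* a column that becomes consistent after removing exactly one row marks
  that row as an outlier; a row flagged by ≥ 2 reference columns is
  **repaired** by solving its printed distances on the 2-mm integer
  lattice all table coordinates live on — accepting only a unique
  solution. In the control table this pins row Ctrl 3 to (−54,−70,18)
  (printed (−54,−72,26)), which simultaneously restores the printed
  pairwise median (21.35 mm) that the printed coordinates alone cannot
  produce. The repair never references the statistic being reproduced,
  only the row's own distance cells.
* a column consistent under no single-row removal is flagged inconsistent
  and excluded from exact checks. The patient BA46 column is the one such
  case (five of its cells duplicate the 5-cm column); its printed
  p-values also fail to reproduce, consistent with column-level
  corruption rather than a defect of the test implementation.

## Problem sizes and determinism

The default test and acceptance workloads use the desk-scale phantom
(32×38×32 × 200 frames, ~9,000 mask voxels), 10 ICA repetitions per
pipeline run and 5 pipeline seeds — about 15 s per seed on one core. One
global seed fixes phantom noise and all derived ICA seeds; identical
configurations produce byte-identical outputs.

## Known limitations

* Realignment is simplified (see above); rigid-body mode is slow on large
  volumes (Powell per frame).
* The MP dimensionality estimator assumes spatially uncorrelated noise;
  it is therefore applied before smoothing, and will over-count on data
  whose raw noise is strongly spatially correlated.
* Scalp-cortex distance uses voxelized surfaces (half-voxel scale error).
* Sensitivity/selectivity and seed-map matching are reproduced at
  property level on phantoms; the published cohort-level percentages
  require the original raw fMRI and are not reproducible here.
* The criterion-(iii) interpretation (nearest-surface distance) and the
  criterion-(i) threshold reuse (other-network threshold = cluster
  threshold) are documented choices where the source procedure is
  underspecified.
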