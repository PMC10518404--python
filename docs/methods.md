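# Methods

## Model and procedure

`qcdseg` implements ensemble segmentation with built-in, ground-truth-free
quality control. The assumption doing the work is that *inter-candidate
agreement carries information about accuracy*: when independently trained
segmenters of different capacity agree, the consensus is usually right, and
a candidate that diverges from the rest of the pool is usually wrong. The
pipeline per image is

1. preprocess: min–max scale intensities to [0, 1] (a constant image maps to
   all zeros), zero-pad symmetrically to a square grid, extra pixel on the
   trailing side;
2. N encoder–decoder networks (depths 1…N levels) each produce a single
   candidate segmentation by per-pixel argmax over a 2-class softmax;
3. rank filters over the SCS stack add one combined candidate per vote
   threshold k = 1…N (k = 1 union, k = N intersection; outputs nested
   monotonically in k), giving 2N candidates;
4. the symmetric pairwise-Dice agreement matrix over all candidates is
   computed (both-empty pairs count as Dice 1: two observers agreeing there
   is no myocardium agree perfectly; one-empty pairs as 0);
5. per candidate position, a linear regressor maps that candidate's
   off-diagonal matrix row (2N−1 agreements) to predicted Dice, clipped to
   [0, 1];
6. the argmax-predicted candidate is returned with a pass/fail flag at a
   Dice threshold of 0.7.

The regressors are ordinary least squares with intercept, fitted on the
validation split only — never on the networks' training images, which would
couple the quality model to training-set overfitting. If a fit is
under-determined (fewer validation images than 2N features + intercept) the
implementation falls back to ridge regression with a small fixed penalty
(alpha = 1e-3) and warns.

## Segmentation networks

The networks are conventional U-Nets built on a small numpy CNN core written
for this package (im2col/GEMM convolutions with hand-derived backward passes,
verified against float64 finite differences; Adam; inverted dropout;
validation-loss early stopping that restores the best epoch's parameters).
Architecture choices the contract leaves open were fixed as:

* convolution block = two 3×3 convolutions + ReLU (standard U-Net
  convention);
* filters: `base_filters` at level 1, doubling per level, capped at 512;
* dropout: linear ramp from 0.05 (level 1) to 0.5 (deepest level),
  non-decreasing with depth to regularise the deeper, wider levels harder;
* skip connections taken before dropout/pooling, concatenated after the
  matching transposed-convolution upsampling;
* 2-class softmax head (background / myocardium); multi-structure labels are
  out of scope.

Training defaults mirror the clinical-scale protocol (categorical
cross-entropy, Adam, learning rate 5e-5, up to 200 epochs, early stopping);
the shipped desk-scale config (`configs/desk.yaml`) instead uses learning
rate 1e-3 for ≤15 epochs, because on a ~200-image phantom cohort 5e-5 moves
a freshly initialised network too little to be informative at that epoch
budget. Seeded runs reproduce the epoch-1 loss bit-exactly; full-run
determinism additionally holds in practice on a fixed BLAS but is only
promised for epoch 1.

## Phantom generator

Each patient slice is an annulus (the LV myocardium) around a bright blood
pool on a darker background, with an optional hyperenhanced lesion sector
inside the ring (image only — the mask is always the full ring, matching how
myocardial contours are drawn irrespective of scar). Two contrast modes
render the same anatomy with different piecewise-constant intensity levels
and independent Gaussian noise; anatomy is a deterministic hash of
(seed, patient_id, slice_index) and *never* of mode, so LGE-like/VNE-like
pairs are pixel-exact augmentation pairs — the phantom analogue of
position-matched virtual-enhancement data. A configurable fraction of
patients (default 15%) have pool and wall intensities blended toward each
other (blend 0.72), which degrades the contrast the networks rely on while
leaving the ground-truth mask valid; these hard cases are what gives the QC
arm true negatives to detect.

Defaults: 64×64 grid, inner radius 8–13 px, wall 4–8 px, centre jitter
±4 px, noise sigma 0.05, lesion probability 0.3 with a 40–120° arc. A
256×256 configuration with proportionally scaled radii is provided. The
phantom reproduces the *statistical structure* the framework needs (shared
anatomy across modes, inter-patient variability, graded difficulty); it does
not emulate MR physics, partial-volume fuzziness, papillary muscles,
through-plane motion or scanner artefacts, so passing results bound what the
pipeline can do on clean geometry, not clinical performance.

Cohort splitting is at patient level (all slices and both modes of a patient
share a split) with largest-remainder rounding of the 85/7.5/7.5 fractions
after a seeded patient shuffle; splits with fewer than three patients are
refused. Hard-case counts round to the nearest integer (halves up). No
stratification beyond patient grouping is attempted.

## Quality-model calibration bench

`qcdseg.perturb` builds candidate pools directly from ground-truth masks by
graded binary erosion/dilation (0–3 iterations) plus random pixel flips, so
every candidate's true Dice is known exactly without training networks.
Severity for candidate i is q·(0.5 + 0.5·(i+1)/N) with an image-level
quality draw q (75% of images q ~ U(0.05, 0.45), 25% q ~ U(0.75, 1.4)); the
0.5 floor ties all candidates of a bad image down so that images with *no*
acceptable candidate exist. This bench is deliberately easier than live
network candidates — perturbations are centred on the truth, so agreement is
an almost deterministic function of severity — and is used to verify
calibration machinery (held-out MAE, QC accuracy, selection dominance), not
to claim clinical error rates.

## Evaluation protocol

Reports carry mean Dice ± population s.d. (ddof = 0), MAE of
|predicted − observed| Dice computed on the *selected* candidate only,
binary QC accuracy and the TP/TN/FP/FN confusion at threshold 0.7, and
per-mode subgroups. Across the two contrast modes a two-sided Wilcoxon
signed-rank test is applied, paired by (patient, slice) anatomy when both
modes are present (identical paired values short-circuit to p = 1), with a
rank-sum fallback for unpaired or tiny samples. The experiment grid crosses
training composition (mode A / mode B / both) with test composition on one
shared patient-level split, retraining the full pipeline per row with the
same seed; the single-network comparator reports Dice only, since it has no
QC arm.

Problem sizes in the shipped studies — 60 patients × 2 slices × 2 modes,
depths 1–3 with 8 base filters, ≤15 epochs, and 200-image calibration
pools — were chosen as the smallest scale at which the framework's
behaviour (selection gain, augmentation direction, QC taxonomy) is stable
across seeds.

## Known limitations

* The numpy CNN is single-threaded-BLAS CPU code; full-scale 256×256 ×
  six-depth × 200-epoch training is supported but slow.
* Linear regressors assume an approximately linear agreement→Dice map;
  candidates produced by systematically biased segmenters (all wrong the
  same way) would inflate predicted Dice — agreement cannot detect
  consensus error. This is intrinsic to the method, not the implementation.
* Binary (not per-class) rank voting; a multi-class generalisation would
  vote per label.
* Phantom realism limits noted above; no pathology subgroups and no scar
  quantification.
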