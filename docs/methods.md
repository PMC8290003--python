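# Methods

## The assay model

Each cell's activation state is summarized by the nuclear/cytosolic ratio
*r* of the transcription-factor channel's mean fluorescence intensity
(arithmetic mean over region pixels — "mean fluorescence intensity" taken
literally, not a median). Per sample of *n* cells:

- **mode** *m* — the most frequent ratio, estimated from the sample's own
  cells;
- **threshold** τ = *k·m* with *k* = 1.5 (strictly greater-than: a cell at
  exactly τ is not translocated);
- **prevalence** *P* = 100 · #{*rᵢ* > τ} / *n*;
- **aberrant strength** *S* = Σ *rᵢ* over cells with *rᵢ* > τ (the sum of
  the ratios themselves; an `excess_sum` variant summing *rᵢ* − τ is
  available behind a flag but is not the default reading);
- **responder** — *P* ≥ 5%.

The threshold is always anchored to the same sample's cells, never to a
pooled healthy reference, so the score is self-calibrating: multiplying
every intensity (or every ratio) in a sample by a constant leaves the
count of translocated cells unchanged.

### Mode estimation

"Most frequent ratio" is not a uniquely defined estimator for continuous
data, so two are provided:

- **kde** (default): argmax of a Gaussian kernel density (Silverman
  bandwidth, or fixed) evaluated on a 512-point grid over [0, max ratio];
  smooth and binning-free for the 75–100 ratios a sample typically has.
  Ties break to the smallest grid value.
- **histogram**: center of the most populated fixed-width bin (default
  width 0.05, bins anchored at 0, ties to the lowest bin); exact and
  convenient for hand-checkable tests.

The two agree to within a bin width on well-separated mixtures (asserted
in tests). Samples whose ratios are all identical return that common value
directly. Degenerate inputs (fewer than 2 usable cells, non-finite or
non-positive ratios) are errors; samples below 75 usable cells are scored
with a warning flag rather than rejected, since the 75–100 range describes
the intended acquisition regime, not a hard QC gate.

## Segmentation and measurement

Nuclei are thresholded from the DNA-stain channel (Otsu by default; a
fixed threshold is available for reproducible fixtures), connected
components are labeled, regions outside [50, 2000] px² are dropped,
border-touching nuclei are removed by default, and touching nuclei can be
split by a distance-transform watershed (`split_touching`).

The cytosolic measurement region of each cell is a **ring of width 4 px**
around its nucleus, separated from the nucleus boundary by a **1-px guard
gap** so nuclear signal cannot bleed into the cytosolic estimate. Pixels
contested between cells are assigned to the nearer nucleus via a single
Euclidean distance transform, which also makes the assignment
deterministic. Whether the original pipeline this emulates measured
cytosol as a ring or as whole-cell-minus-nucleus is unknowable from its
description; the ring was chosen because it needs no whole-cell channel
and is robust for round suspension cells spun onto glass. Cells whose ring
comes out empty are QC-excluded with a reason code, and excluded ids are
removed from both label images so every segmented id is either fully
retained or fully excluded.

MFIs are measured on the TF channel only. Background subtraction is off by
default (the simplest reading of an MFI ratio); a `global_median` option
subtracts the median intensity of pixels outside every region, floored at
0. Cells whose cytosolic MFI is at the division-guard floor (1e-6
intensity units) are excluded rather than clipped, so the ratio
distribution never contains artifact infinities.

## The synthetic-data generator

The simulator emulates the statistical structure of the assay's human
study, not its optics:

- **Geometry**: cells are disks (radius 12–16 px) with concentric circular
  nuclei (radius fraction 0.55), placed by rejection sampling with a
  minimum 8-px gap on a 768×768 px field; the assay only needs a nuclear
  vs a cytosolic region, so disks exercise every measurement path.
  The gap and field size keep 100-cell packings feasible and cytosolic
  rings (guard 1 + width 4 px ≤ annulus width ≥ 5.4 px) inside the true
  cytosol, so the noise-free round trip is exact.
- **Ratios**: a two-component truncated-normal mixture. Baseline mean 0.58,
  SD 0.07 — the modal ratio regime of resting monocytes. The translocated
  component (mean 1.2, SD 0.15) is a free parameter: real data constrain
  only that translocated ratios sit well above 1.5× the mode; 1.2 ≈ 2× the
  baseline mode puts the component clearly above threshold while leaving a
  realistic small classification overlap.
- **Rendering**: channel 2 is piecewise-constant per cell (nuclear plateau
  = ratio × cytosolic plateau of 2000 AU; nuclear stain 8000 AU), with
  optional Poisson shot noise followed by additive Gaussian read noise
  (default SD 10 AU) — the standard fluorescence noise model. Per-sample
  cell counts default to uniform 75–100.
- **Truth**: the number of translocated cells is exactly
  round(fraction × n) so tests can assert integers; a binomial mode exists
  behind a flag.
- **Cohorts**: the default cohort is 25 healthy donors
  (Beta(1, 60) translocated fractions, median ≈1%) plus 18 active-phase
  and 26 remission-phase patients drawn from a common Beta(1.3, 17)
  (quartiles ≈3–10%), mirroring a study in which prevalence stays elevated
  in remission, with activity scores straddling the active/remission
  boundary at 5. An expression covariate is log-linearly coupled to true
  prevalence (slope 0.15 per percentage point, log-scale noise SD 0.8);
  only its monotonicity matters downstream, so any monotone coupling is
  faithful.
- **qPCR**: Ct = reference Ct − log₂(expression) + noise, i.e. perfect
  amplification doubling; the reference gene is forced to fold change 1 in
  every group.

What the simulator does **not** model: distinct immune-cell types, antibody
chemistry, confocal optics (PSF, z-stacks), uneven illumination, or
cell-shape variation. Passing tests therefore demonstrate correctness of
the measurement and scoring machinery on images satisfying the assay's
geometric assumptions, not robustness to real-microscopy artifacts.

## Statistics

- **Mann–Whitney U** (two-sided): U from mid-ranks; exact enumeration of
  the null when both groups have ≤10 observations and no ties, otherwise
  the normal approximation with tie correction and 0.5 continuity
  correction. The result records which path ran. The boundary at 10 keeps
  the exact path testable by brute-force enumeration.
- **Spearman** (two-sided): Pearson correlation of mid-ranks; p from the
  t approximation with n−2 df; an exact permutation p is available for
  n ≤ 8. Constant inputs are errors (the correlation is undefined).
- **ΔΔCt**: ΔCt = Ct_target − Ct_reference per sample;
  ΔΔCt = ΔCt − mean ΔCt of the calibrator group (arithmetic mean chosen as
  the calibrator aggregate); fold change = 2^(−ΔΔCt) exactly. Technical
  replicates are averaged before the computation.
- **Group summaries**: median and quartiles by linear interpolation.
- Student/Welch/paired t tests are thin scipy wrappers sharing the result
  shape. No multiple-testing correction is applied by default (a Holm
  adjuster is provided but off), matching how such cohort panels are
  usually reported.

Scipy provides the distributional machinery throughout; this module pins
the exactness boundaries, sidedness and result shapes.

## Numerical choices

- Strength sums accumulate left-to-right over cells so results are
  bit-identical to a per-cell loop.
- Pixel coordinates are 0-based, row-major and pixel-centered; a pixel
  belongs to a disk when its center is within the radius.
- KDE grid: 512 points; histogram bins anchored at 0.
- p-values are clipped into (0, 1].
- All simulator outputs are bit-reproducible given (config, seed); cohort
  and acceptance runs derive per-sample seeds from one generator.

## Problem sizes

The test suite and the acceptance script use 10–20 rendered images of
~75–100 cells, 20-seed ensembles for recovery/cohort checks, and 10k draws
for mode-estimator fidelity — sizes at which every check runs in seconds
while estimator variance is already far below the asserted tolerances.

## Known limitations

- Prevalence is computed over QC-passing cells; if QC exclusions correlate
  with translocation state in real data, prevalence would be biased.
- The ring cytosol underestimates cytosolic signal for highly non-circular
  cells; a whole-cell-minus-nucleus variant would need a cell-boundary
  channel the pipeline deliberately does not require.
- The KDE mode on small samples (<30 cells) is noisy; the low-cell warning
  flags this but scoring proceeds.
- The exact Mann–Whitney path refuses ties; tied data always use the
  corrected normal approximation, whose p-values are approximate for very
  small samples.
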