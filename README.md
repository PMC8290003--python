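# ntquant

Quantification of transcription-factor nuclear translocation from
two-channel fluorescence microscopy, with the cohort statistics used to
compare translocation scores between donor groups.

## The problem

Transcription factors such as IRF5 signal by moving from the cytoplasm
into the nucleus. In immune cells imaged by confocal microscopy (a DNA
stain in one channel, TF immunofluorescence in the other), activation can
be read out per cell as the **nuclear/cytosolic ratio** of the TF signal's
mean fluorescence intensity (MFI):

&nbsp;&nbsp;&nbsp;&nbsp;*r*ᵢ = MFI(nucleus) / MFI(cytosol)

Resting cells cluster tightly around a modal ratio (≈0.58 in monocytes),
while translocated cells sit well above it. Each sample of 75–100 cells is
scored against its **own** distribution: the most frequent ratio *m* is
estimated (KDE mode by default), and cell *i* is called translocated when

&nbsp;&nbsp;&nbsp;&nbsp;*r*ᵢ > 1.5 · *m*.

Per-sample outputs are the translocation **prevalence** (% of cells above
threshold), the **aberrant strength** *S* = Σ *r*ᵢ over translocated cells,
and a **responder** call (prevalence ≥ 5%). Because the threshold is
anchored to the sample's own mode, the score is invariant to staining
intensity differences between samples.

The package covers the full pipeline: a synthetic image/cohort/qPCR
simulator with known ground truth, nuclear segmentation (Otsu or fixed
threshold, optional watershed splitting), cytosolic-ring region definition,
per-cell MFI measurement, mode-anchored scoring, and cohort statistics
(two-sided Mann–Whitney U, Spearman rank correlation, ΔΔCt relative
expression, median/IQR summaries).

## Worked example

`examples/score_one_sample.py` renders one image of 80 cells with a true
translocated fraction of 10%, segments, measures and scores it:

```
cells measured:        80
modal N/C ratio:       0.579   (true baseline mode 0.58)
threshold (1.5x mode): 0.869
translocated cells:    8  (10.0%)   (true fraction 10%)
aberrant strength:     9.57
responder (>=5%):      True
```

The recovered mode sits at the simulated resting value, and the scored
prevalence matches the simulated fraction exactly here (it is accurate to
a few percentage points in general). `examples/cohort_comparison.py` runs
a three-group cohort (healthy / active / remission) end to end:

```
  healthy vs active     U= 111.0  p=0.0051  (normal_approx_tie_corrected)
  healthy vs remission  U= 112.0  p=0.0001  (normal_approx_tie_corrected)
   active vs remission  U= 162.5  p=0.0901  (normal_approx_tie_corrected)

prevalence ~ expression (patients): rs=0.692, p=1.9e-07, n=44
```

Both patient groups score significantly above healthy donors, the two
patient phases are statistically indistinguishable (aberrant translocation
persists in remission), and prevalence rank-correlates with the coupled
expression covariate. `examples/qpcr_fold_change.py` shows ΔΔCt fold-change
recovery from a simulated Ct table.

A thin CLI mirrors the library (`ntquant simulate sample|cohort|qpcr`,
`ntquant segment|measure|score|cohort`); run any subcommand with `--help`.

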