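# Methods

## Problem

The *Crithidia luciliae* indirect immunofluorescence test (CLIFT) detects
anti-dsDNA autoantibodies, a diagnostic hallmark of systemic lupus
erythematosus. The substrate cell carries a kinetoplast — a dense network
of mitochondrial dsDNA — whose green (FITC) fluorescence alone defines a
positive reaction; fluorescent nuclei or basal bodies are diagnostic noise.
Each biochip is photographed twice through co-mounted cameras: the green
channel carries the antibody-specific signal, the red channel the Evans
blue counterstain that renders every cell visible regardless of antibody
status. `clift` turns such image pairs into per-cell, per-image and
per-sample positive/negative calls with titer estimates.

## Pipeline

1. **Registration.** The green channel is aligned onto the red by the
   integer-pixel translation maximizing cross-correlation (plain, not
   phase-whitened, because the two channels share structure but not
   content). Rigidly co-mounted dual cameras justify translation-only
   registration. A shift above 5% of the image width, or near-zero
   correlation despite a structured green channel, flags the pair as
   unregistrable. A featureless green channel — an all-negative biochip —
   registers trivially at (0, 0): negativity must never be mistaken for a
   registration or focus failure.
2. **Focus.** Sharpness is scored on the red channel only, as the variance
   of a 3×3 Laplacian after light Gaussian denoising (σ 1 px), normalized
   by the squared mean intensity. The denoising stops sensor read noise
   from dominating the edge response, making the score strictly decreasing
   in defocus blur. Default threshold 0.008 accepts the simulator's
   nominal optics (blur σ 0.8 px) and rejects blur σ ≳ 2.5 px.
3. **Artefacts.** Incubation artefacts are masked as (a) bright connected
   components larger than any plausible cell (default > 2000 px at test
   scale) under a robust global threshold (median + 0.10), and (b)
   saturated components larger than 400 px. Small saturated spots are
   deliberately spared: a strongly positive kinetoplast may legitimately
   clip a few dozen pixels. Images whose artefact fraction exceeds 0.25
   are rejected.
4. **Segmentation** (red channel): adaptive threshold = local mean over an
   81 px window (≈ 2× cell length) plus max(2 × local SD, 0.05), followed
   by a binary opening (disk r=1) and 8-connected labelling; components
   under 50 px or touching the artefact mask are dropped. Touching-cell
   clumps are not split — they fail shape QC downstream, mirroring the
   strategy of excluding defective masks rather than repairing them.
5. **Cell QC.** Area within [0.3×, 3×] the per-image median, aspect ratio
   in [2, 12], solidity ≥ 0.85 (the elongated body is convex; fused cells
   are not). Violations are named per feature ("area", "ellipse_form",
   "convex_defect").
6. **Dark-cell rule.** A cell is negative without further analysis when
   its mean green intensity is below background mean + k·SD (k = 3). If
   *every* evaluable cell is dark the image is set negative and the
   classifier is never invoked — observable through the model's
   invocation counter.
7. **Orientation and axis profile.** The main axis comes from the second
   central moments of the mask; the 180° ambiguity is resolved by placing
   the red-intensity centroid (the wide, nucleus-bearing half of the
   tapered body) in the upper half of the profile, so the basal body maps
   near 0 and the nucleus near 1. Cells with aspect ratio < 1.3 have no
   reliable axis and are excluded. Green intensities are sampled in a
   fixed-width corridor around the axis (half the minor semi-axis, at
   least 1.5 px) so bin means do not depend on the body taper, binned into
   32 equal axis segments (≥ 4 bins per organelle), and min–max normalized
   per cell; the per-bin SD block is scaled by the same factor and kept as
   a second feature block. Absent organelles therefore read ≈ 0.
8. **Cell classification.** A two-class linear discriminant over the 64
   profile features (means + SDs): class means, pooled covariance with
   ridge 1e-6·trace/d, decision by the sign of the linear score, posterior
   by its logistic transform. Linear discriminants are deterministic,
   stable at small n, and serialize to flat JSON. Dark cells bypass the
   model. Training data come from the simulator (the expert-labelled
   reference database this emulates is not distributable); non-dark cells
   only, since dark cells never reach the model at prediction time.
9. **Image call.** fraction_positive = positives / classified; positive
   when it reaches the cutoff (default 0.5, ties positive). Confidence is
   a logistic transform of |fraction − cutoff| scaled by the binomial
   standard error at the classified-cell count.
10. **Titer.** The median kinetoplast brightness of positive cells — the
    un-normalized, background-subtracted green mean over axis fractions
    0.15–0.35 — is mapped through monotone breakpoints onto the titer
    steps ["1:10", "1:32", "1:100", "1:320", "1:1000"]. Median rather
    than mean: robust to the occasional misclassified bright nucleus.
    Dilutions of one sample merge to: positive iff any dilution positive;
    final titer = max(per-image estimates, level implied by the highest
    positive dilution); confidence = min over contributing images.

## Synthetic data

The simulator draws elongated cells as convex teardrops (an ellipse
clipped at the posterior end: pointed at the basal/anterior end, widest
near the nucleus), placed without overlap by rejection sampling (≤ 100
attempts per cell; unplaceable cells are counted, never silently dropped).
Organelles are isotropic Gaussian spots on the axis at fractions 0.10
(basal body, σ 1.5 px), 0.25 (kinetoplast, σ 2.6 px), 0.60 (nucleus,
σ 4 px) of the rasterized body extent — the biology fixes only the order,
these defaults keep the organelles separable at 32 profile bins. Nucleus
and basal body fluoresce independently (default probability 0.5 each),
generating all six diagnostic archetypes. Rendering: red body intensity
~N(0.45, 0.05) on background 0.05; optional defocus blur; Gaussian read
noise (σ 0.01) added after blur; clip to [0, 1]. Shot noise is omitted by
default for test determinism. Identical configs (including seed) yield
bit-identical images.

Default frame 612×512 px with 30 cells — one quarter of the full
2448×2048 acquisition at the same cell density; full scale is supported,
and property tests use 306×256 frames with 10–12 cells to keep the suite
fast. Default kinetoplast amplitude is 0.8 (SD 0.12): calibrated once so
that a lone kinetoplast keeps even the largest cells clearly above the
whole-cell darkness threshold; nucleus 0.55, basal body 0.45.

A dilution series re-renders one fixed scene with all green amplitudes
scaled by 1/factor. Ground-truth titer level is the last dilution whose
mean kinetoplast amplitude reaches the positivity threshold θ = 0.32 —
the amplitude at which a default-geometry cell's mean green rises 3 SD
above background, i.e. the detection limit of the dark-cell rule.

**What the simulator does not emulate:** realistic PSFs and chromatic
aberration, flagella, cell-cycle morphology, autofluorescence gradients,
partially stained or overlapping clumped cells, and the full variability
of patient sera. Passing property tests therefore demonstrate internal
consistency of the pipeline under a controlled model, not clinical
performance on real slides.

## Calibration constants

* Brightness-to-titer breakpoints: one titer step corresponds to a √10
  brightness factor. The kinetoplast-band brightness of a cell with spot
  amplitude A measures ≈ 0.45·A on the default geometry (slope fitted
  once on simulator cells), so the breakpoints are anchored at
  0.45·θ ≈ 0.144 and spaced by √10: [0.144, 0.454, 1.437, 4.543, 14.367].
  Brightness saturates near 1, so high titers are reached through the
  highest-positive-dilution route of the merge rather than through
  brightness alone.
* Known bias: at the first dilution past the true endpoint the kinetoplast
  (≈ θ/1.8) is below the whole-cell darkness threshold for cells without
  other fluorescent organelles, but cells with a fluorescent nucleus stay
  above it and the scale-invariant profile still shows a faint kinetoplast
  band, so that image is frequently called positive. The merged titer then
  lands one step high — within the ±1-step reproducibility window that
  immunofluorescence titration is read to.

## Numerical conventions

0-based (row, col) coordinates, origin top-left; intensities normalized by
dtype max (never per-image min/max, which would destroy cross-dilution
brightness comparisons); all boundary comparisons resolve upward (fraction
at cutoff → positive, brightness at breakpoint → higher step); constant
cells yield all-zero profiles; undefined agreement ratios report as
not-available, never 0 or 1; percentages round half-up to one decimal.
All stochastic steps take explicit seeds; classification itself is
deterministic.

## Problem sizes used by the checks

The acceptance script re-derives every quantity at run time: the cohort
statistics from the printed 669-sample confusion counts; segmentation
agreement on 20 full-density 612×512 frames; classifier accuracy on a
2,000-cell balanced table (80/20 split); the short-circuit count on 10
all-dark slides; titer recovery on 100 five-dilution series (12 cells per
306×256 frame, true levels cycling over all five steps).

## Known limitations

* The discriminant is trained on simulator data; applying it to real
  micrographs requires retraining on an expert-labelled cell table (the
  per-cell CSV written by the pipeline doubles as the training format).
* Bright basal bodies are the hardest negative archetype — the simulator
  generates it specifically so regressions in that failure mode are
  caught — but the default geometry keeps basal body and kinetoplast
  separable; poorly resolved real images may not.
* Touching cells are excluded, not split; heavily clumped fields lose
  evaluable cells and may be rejected for lack of them.
* Registration is integer-pixel and translation-only.
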