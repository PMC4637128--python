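# clift

Automated evaluation of *Crithidia luciliae* indirect immunofluorescence
tests (CLIFT) for anti-dsDNA antibodies — a confirmatory assay in the
diagnosis of systemic lupus erythematosus (SLE).

A CLIFT biochip is photographed in two channels: green carries the
FITC-labelled, antibody-specific signal; red carries the Evans blue
counterstain that shows every cell regardless of antibody status. A sample
is anti-dsDNA **positive** exactly when the cells' kinetoplasts — dense
networks of mitochondrial dsDNA — fluoresce in green; fluorescent nuclei
or basal bodies alone do not count. Manual read-out of this pattern is
subjective; `clift` implements the automated chain:

```
register channels → focus & artefact QC (red) → segment cells (red)
→ per-cell shape QC → dark-cell threshold rule → axis profile (green)
→ linear-discriminant cell call → image verdict + titer → dilution merge
```

Per cell, the green intensity is projected onto the cell's main axis into
a discrete normalized signal *p*₁…*p*₃₂ (with per-bin SDs as a second
feature block). Because the organelles sit in fixed order along the axis —
basal body, kinetoplast, nucleus — this signal encodes which organelles
fluoresce. A two-class linear discriminant (class means μ₀, μ₁, pooled
ridge-regularized covariance Σ, decision wᵀx + b with w = Σ⁻¹(μ₁−μ₀))
calls each cell by its kinetoplast status. An image is positive when the
positive-cell fraction reaches a configurable cutoff (default 0.5); the
median kinetoplast brightness of positive cells maps through monotone
breakpoints onto titer steps (1:10 … 1:1000), and dilutions of one sample
merge into a final verdict and titer.

The package also ships a ground-truthed synthetic image simulator (every
downstream stage is testable without real slides) and an evaluation module
for software-vs-visual agreement statistics.

## Worked example

Train a classifier on simulator-labelled cells, simulate a 10-biochip
slide, and classify it:

```sh
clift train --out model --n-cells 600 --seed 1
# trained on 600 cells, training accuracy 1.000 -> model/classifier.json

clift simulate --out slide --seed 3 --n-images 10
clift classify --input slide --model model/classifier.json --out results
# 10 images classified (0 rejected by QC)
```

`results/results_images.csv` (the slide was simulated with each cell
positive at probability 0.5, so verdicts sit near the cutoff):

```
sample_id,biochip_id,dilution_factor,verdict,n_cells_total,n_cells_classified,fraction_positive,titer_estimate,confidence,reject_reason
S00,B00,1.0,positive,30,30,0.5,1:10,0.5,
S01,B01,1.0,negative,30,30,0.433333,negative,0.67487,
S02,B02,1.0,positive,30,30,0.566667,1:10,0.67487,
...
```

Each row is one biochip: 30 cells found, the fraction called positive, the
verdict by the ≥ 0.5 cutoff (a fraction of exactly 0.5 is positive), the
titer proposal from the kinetoplast brightness of the positive cells, and
a confidence that grows with the distance of the fraction from the cutoff.
`results_samples.csv` carries the dilution-merged verdict per sample.

Agreement statistics against expert visual calls:

```sh
clift evaluate --calls calls.csv --out summary.json
```

where `calls.csv` has `software_verdict`/`reference_verdict` (and
optionally titer level) columns; the output reports TP/FP/FN/TN,
sensitivity, specificity and accuracy to one decimal.

## Library use

```python
from clift import RunConfig, load_channel_pair, analyze_pair, TrainedClassifier

cfg = RunConfig()
model = TrainedClassifier.load("model/classifier.json")
pair = load_channel_pair("S01_B01_1_green.tif", "S01_B01_1_red.tif")
analysis = analyze_pair(pair, cfg, model)
print(analysis.image_call.verdict, analysis.image_call.titer_estimate)
```

Every threshold (cutoff, titer steps, brightness breakpoints, QC limits,
focus threshold…) lives in `RunConfig`, loadable from YAML/JSON.
See `docs/methods.md` for the model, its assumptions, the simulator's
scope and all numerical conventions.

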