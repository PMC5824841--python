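# elasto-bcp

Semi-quantitative analysis of endobronchial-ultrasound (EBUS) strain
elastograms of mediastinal and hilar lymph nodes. Strain elastography
overlays a color map on the B-mode image in which **blue encodes hard
tissue**, green intermediate, and yellow/red soft tissue. Because metastatic
nodes tend to be stiffer than benign ones, the **blue color proportion
(BCP)** — the number of blue pixels inside the node region divided by the
total node pixel count —

```
BCP = N_blue / N_ROI
```

is a reproducible malignancy score that replaces subjective "predominantly
blue / partly blue" pattern reading. The package is aimed at
bronchoscopists and imaging researchers who want to quantify elastogram
color distributions and evaluate BCP (or any per-node score) as a
diagnostic test.

It provides three stages behind one library and CLI:

1. **Image stage** — seeded region growing (a reproducible magic-wand
   analogue: 8-connected pixels within a Euclidean RGB tolerance of the
   seed color) to delimit a node, HSV blue-band classification (default hue
   190°–270°, saturation and value ≥ 0.15), and the BCP ratio; multiple
   images of one node are averaged.
2. **Diagnostics** — empirical ROC curve of BCP for malignancy, trapezoidal
   AUC (equal to the Mann–Whitney concordance with ties counted ½),
   stratified bootstrap 95% CI, the Youden-optimal cutoff
   (max sensitivity + specificity − 1, ties broken toward the lowest
   threshold), confusion metrics at a cutoff (malignant iff BCP strictly
   above it), benchmarking of conventional B-mode/PET features, and a
   two-sided Welch comparison of the group BCP distributions.
3. **Synthetic data** — an elastogram renderer with pixel-exact ground-truth
   blue fraction and ROI, and a cohort simulator that draws BCP from
   moment-matched truncated normal group distributions (defaults: malignant
   mean 57.1%, SD 14.4; benign mean 31.1%, SD 17.3; 39 vs 40 nodes) with
   conventional features drawn from per-feature sensitivity/specificity
   models, so the whole pipeline is testable without patient data.

## Worked example

Render a synthetic node whose true blue fraction is 55%, measure it, then
simulate and analyze a 79-node cohort:

```bash
$ elasto-bcp simulate-image --out node.png --mask-out node_mask.png \
      --blue-fraction 0.55 --seed 7
wrote node.png (true blue fraction 0.5500)

$ elasto-bcp image --image node.png --mask node_mask.png
image_id,node_id,blue_pixels,total_pixels,bcp_percent
node,,7353,13369,55.0

$ elasto-bcp simulate-cohort --out cohort.csv --seed 11
wrote 79 records to cohort.csv

$ elasto-bcp analyze --cohort cohort.csv --bootstrap 2000 --seed 1 --out report.json
AUC 0.905 (95% CI 0.834-0.958), cutoff 50.6%
```

The image stage recovered the rendered ground truth exactly (7353 of 13369
ROI pixels, BCP 55.0%). For this particular simulated cohort the BCP
discriminates malignant from benign nodes with AUC 0.905 (a single 79-node
draw scatters around the generator's theoretical concordance of 0.876 with
SD ≈ 0.04); the Youden cutoff lands at 50.6% BCP, and `report.json` holds
the full confusion table, sensitivity/specificity/accuracy/PPV/NPV, the
conventional-feature benchmark and the Welch group comparison. Use
`--cutoff` to evaluate a pre-specified threshold instead, and
`elasto-bcp batch --manifest manifest.csv` to process many image/mask pairs
into a per-node BCP table.

A note on one reference value: at the published 36.7% cutoff the printed
two-row classification counts (26 of 40 benign below the cutoff, 14 above)
imply a specificity of 65.0%; the accompanying text prints 67.5%, which
would require 27 benign nodes below the cutoff. The package reproduces the
count-derived 65.0%.

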