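# benthofind

Weakly-supervised detection of megabenthic fauna in seafloor photographs.

Towed-camera platforms photograph the deep seabed at 0.1 Hz for hours,
producing tens of thousands of images in which visible megafauna (ophiuroids,
sponges, xenophyophores, anemones, ...) are rare — typically well below one
individual per square metre on abyssal nodule fields. Manually screening such
surveys to build training annotations for an object detector is the
bottleneck of image-based benthic ecology. `benthofind` automates the
annotation step: it proposes *weak* bounding-box annotations fully
unsupervised, leaving a human (or, on synthetic data, an emulated expert)
only the tasks of filtering and labeling them.

The workflow:

1. **Superpixels** — each image is over-segmented with graph-based
   (Felzenszwalb–Huttenlocher) segmentation after Gaussian smoothing. On a
   quasi-homogeneous sediment background the seafloor collapses into one
   dominant segment; organisms, nodules and distractors become small
   segments, each cropped to a square patch.
2. **VAE features** — a small convolutional-free variational autoencoder
   (numpy, CPU) maps each patch to the posterior mean **μ** of a
   100-dimensional diagonal-Gaussian latent, trained with per-pixel MSE plus
   the KL regularizer ½·Σ(μ² + σ² − 1 − log σ²).
3. **Isolation forest** (implemented from scratch) — anomaly score
   s(x) = 2^(−E[h(x)]/c(ψ)) with c(n) = 2H(n−1) − 2(n−1)/n. A deliberately
   high contamination (0.4) flags subtle, camouflaged organisms too.
4. **Weak annotations** — flagged superpixel boxes are filtered either by a
   75th-percentile score threshold or (preferred) a small binary patch
   classifier that removes false positives such as laser points and dark
   water-column patches; survivors are labeled with one of ten morphotype
   classes and split 90/10 by scene for detector training.
5. **Evaluation** — detector-agnostic COCO-style metrics (IoU, greedy NMS,
   101-point AP at IoU 0.50 and 0.50:0.95, size-stratified AP/AR, AR_1/10/100,
   confusion matrix with background row/column) plus a configurable noisy
   oracle detector standing in for a trained Faster R-CNN.
6. **Ecology** — detections are georeferenced by acquisition time against the
   navigation track, converted to abundance (ind·m⁻², footprint
   4a²·tan(fov_x/2)·tan(fov_y/2) from altitude *a* and a 64°×64° field of
   view), exponential Shannon diversity exp(−Σ pᵢ ln pᵢ), and 200-m gridded
   density maps.

Everything is exercised end-to-end on a built-in synthetic benthic-survey
generator (sediment background, Mn-nodule speckle, rare parametric fauna,
red laser-point distractors, timestamped camera track), so the full pipeline
runs on a laptop CPU in about a minute.

## Worked example

```sh
benthofind init-config demo.yaml   # then set survey.n_images: 40, seed: 7
benthofind run all -c demo.yaml --workdir demo_run
```

runs the ten pipeline stages on a 40-image synthetic survey and logs:

```
benthofind INFO simulate: wrote 40 scenes
benthofind INFO segment: 2215 patches from 40 scenes (40 sampled for training)
benthofind INFO train-vae: 2215 patches, final loss 0.00853
benthofind INFO features: (2215, 100) matrix
benthofind INFO train-iforest: fitted on 2215 rows (psi=256)
benthofind INFO score: 2215 scored, 886 flagged
benthofind INFO filter(classifier): 141 weak annotations from 886 flagged patches
benthofind INFO annotate: 139 labeled annotations
benthofind INFO evaluate: AP50=100.0% over 69 detections
benthofind INFO ecology: 0.1681 ind/m2, effective diversity 4.64
```

Reading the run: ~2.2k superpixels were scored, the top 40% (contamination)
flagged, and the patch classifier kept 141 as weak annotations — of which
139 overlap a planted organism (an organism often spans several superpixels)
and receive its morphotype label. The zero-noise oracle detector then
reproduces the 69 planted fauna exactly (AP@0.50 = 100%), and the ecology
stage estimates 0.168 individuals·m⁻² — the survey planted fauna at Poisson
mean 2 per image over a ~10 m² mean footprint — with an effective diversity
of 4.6 equally-common morphotypes out of the 6 rendered.
Outputs land in `demo_run/`: `weak_annotations.csv`, `annotations*.csv`,
`annotations.json` (COCO), `eval_summary.json`, `confusion_matrix.csv`,
`ecology.json`, `grid_density.csv`, plus per-stage run manifests with config
hash and output checksums.

The same stages are available as a library (`benthofind.run_stage`, or the
individual functions in `benthofind.superpixels`, `.vae`, `.iforest`,
`.weak_annotations`, `.detection_eval`, `.ecology`).

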