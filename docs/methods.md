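# Methods

## Problem and model

`aplsmear` screens for acute promyelocytic leukemia (APL), the
t(15;17)/PML-RARA-defined subtype of acute myeloid leukemia, from
peripheral-smear single-cell images of the kind exported by automated
slide analyzers. Labels (APL vs non-APL) attach to *patients*, not to
cells, which motivates the two classifiers the package implements:

* **Single-cell classifier.** A convolutional network maps one RGB cell
  image to a softmax over three classes {non-APL, APL, blurred}. The
  patient score is the post-hoc mean of the per-cell binary scores.
* **MIL sample classifier.** The same backbone is applied to every cell
  in a patient's bag; the softmax assignments are averaged *inside* the
  network and the bag-level cross-entropy trains the weights
  (multiple-instance learning with mean aggregation). By construction
  the bag probability equals the arithmetic mean of the per-cell
  assignments — this identity is asserted end to end in the tests.

The backbone is four valid-padding convolutions (3×3 kernels, stride 2,
ReLU), a global max pool over the remaining spatial grid, three fully
connected ReLU layers (32/22/11 units) and the 3-way softmax. The global
max pool makes the network input-size agnostic and translation invariant
*modulo the stride lattice*: translations by multiples of the cumulative
stride (16 px) away from borders leave the output exactly unchanged,
while sub-stride shifts re-sample the feature grid and perturb the
output mildly. The FC sizes were chosen so that the concatenated
activations of the last four layers (32+22+11+3) span a 68-dimensional
latent space per model.

The network, its backpropagation, the Adam optimizer and the input
gradients needed for attribution are implemented directly in numpy
(`aplsmear.nn`); the surrounding pipeline uses scipy, scikit-learn,
umap-learn and pillow for the standard steps.

### Binary score

The blurred class is a training device, not a diagnosis. All reported
APL probabilities renormalize over the two real classes:
`p = P(APL) / (P(APL) + P(non-APL))`, with a warning and `p = 0.5` in
the degenerate all-blurred case.

## Blurred outgroup (batch-effect control)

Wright-stain color drifts with slide age, and collection date can be
strongly correlated with diagnosis (an era containing only APL
patients). To discourage the model from reading stain color, a third
training class is built per split: a Gaussian-blurred copy of *every*
training image (outgroup size = training-set size). Blur destroys
cellular morphology but preserves global color statistics, so color
alone cannot separate APL from blurred and the model is pushed toward
morphology. The outgroup is rebuilt from training images only in every
Monte-Carlo repetition; held-out images never contribute members.

Blur sigma defaults to 11 px at the 360-px input (scaled linearly at
other sizes), truncated at 4σ — strong enough to remove morphology at
the scale of nuclear structure while leaving stain statistics intact.
Blur is applied after resizing.

**Limitation observed on the synthetic null.** When the *only*
class-correlated signal is the color shift (no morphology effect at
all), any model that fits the confounded training data must use color;
the outgroup then attenuates, but cannot eliminate, era-driven ranking.
The deconfounding experiment therefore measures a *contrast*: the
outgroup model's AUC on an era-balanced cohort sits closer to chance
than the no-outgroup control's, but not at 0.5. With a genuine
morphological signal present the outgroup simply biases learning toward
it, which is the intended real-data regime.

## Monte-Carlo cross-validation and ensembling

Each repetition partitions the *patients* (never cells) at random,
stratified by class: 75% train and, for the cell classifier, the
held-out 25% split in half into validation (early stopping, patience 5
on held-out loss) and test; the MIL classifier uses 75/25 train/test and
stops when the epoch training loss reaches a threshold (default 0.2,
300-epoch cap), since with few bags a held-out validation loss is too
noisy to monitor. MIL training subsamples 25 random cells per bag per
epoch (all cells for smaller bags). Per-cell and per-sample predictions
are pooled across repetitions strictly out-of-fold; after `n_reps`
repetitions (default 100) the trained models form an ensemble that
scores independent cohorts by unweighted score averaging.

Optimization uses Adam at learning rate 1e-3 (the standard Adam
default; it converges within the benchmark epoch budgets where 1e-4
does not), batch 32 for the cell classifier and one bag per step for
MIL. Training is float32; softmax probabilities are emitted in float64
so bag averages are numerically exact at the 1e-6 identity tolerance.

Evaluation is ROC AUC (scikit-learn, ties at ½), always on the
renormalized binary score, never including the blurred class. The
promyelocyte fraction of each bag — the classical morphological
biomarker of APL — is reported as the baseline comparator, and sample
AUC is additionally stratified by per-patient cell-count quartiles
(observational; no monotonicity is asserted).

## Interpretability

**Integrated gradients.** Attribution of ΔP = P(APL) − P(non-APL) for
one image integrates the input gradient along a straight path from a
blurred baseline (same sigma as the outgroup, so the baseline is
stain-preserving but morphology-free) to the image, in 100 left-Riemann
steps, multiplied by (image − baseline) and summed over channels. The
completeness identity (attributions sum to ΔP(image) − ΔP(baseline))
holds with error O(1/steps); tests check the error shrinks as steps
double and that the linear-model closed form is exact. Consensus maps
average 25 members drawn uniformly without replacement under a seed.

**Latent embedding.** Per cell and per MIL-ensemble member, the last
four layers' activations (post-ReLU FC, post-softmax head) are
concatenated (68 dims/model; 6800 across 100 members). Features are
standardized per dimension (the blocks have heterogeneous scales), PCA
keeps the minimal number of components reaching ≥99% explained
variance, UMAP (15 neighbors, min_dist 0.1, fixed seed) embeds to 2-D,
and per-class Gaussian KDE grids (scipy `gaussian_kde`) summarize class
geography. Seeded embeddings are bit-reproducible.

## Synthetic cohort generator

The generator emulates the structure of a smear cohort with three
plantable signals, each controllable and each off by default unless
stated:

* **Morphology (the planted class effect).** Immature myeloid cells
  (blast, promonocyte, promyelocyte, myelocyte, metamyelocyte) are
  rendered from per-class regimes that differ only in chromatin
  centrality (APL 0.85 — condensed, central; non-APL 0.15 — dispersed,
  rim-focused) and granule density (16 vs 3 per 1000 px²); colors are
  identical across classes so the signal is purely morphological.
  Mature cell types use one neutral regime for both classes.
* **Cell-type mixtures.** APL patients draw 40% promyelocytes; non-APL
  patients 5%, with more monocytoid cells — so the promyelocyte-fraction
  baseline is informative by design.
* **Stain-era batch effect.** An additive RGB shift (+22, −10, −18)
  tied to a collection era; an APL patient lands in the confounded era
  with probability `class_correlation` (non-APL patients with a
  separate, default-zero probability), so 1/0 reproduces a perfect
  class/era confound and 0.5/0.5 an era independent of class.

Cells per patient default to 200 (valid range 100–400, the analyzer's
configurable limit). Renderer: background field, cytoplasm disc,
elliptical nucleus (lobed for neutrophils) with a radial chromatin
density gradient parameterized by a single centrality scalar, Poisson
granules, Gaussian pixel noise, then the era color shift — the smallest
model that makes chromatin centrality one controllable number. With
noise and granules both zero the render is a deterministic function of
geometry (seed-independent). An identical config yields a byte-identical
dataset.

What the generator does *not* emulate: real Wright-stain texture,
focus/illumination variation, segmentation artifacts, inter-patient
morphological heterogeneity beyond rendering jitter, red-cell
background. Passing the synthetic benchmarks therefore demonstrates
that the pipeline's machinery (splitting, training, aggregation,
deconfounding pressure, attribution, embedding) behaves correctly, not
that the real-data accuracies are reproduced; the real cohorts are a
separate, optional workflow (see README).

## Reference problem sizes

The benchmark experiments (`aplsmear.experiments`) run on one CPU:

* planted-signal recovery: 10+10 patients × 100 cells, 64-px images,
  5 Monte-Carlo repetitions, reduced conv widths (8/12/16/16) with the
  full 68-dim head;
* deconfounding contrast: 8+8 confounded training patients, 10+10
  era-balanced evaluation patients, 5 seeds, with/without outgroup;
* structural checks: a complete 100-repetition MIL run at 8 patients ×
  10 cells, 32-px images, 2-epoch cap.

All experiment entry points force single-threaded BLAS
(threadpoolctl), so results are reproducible regardless of host core
count. Seeds derive from a single integer everywhere.

## Numerical choices and edge cases

* Resize: half-pixel-center bilinear interpolation
  (`scipy.ndimage.map_coordinates`, order 1), intensities scaled to
  [0, 1]; idempotent on already-preprocessed input.
* Global max pool backward distributes gradient equally over tied
  maxima; ties occur only on degenerate (constant) inputs.
* AUC with a single class present raises rather than returning NaN;
  per-bin AUCs in the cell-count stratification are NaN when a bin is
  single-class.
* Empty bags, empty manifests, conflicting patient labels, unknown
  cell-type strings (mapped to "unidentified" with a warning) and
  missing image files are rejected or flagged as described in the API
  docstrings.

## Known limitations

* The numpy network is small-scale by design; it is not a route to the
  full-size real-data training runs.
* Sub-stride translation sensitivity (above) is inherent to strided
  valid convolution without anti-aliasing.
* The deconfounding contrast on a pure-color null is an attenuation,
  not an elimination (above).
* UMAP coordinates are only meaningful jointly with the seed; across
  library versions layouts may differ while the PCA contract still
  holds.
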