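# Methods

## Problem and model

The package classifies single-channel 8-bit images of mammographic-style
masses into three classes — benign, malignant, and *ignorant* (normal
tissue / no committed diagnosis) — by fusing two independent probability
sources at the decision level:

1. an **MLP** over gray-level co-occurrence (GLCM) texture statistics, and
2. a **CNN** over the (preprocessed) images themselves,

combined per sample with **Dempster's rule**.  The premise is that the two
classifiers see different views of the data (hand-crafted texture vs.
learned spatial features), so their error mechanisms are partly
independent; pooling their evidence then cancels part of each source's
mistakes, while the conflict coefficient `k` exposes samples on which the
sources disagree.

### Frames of discernment

The status of the third class is genuinely ambiguous in evidential terms,
so both readings are implemented behind one `Frame` switch:

- **`disjoint_singleton`** (default): ignorance is a third pairwise-disjoint
  hypothesis.  The unnormalized combination is the elementwise product of
  the two mass triples, and `k` is the sum of all nine cross products minus
  the diagonal.  This makes the rule associative and treats "normal" as a
  diagnosis in its own right.
- **`classical_ds`**: ignorance is the vacuous element `Θ = {benign,
  malignant}`.  Only benign×malignant products conflict; a source with all
  mass on `Θ` is the identity of the rule.  This is the textbook
  Dempster–Shafer reading and gives the ignorance mass its usual
  "uncommitted belief" semantics.

Classifier triples are mapped to masses by identity (renormalizing drift);
no discounting is applied.  At total conflict (`k = 1`, possible only with
degenerate 0/1 triples) the rule is undefined; the pipeline then falls back
to the single source with the higher committed mass and flags the sample.
Argmax ties are broken by the fixed order benign < malignant < ignorance
and recorded on the result.

## Synthetic phantoms

The generator emulates the two margin phenotypes that drive visual mass
assessment, on a textured background:

| parameter | default | meaning |
|---|---|---|
| `image_size` | 128 px | square image side |
| `mass_radius` | 14 px | disc radius (jittered ±15% per image) |
| `spicule_count` | 8 | radial needles, malignant only |
| `background_texture_scale` | 8 px | correlation length of smoothed uniform noise |
| `noise_gaussian_sigma` | 4 intensity units | additive sensor noise |
| `noise_salt_pepper_frac` | 0.01 | impulse-noise pixel fraction |

Benign masses are discs blurred with `sigma = radius/4` (smooth margins);
malignant masses are sharp discs plus `spicule_count` radial segments
reaching `1.5·radius` (needle-like margins); ignorant phantoms are
background only.  Mass position is jittered around the center so a dataset
is not a set of translated copies.  Noise is applied last, Gaussian before
impulses.  A mean-Sobel-magnitude statistic ranks malignant above benign on
essentially all matched seed pairs, and GLCM contrast separates the classes
— the two facts the classifiers rely on.

What the phantoms do **not** model: anatomy (pectoral muscle, parenchymal
patterns, calcifications), film artifacts, burned-in text, scanner MTF, or
class-conditional intensity distributions of real mammograms.  Passing
tests therefore demonstrate the *pipeline's* correctness and the fusion
mechanism's behavior, not clinical performance.

### Simulated probability sources

`simulate_source_pair` emulates two trained classifiers' outputs directly:
per sample, source *i* errs with probability `1 − accuracy_i`, error
events are coupled through a shared uniform variate (`error_correlation`
interpolates between independent and comonotone mistakes), and an erroneous
prediction picks one of the two wrong classes uniformly.  The probability
triple is a Dirichlet draw concentrated on the predicted class
(`confidence_concentration`, default 16), with the largest component
swapped into the predicted slot so the argmax always equals the simulated
prediction.  Erroneous predictions use a quarter of the concentration:
real classifier posteriors are systematically less peaked on mistakes, and
this graded confidence is what lets any combination rule favor the correct
source when the two disagree — with equally confident right and wrong
triples, conflicting sources tie and no fusion gain is possible.

## Preprocessing

- **Median filter**: odd window (default 3×3), replicate borders, so edges
  are preserved and no dark rim is introduced.
- **Histogram equalization**: transfer function
  `f(x) = x0 + (x_{L−1} − x0)·c(x)` with `c` the cumulative histogram
  fraction and `[x0, x_{L−1}] = [0, L−1]`; output rounded half-up and
  clipped.  The transfer function is monotone by construction.
- **ROI extraction**: Otsu binarization (overridable threshold), erosion by
  a flat diamond of city-block radius 3, largest 8-connected component,
  background zeroed.  Off by default for phantoms (a normal phantom has no
  bright foreground to isolate); intended for full-field images.

## Texture features

GLCMs are counted directly at distance 1 (configurable) for the four
standard angles in the classic texture-analysis convention (0° pairs
right, 45° up-right, 90° up, 135° up-left), after uniform quantization to
16 gray levels; matrices are symmetrized and normalized.  Twenty-one
Haralick-style scalars are computed per matrix (0-based level indices,
`0·log 0 = 0`, natural logs) and averaged over angles by default
(`concat` is available).  Degenerate GLCMs (constant image) define
correlation as 1 and the information measures as 0 rather than NaN.
Sixteen levels keep toy matrices dense while preserving class contrast;
features from difference moments and centered moments are invariant to a
constant intensity shift at fixed quantization.

## Classifiers

**MLP** — two hidden layers of 10 sigmoid units, sigmoid output,
full-batch gradient descent with momentum 0.9 on an MSE loss against
one-hot targets, features standardized internally.  The input width follows
the feature table rather than being fixed.  Sigmoid outputs are
renormalized to a probability triple.  Default 300 epochs at learning rate
0.5: on the reference cohort the fully-converged network overfits (train
1.0, test ≈0.83) while 300 epochs match a regularized linear baseline
(≈0.92); the backward pass is verified against central finite differences
at 1e-4 relative error.

**CNN** — four blocks of convolution (stride 1, 'same' padding) → batch
normalization → ReLU → 2×2 stride-2 pooling, with filter counts
(16, 32, 32, 64); max pooling in blocks 1–3 and average pooling in block 4;
then FC(100) → ReLU → FC(3) → softmax, trained with cross-entropy by
mini-batch SGD with momentum.  The class default keeps the reference
geometry (kernels 28/14/7/4 at 128 px input); the pipeline's desk default
resizes inputs to 32 px with kernels (7, 5, 3, 3), which trains orders of
magnitude faster in pure numpy at the cost of fine spicule detail — chosen
so a full cross-validated run finishes in minutes on one CPU.  Grayscale
input is replicated to three channels.  Training batches are augmented
with random flips and 90° rotations by default: the phantom phenotypes are
rotation-invariant, and with ~120 training images augmentation is the
difference between a memorizing and a generalizing network.  All
randomness (init, shuffling, augmentation) flows from the config seed;
training is bit-reproducible.

Hyperparameters the underlying design leaves open (learning rate, epochs,
batch size) are explicit config fields with the documented defaults above
rather than hidden constants.

## Evaluation

Stratified 5-fold cross-validation (deterministic given the seed); each
sample is predicted once by models trained on the other folds, and one
pooled confusion matrix per method is reported.  Sensitivity and
specificity are one-vs-rest over the benign+malignant subpopulation
(normal/ignorant samples excluded from those two ratios, mirroring a
benign-vs-malignant diagnostic readout); overall accuracy is the 3-class
rate.  Ratios with zero denominators are reported as undefined, never 0.
ROC curves keep every threshold point; the fused method's score is the
combined mass of the positive class — a documented convention, since a
hard-decision fusion has no canonical score.

## Numerical choices

- Mass functions validated to sum to 1 within 1e-9; combination
  renormalizes exactly, and the implementation matches a set-based
  brute-force enumerator to 1e-12 on random pairs.
- Round-half-up for equalization outputs; quantization by
  `value · levels // L`.
- Max-pool backward splits gradient equally among tied maxima
  (deterministic); batch norm uses eps 1e-5 and running-stat momentum 0.9.
- Per-stage and per-fold seeds are spawned from the master seed via
  `SeedSequence`, so every artifact is a pure function of config + seed.

## Known limitations

- Phantom realism is deliberately minimal (see above); absolute accuracies
  on phantoms say nothing about mammogram databases.
- The desk-scale CNN underperforms the texture MLP on phantoms; the fused
  accuracy exceeding both is the behavior of interest, not the CNN's own
  score.
- The identity mapping from softmax/sigmoid outputs to masses ignores
  calibration; discounting or temperature scaling would change conflict
  statistics.
- `combine_many` folds pairwise; in the disjoint frame this is associative,
  but mixing frames across a fold is not supported.
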