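# Methods

This note documents the models, the numerical choices and the limits of what
the synthetic experiments can show. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic dermoscopy generator

`lesionforge.synthetic` renders images that reproduce the *statistical
regime* of dermoscopic lesion photographs rather than their appearance: a
lighter textured skin background (smooth Gaussian-filtered texture, a gentle
illumination gradient, mild per-pixel noise) with a darker, roughly
elliptical lesion whose border is perturbed by a few low-frequency radial
Fourier modes. The lesion's pixel fraction is controlled by an area
correction loop and lands within ±10% (relative) of the requested value for
fractions in `[0.05, 0.5]`; the default fraction is 0.20, the imbalance
regime in which pixel accuracy saturates at 80% for an all-background
predictor and Jaccard becomes the informative score.

Artifacts are layered in a fixed order — lesion compositing, then hair
strokes (cubic Bézier curves, 1–3 px wide, intensity ≤ 60, never recorded in
the mask), then impulse ("salt and pepper") and multiplicative speckle noise
— and each layer draws from an independent child stream of the image seed.
Consequently two specs differing only in `hair_count` are *pixel-identical
twins* outside the hairs, which is what makes the hair-removal claim
testable: the restored image can be compared against ground truth that never
existed in the corrupted one.

What the generator does **not** emulate: real lesion chromatics and
dermoscopic structures (networks, globules), camera vignetting and color
calibration, ruler/gel artifacts, and hair that varies in translucency.
Passing tests therefore demonstrate the algorithms' contracts (restoration,
routing, convergence), not clinical performance.

## Preprocessing stack

Default order: resize (bilinear; nearest-neighbour for masks) → color
conversion → hair removal → adaptive median → adaptive local filter → CLAHE.

* **Target size** defaults to 128×128 (64×64 in the desk-scale runs);
  all sizes are configurable.
* **CLAHE** runs on the HSV value channel only, with an OpenCV-style clip
  limit (default 2.0, mapped to scikit-image's fractional 0.02). Adaptive
  equalisation re-stretches tile histograms on every application and is
  inherently non-idempotent (measured: a second pass moves intensities by
  ~10 mean levels); the rest of the stack is idempotent to within ±3 levels,
  and that is the property the suite asserts.
* **Adaptive median** implements the classical two-stage algorithm (grow the
  window from 3 up to `median_max_window` until the median is a strict
  interior value; replace the pixel only if it sits at a window extreme),
  with one refinement: the pixel must also deviate from the window median by
  more than `median_impulse_tolerance` (default 16 levels). Without the
  guard, ordinary texture extrema — present in every natural image — are
  rewritten; with it, an impulse-free image passes through bit-identical
  while ≥ 99% of 5% salt-and-pepper pixels are restored to within ±10 levels
  of their clean values (measured across seeds).
* **Adaptive local filter**: `out = x − (σ²_noise/σ²_local)(x − μ_local)`
  with the ratio clipped to `[0, 1]`, window 7. `σ²_noise = None` ("auto")
  estimates the noise power as the median of local variances.
* **Hair removal** is DullRazor-style: maximum black-hat response over six
  oriented linear structuring elements (length `hair_kernel_length`, default
  9 px) thresholded at `hair_threshold` (default 40), followed by biharmonic
  inpainting. A plain black-hat detector also fires along lesion-border
  concavities (the closing bridges them exactly as it bridges hairs), so
  detections inside the *lesion body* — the large dark Otsu blob, opened to
  remove thin structures and dilated two pixels to cover its fringe — are
  suppressed. The deliberate trade-off is that hair segments crossing the
  lesion interior are left in place; on the paired-twin benchmark the
  operator strictly reduces MSE on every seed while changing no pixel of
  hair-free images.

## The segmenter and its encoding

The FCEDN maps `H×W×C` to an `H×W` lesion-probability map. Encoder:
conv+ReLU ×2, max-pool, conv+ReLU ×2, max-pool, dropout. Decoder: the
mirror with nearest-neighbour unpooling and stride-1 transposed
convolutions, a dropout, and a 1×1 sigmoid output head. Unpooling carries
no switch indices; it is plain repetition by the stored pool factor.

The 22-gene layout covers, in order: `cv1..cv4` (kernel count, kernel size),
`mp1, mp2` (pool size), `dl1` (drop rate) for the encoder and `un1, tcv1..
tcv4, un2` *(sic, mirrored)*, `dl2` for the decoder. Ranges: counts
`[20, 200]`, conv kernel sizes `[3, 5]`, drop rates `[0.2, 0.4]`. Pool-size
genes are bounded `[2, 4]`: two pooling stages must divide the input evenly,
and 64/128-px inputs are divisible only by products of {2, 4}; a 5×5 pool
would also discard most of the resolution that a lesion boundary needs.
Decoding repairs the unpool factors to mirror the pool factors in reverse
(constraint repair, in the same spirit as clipping); building a network
whose pool product does not divide the input raises a validation error, and
the architecture objective records such genomes as `-inf` fitness so the
search simply routes around them.

Training uses Adam (default 1e-3), batches of 8, and the loss `1 − J_ε`
per image with the same ε-smoothed Jaccard the search maximises (ε = 1.0;
a configurable constant — a randomly drawn smoothing value would make
fitness non-reproducible). All weight initialisation, shuffling and dropout
derive from explicit seeds; identical seeds give bit-identical histories.

Networks are implemented in `lesionforge.nn`, a compact numpy core: im2col
convolution assembled from k² contiguous block copies feeding batched GEMM
(the whole training loop is BLAS-bound), non-overlapping max pooling,
inverted dropout, batch normalisation and dense layers, with explicit
backward passes verified against numerical gradients in development.

## Sparrow search

Positions are clipped to bounds after every move and an elitist best-ever
record is maintained; the per-iteration trace of that record is monotone
non-decreasing by construction. Defaults: population 10, 10 iterations,
producer fraction 0.2, scout fraction 0.1, safety threshold 0.8 — each
fitness call trains a network, so the flock is kept small.

The three update rules, with the constants this package chose (the method
family fixes the roles, not the constants):

* **Producers** (top fraction by fitness): under a quiet alarm
  (`rand < safety_threshold`) the multiplicative contraction
  `x ← x·exp(−rank/(α·T))`, `α ~ U(0,1]`; otherwise a per-gene Gaussian
  step.
* **Scroungers** (the rest) follow the best-known position `x_p`:
  `x ← x_p + |x − x_p| ⊙ s / 2` with `s` random signs. Following the
  *elitist record* rather than the just-moved top producer prevents the
  whole flock from drifting with a producer that contracted away from the
  optimum, and the halving reflection contracts the flock's spread
  geometrically while probing both sides of the optimum. A flock sitting on
  a single point has zero displacement. The more common `1/k` scaling
  collapses the flock within ~3 iterations and stalls; measured on the
  planted-architecture benchmark it recovers 0/5 runs versus 4–5/5 for the
  halving rule.
* **Scouts** (a random fraction): birds worse than the best jump toward it
  with per-gene Gaussian factors over a *sparse* (~3-gene) probe whose scale
  never falls below 1% of the gene range (decaying to 0.1% late in the
  run), so refinement of one gene does not disturb already-correct ones;
  the best bird itself takes a fitness-scaled step away from the worst
  position.

Non-finite objective values are recorded as `−inf` and the run continues.
Fitness evaluations are cached by the rounded-and-clipped genome, so
re-visits of the same integer architecture cost nothing.

## Tree-CNN

Routing nodes are adaptive CNNs: conv(+batch-norm)+ReLU+pool blocks, flatten,
dropout, a dense layer and a softmax head (defaults: blocks (8,3),(16,3),
dense 32, input 32×32 — configurable through `GrowthPolicy`). Placement uses
a seeded `sample_fraction` (default 10%) of each new class's images; the
routing threshold is `2/(n_outputs + 1)` (configurable), a scale-aware bar
that is permissive for small nodes and demanding for wide ones. If two
children both clear the bar, the lower-mean-softmax child merges into the
higher (ties broken by seeded coin flip) and the new class joins the merged
node. Tree depth is capped at 2 by default (root + branch + leaf);
deeper growth is a config flag.

Each node keeps a `labels_transform` table (global class → local output
index), rebuilt after every structural change; composing tables along a
root-to-leaf path is invertible, and `validate_tree` asserts the leaf-class
bijection and table consistency after every grow. The root retrains at every
increment (it must route all classes); a branch node retrains only when a
class lands beneath it, warm-started by copy-and-branch when its output
count grew. Nodes off every new-class path are left bit-identical — the
property that makes the increment cheap.

The optional per-sample loss filter (drop training points whose current
cross-entropy exceeds a threshold before retraining) is off by default.

## Desk-scale problem sizes

The package's own experiments use: 60 synthetic 64×64 images split 80/10/10,
search population 5 for 3 iterations with 5 training epochs per fitness
evaluation (each candidate trains on a 16-image cap of the training split;
the final model trains on the full split for 8 epochs), and 30 images per
class at 32×32 for the classifier. At these sizes the full pipeline
completes in minutes on one CPU, the searched architecture reaches
validation Jaccard ≈ 0.97 against an all-background baseline of 0.0, and the
two-grow Tree-CNN script reaches held-out accuracy ≥ 0.85 on separable
classes.

## Known limitations

* Synthetic-only evidence: see the generator section; no claim transfers to
  ISIC/PH-2-scale data without GPU-scale training.
* The segmenter has no skip connections or batch norm by design, so very
  fine boundary detail saturates before a U-Net-style model would.
* CLAHE non-idempotency (above) means repeated pipeline application keeps
  shifting intensities; run the enhancement stage once.
* The hair detector forgoes hairs that cross the lesion interior.
* AUC is a simple rank-based implementation for the pipeline's own
  probability outputs; boundary-distance metrics (Hausdorff) are out of
  scope.
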