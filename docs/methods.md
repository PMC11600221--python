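# Methods

## Signal model and the synthetic-data generator

The simulator emulates the statistical skeleton of a potentiometric
electronic-tongue measurement: per channel, a flat reference-phase trace
followed by an exponential approach to a class-specific steady state once
the electrode array enters the test liquid. For channel c of a measurement
of class k,

    v_c(t) = b_c + j_c + Δv_{k,c} · (1 − e^{−t/τ}) + d·t + ε_c(t),  t in the test phase,

with per-channel dataset baseline b_c ~ U(−50, 50) mV (one electrode array
per dataset), replicate jitter j_c ~ N(0, σ²), drift d, i.i.d. noise
ε ~ N(0, σ²), and the class archetype Δv_k drawn per channel from
N(0, (s·10 mV)²) where s is the `separation` parameter. Defaults — s = 1,
σ = 0.5 mV, d = 10 µV/s, τ = 10 s, 15 channels, 100 s + 60 s at 1 Hz — are
chosen to look like a benchtop potentiometric array: millivolt-scale
class differences an order of magnitude above the noise floor, settling
within the first quarter of the test window. `separation = 0` collapses all
classes onto the same archetype and is the null condition used for
chance-level checks.

Task layouts mirror typical small e-tongue studies: 7 wines × 10
replicates; 6 protein products × 10; glucose/sucrose at 2.5/5/10 %w/w × 10
(concentration embedded by scaling Δv with level/10, so concentration
ordering is physically monotone); 12 milk products over 5 protein sources ×
5 replicates, where products of one source share the source archetype plus
a smaller per-product offset (0.3× the class scale) so leave-one-product-out
is nontrivial but solvable; and a 4-category beverage layout (8 coffees, 9
juices, 8 waters, 7 wines) for clustering. The beverage layout uses a
uniform 5 replicates per product (160 recordings); studies of this kind
often have ragged replicate counts (e.g. 150 over 32 products), which the
uniform layout intentionally simplifies.

What the generator does **not** emulate: Nernstian electrochemistry,
cross-sensitivity structure between channels, session-to-session sensor
drift or aging, rinse-phase carry-over, and temperature effects. Passing
tests on synthetic data therefore demonstrate that the pipeline's
*mechanics* (encoding, featurization, protocols, statistics) are correct
and that it recovers class structure of the assumed shape — not that any
particular accuracy will be achieved on a physical sensor array.

All randomness flows through `numpy` `SeedSequence`s keyed by
(seed, class index, replicate index), so identical configurations are
bit-identical, replicates are independent, and no stream is shared between
the data generator, the split resampler and stochastic classifiers (head
seeds are mixed with a distinct constant: sharing the raw integer between
`train_test_split` and a seeded uniform dummy classifier measurably
correlates their draws).

## Encoding

Chain: test-window extraction → optional baseline subtraction (off by
default; raw test-phase voltages are encoded) → channel-major concatenation
(ascending channel index — the Gram matrix depends on this order, so it is
fixed and documented) → piecewise aggregate approximation to the extractor
resolution M (segment m averages indices [⌊mN/M⌋, ⌊(m+1)N/M⌋); applied to
the 1-D series, not the rendered image, keeping the cost O(M²)) → min-max
scaling to [−1, 1] → φ = arccos(x) → G = cos(φᵢ+φⱼ). Scaling is applied
after PAA so the image always spans the full [−1, 1] range per measurement.
A constant signal normalizes to all zeros rather than erroring, letting
degenerate fixtures flow through. arccos tolerates overshoot of [−1, 1] up
to 1e−9 (clipped); anything larger raises, because it indicates a
normalization bug rather than float slop.

GAF* multiplies column j of G by w_j, the PAA-reduced raw response min-max
mapped to [0, 1] per measurement (raw volts would leave the renderable
range; the unscaled option is available via `unit_scale=False`). A constant
raw signal yields unit weights. Rendering maps [min, max] of the matrix
affinely onto [0, 255] with round-half-to-even; the gray plane is
replicated to 3 channels by default, with a viridis colormap as the
alternative (which mapping a colored-figure pipeline used is generally not
knowable from published images, so both are provided and replicate is the
deterministic default).

## Features and heads

The built-in extractor is a deterministic 1280-dim function of the pixels:
8×8-grid cell statistics of the gray plane (64 means, 64 stds, 64 mins, 64
maxes, stat-major) followed by the lowest 32×32 block of the orthonormal
2-D DCT. It is not a learned model and makes no claim of matching a
pretrained backbone's representational power; it honours the same contract
(pure, frozen, fixed dimension) so every protocol runs offline. External
backbones (MobileNet/ResNet/ViT/BeiT-class models at 96/224/384 input)
enter through `register_backbone`; an unregistered name raises a capability
error naming the fallback rather than downloading anything. Embeddings are
cached by pixel content hash, which makes the 50-repetition and
augmentation loops cheap.

PCA (k ∈ {5, 10, 15, 20, 25}; 20 for identification, 10 few-shot) is
refitted on the training portion of every split — test embeddings never
touch the basis. Heads: RF with 50 trees, LDA, 3-NN, SVM, Extra Trees and
XGBoost at library defaults, plus a uniform-random dummy head as the chance
baseline. KNN ties are resolved by scikit-learn's class-order rule (the
standard implementation's behaviour) rather than a custom nearest-neighbour
tie-break. Report standard deviations use ddof = 1.

## Protocols and statistics

* Repeated k-fold: "random five-fold 80/20" is realized as 50 independent
  stratified 80/20 resamplings (fresh split per repetition), which
  guarantees every class appears in training at 10 replicates/class.
* Sugar leave-one-class-out: 4 iterations (each extreme of each sugar);
  the middle 5% level of **both** sugars is relabelled to the held-out side
  in that iteration; the 10 held-out replicates are scored among
  {glucose, sucrose} × {low, high}; predictions pool to 40.
* Milk leave-one-product-out: 12 iterations, predictions pooled (60 with
  the default roster of almond 2 / cow 2 / soy 2 / oat 3 / pea 3 products —
  the roster is configuration, since published rosters are sometimes
  ambiguous, and every source must keep ≥ 2 products for the protocol to be
  defined).
* Clustering: ward linkage on Euclidean distances over PCA scores, fixed
  k = 4, scored by ARI against the true category labels. Because archetypes
  are random draws and the class/offset geometry is scale-invariant, a
  minority of simulation seeds place two categories close enough that ward
  merges them; ARI = 1 is the typical, not universal, outcome.
* Few-shot: k ∈ {3, 5, 7} shots/class, 50 paired splits, 10 PCs; the
  augmented condition tops every class up to 50 training images by mixing
  a random real shot of the class with a random shot of a random other
  class at a = 0.85 (the accuracy is flat across the 0.95–0.75 ratio grid,
  so one ratio is fixed as default); synthetic images are re-extracted and
  never enter the test set. Conditions are compared with a two-sided
  two-sample t-test; both-degenerate distributions with equal means return
  p = 1 by convention.

Chance-level assertions use the 95% binomial interval of the pooled correct
count over all repetitions' test predictions. Pooling understates the
variance of a mean of correlated repetition accuracies slightly, so these
checks are asserted at fixed seeds.

## Problem sizes

Tests and the acceptance script run entirely on simulated data at the study
layouts above (70/60/60/60/160 measurements), 96×96 fingerprints and the
built-in extractor; the full acceptance run and the full test suite each
complete in well under a minute on one CPU. Real-backbone benchmarks on
public datasets are out of scope of the test suite: they require downloaded
weights and data, and the adapter contract is the supported entry point.

## Known limitations

* The built-in extractor's embeddings are far lower-capacity than
  pretrained vision backbones; absolute accuracies on real data will differ.
* The simulator's i.i.d. Gaussian noise and linear drift are optimistic;
  real sensor noise is correlated in time and across channels.
* GAF encoding discards the sign of x via the diagonal only up to x²;
  amplitude information lost to per-measurement scaling is recovered only
  through GAF*.
* The milk and clustering rosters are configurable but default to one
  plausible layout; conclusions about roster-sensitive quantities (pooled
  prediction counts) follow the configured roster.
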