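# Methods

## Model and assumptions

The classifier treats each activity instance as a bag of sensor activations
over a fixed L-sensor inventory. Both encodings (counts or presence) discard
event order and timing entirely, so the model assumes class identity is
carried by *which* sensors fire (and, for the numeric encoding, how often),
not by their sequence. Segmentation is assumed done upstream: every input
row is exactly one activity.

Each of K base classifiers is a k-means clustering of the full training set
under a random feature subset, summarised by a support matrix; classification
fuses the nearest cluster's support row from every collection with
exponential distance damping (see the README for both formulas). Two
properties of the support formula matter in practice:

* it is normalised by the perfectly-mixed expectation N_i/M rather than the
  cluster size alone, so support for a class depends on the whole cluster's
  composition, and the value is bounded in [−1, 1] for any counts;
* the fusion exponent A/(1 + d) means a *nearby* cluster pushes the score
  toward e^A (strong evidence either way) while a *distant* one pushes it
  toward e^0 = 1 (indifference); entries of exactly −1 (class absent from
  the cluster) are excluded rather than damped, contributing 0.

The fusion exponent is the ratio form e^{A/(1+d)}, which the bundled worked
example pins down numerically (e^{0.3/2.7} = 1.12 etc.).

Randomising both the feature subset and the cluster count — instead of
tuning them per classifier — is a deliberate anti-overfitting choice; the
price is run-to-run variance, which is why K matters (below).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_classifiers` (K) | 30 | ensemble size. The stability experiment (accuracy s.d. over 50 retrainings) shows the spread collapsing by an order of magnitude between K = 1 and K = 30 while gains beyond that flatten. |
| `cluster_bound_multiplier` | 3 | P is drawn uniformly from [M, 3M], M = number of classes. The lower bound gives each class a chance at its own cluster; the upper bound keeps empty clusters rare. Empty clusters at convergence are dropped (their support row would be undefined). |
| `centroid_mode` | `auto` | per-feature arithmetic mean for numeric data; per-feature mode for binary data (centroids stay 0/1, matching how categorical attributes are usually summarised). `auto` picks by encoding. |
| encoding | — | `binary` is the recommended default for ADL data: count variability within a class (a fridge opened 1–10 times while cooking) inflates numeric Euclidean distances between same-class instances. |

## Numerical and algorithmic choices

* **k-means**: Lloyd's algorithm, single run, centroids seeded from P
  distinct instances drawn uniformly; no k-means++ and no restarts, so one
  (seed, data) pair maps to exactly one model. Convergence = unchanged
  assignments, capped at 100 iterations (the cap matters for mode centroids,
  which can in principle cycle). Assignment ties go to the lowest cluster
  index; prediction ties go to the earlier class in the class order. All
  tie-breaks are deterministic by construction.
* **Subspace semantics**: distances during clustering use only the sampled
  feature subset; retained centroids are reported over all L features, and
  *classification* distance is full-space against those centroids. Duplicate
  indices from sampling with replacement are deduplicated (they would
  silently double-weight a dimension); the raw draw is recorded.
* **Seeding**: each base classifier k draws from a generator spawned from
  (master seed, k) via `numpy.random.SeedSequence`, so ensembles are
  reproducible bit for bit and individual classifiers can be retrained in
  isolation.
* **Support matrix**: computed in full precision; display rounding is left
  to reporting code. M = 1 is defined as support 1 (every cluster is pure).
* **Degenerate inputs**: P > N is an error (cannot seed P distinct
  centroids); training with fewer instances than classes is an error; an
  all-zero fused support vector (possible only for a query excluded by every
  selected row) falls back to the training-majority class.
* **Metrics**: confusion matrices are rows-predicted × columns-actual;
  precision = diagonal/row sum, recall = diagonal/column sum, macro-averaged
  without class weights because the datasets of interest are strongly
  imbalanced. A class never predicted gets precision 0 with a warning.
  Cross-validation accuracy is reported both pooled (trace/total) and as the
  mean over folds; the two differ only through unequal fold sizes.
* **Davies-Bouldin**: per-group scatter is the mean member-to-centroid
  Euclidean distance; coincident centroids raise rather than return an
  arbitrary value. Cross-checked against scikit-learn's implementation.

## Synthetic data

The generator emulates single-resident ambient-sensor corpora: 14 object
sensors, 7 activities with strongly imbalanced frequencies (weights
34 : 112 : 23 : 24 : 20 : 10 : 22 in the bundled recipe, 245 instances by
default), per-activity sensor signatures with a designated confusable pair
(the two meal-preparation activities share the fridge and food cupboards),
geometric per-sensor occurrence counts, and an optional spurious-activation
noise rate (default 2 % in the bundled recipe). Activation draws that come
up empty are redrawn, since a segmented activity always contains at least
one event; event order within an instance is shuffled because the encodings
are order-free — order carries no signal by construction.

The parametric recipe (`synthetic_config`) assigns each class two private
sensors and exposes an `overlap` knob replacing a fraction of one paired
class's sensors with the other's: overlap 0 gives disjoint signatures
(recovery should be essentially perfect), overlap 1 makes the pair
statistically exchangeable (errors should concentrate there).

What passing tests on this data do **not** show: robustness to realistic
daily structure, interleaved or concurrent activities, sensor dropout, or
multi-modal within-class behaviour. None of these are modelled, the first
two because the classifier itself assumes cleanly segmented, bag-of-sensors
instances.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to make their expected effects
large relative to simulation noise while staying quick on a laptop: 300
instances for signature-recovery and encoding-direction runs (5-fold
cross-validation, K = 30), 245-instance bundled-recipe data with 50
repetitions for the stability experiment (K ∈ {1, 30}), 100 random
configurations for the support-matrix sweep and 1000 random queries for the
nearest-cluster scan. The exact-arithmetic checks (support entries, the
worked classification, the reference encodings) are size-independent.

## Known limitations

* The 3M upper bound on P is a heuristic tied to the training set; very
  sparse subsets still produce empty clusters, which are dropped rather than
  prevented.
* Binary encoding discards count and order information; datasets whose
  classes differ only in those respects will not separate.
* Cross-validation retrains K classifiers per fold, so evaluation cost grows
  linearly in K × folds; prediction cost does not depend on N.
* One display entry of the bundled support tables (collection 3, cluster 6,
  class 3) shows 0.8 where the counts give 0.746; the discrepancy is a
  rounding slip in the display, and tests compare against recomputed values
  with one display-unit slack there.
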