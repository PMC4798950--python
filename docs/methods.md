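# Methods

## The simulated screen

The generator (`simspace`) emulates a robotic imaging screen over a hidden
`n × n` grid of latent targets (clones) and latent conditions (drugs, one
no-drug vehicle group). Each latent id is duplicated into
`duplication_factor` (default 2) visible ids whose numbering is a seeded
permutation, so the learner cannot infer duplication from id order; every
latent (target, condition) cell therefore corresponds to a *quad* of four
visible experiments. Latent targets are partitioned into balanced clone
groups and conditions into drug groups; each (clone group, drug group) cell
elicits one phenotype. Drug group 0 is the vehicle group and each clone
group has its own unperturbed phenotype, so the bootstrap vehicle round is
informative about target grouping.

A phenotype is a spherical Gaussian in feature space. Means are drawn by
rejection until all pairwise distances exceed `min_separation` (default 6,
in units of the within-phenotype spread, default 1). A
`hypervariable_fraction` of quads (default 0.1) receives a variance
multiplier drawn uniformly from [2, 4], emulating combinations whose
replicate experiments vary more than others. Every experiment request draws
fresh images, so the two visible ids of a latent pair yield statistically
identical but numerically distinct data. Each image independently fails
quality control with probability `qc_image_fail_prob` (default 0.2); an
experiment whose images all fail counts as not performed and returns to the
unobserved pool.

What the generator deliberately does **not** model: pixel-level image
content, plate layout and technical triplicates, batch or day effects shared
by images of one experiment, non-Gaussian or multimodal phenotype feature
distributions, and drift over rounds. Images within an experiment are i.i.d.
draws from the phenotype distribution — within-experiment variation equals
between-experiment variation for a phenotype, which is the hardest regime
for the data-splitting cutoff below. Passing tests therefore show the
machinery is correct and the loop learns efficiently on clean group
structure; they do not certify performance on real image features.

## Feature conditioning

Pooled per-round features are column centered to zero mean and unit standard
deviation (population convention, divide by N; constant columns are dropped
and reported) and a linearly independent subset of columns is selected by a
greedy left-to-right Gram–Schmidt pass with re-orthogonalization: a column is
retained iff its residual norm after projection on the retained span exceeds
`tol` (default 1e-8) times its own norm. The fitted transform is kept so
held-out images can be projected into exactly the feature space a given
round's model saw.

## Intermingling score

For point sets A and B, each of five draws samples `k = min(max_points, |A|,
|B|)` points from each set (`max_points` default 500), pools them with set
labels, and computes leave-one-out 1-nearest-neighbor accuracy under the
Euclidean metric; the per-draw score is `clamp(2(1 − acc), 0, 1)` and the
final score the mean over draws. Balanced chance-level accuracy is 0.5, so
totally intermingled sets score 1 and perfectly separable sets 0.

Draws are taken **without replacement** — always possible because `k` never
exceeds either set's size. With-replacement draws would insert exact
duplicate points whose zero distance makes them their own nearest neighbors,
biasing LOO accuracy to ≈ 0.82 (score ≈ 0.37) even for identical
distributions and destroying the score's anchor at 1; without replacement
both anchors are exact.

## Clustering and the data-splitting cutoff

Experiments are merged greedily: all pairwise scores are computed, the
highest-scoring pair (ties broken uniformly at random under the run seed) is
merged into a node pooling both point sets, and only scores involving the
new node are recomputed. Merge scores along this process are *not*
monotone: late merges join the stragglers that scored lowest, and because a
finite sample of experiments is partitioned by similarity, the last blobs of
one phenotype are genuinely slightly separable (selection bias), not just
noisy.

The cutoff is calibrated by data splitting: in each of `n_splits` (default
5) rounds, every experiment with ≥ 2 images is divided equally, randomly and
disjointly into two leaves (experiments with fewer images are excluded with
a warning) and a tree is built on the doubled leaves. Walking levels from
most to fewest clusters, the first level at which ≥ `cocluster_frac`
(default 0.90) of the experiments have both halves in one cluster is found.
A level's score is the threshold that reproduces it under pruning — the
running minimum of merge scores up to the level's merge — because raw merge
scores are non-monotone. The cutoff is the mean of this score over
splittings. If the criterion holds before any merge (only possible when
`cocluster_frac ≤ 0`) the recorded score is 1.0, the maximum.

Pruning keeps merges scoring at least the cutoff (pairs at least as
intermingled as within-experiment variation); each kept merge connects every
experiment under its two subtrees, and the connected components are the
phenotypes, labeled by decreasing size. Union semantics make the pruning
robust to a single noisy low merge deep inside an otherwise coherent
cluster.

Because the calibration tolerates 10% of halves not rejoining while the main
tree needs every same-phenotype merge to survive, a few peripheral
experiments per round can still be split off as extra phenotypes. This is a
property of the procedure, not a failure of separation — the original
campaign likewise reported many more phenotypes than latent patterns — and
it is why end-to-end accuracy on clean truth is high but not always perfect.

## Type model and batch selection

Target-types are grown greedily from singletons: the consistent pair of
types sharing the most observed conditions is merged first (ties seeded
random), and when no pair shares evidence, remaining mutually consistent
pairs — including disjoint ones, vacuously consistent — are compressed.
Consistency is pairwise agreement on all shared conditions, which for this
structure implies joint consistency. Condition-types are then minimized
subject to the constraint that no two conditions in a type give any
target-type different predictions: an exact branch-and-bound search (minimum
clique cover of the compatibility graph) when the condition count is at most
`exact_condition_cap` (default 20), greedy largest-overlap merging plus
disjoint compression above it; the solver mode is recorded on the model.
Exact minimization deliberately merges never-observed conditions into
observed types — after the vehicle-only bootstrap the model predicts that
every drug leaves every target unperturbed, which is the correct
maximally-compressed starting hypothesis.

Predictions are table lookups on (target-type, condition-type) cells; cells
with no observed member pair are "unknown". Batch selection repeatedly picks
a random experiment from the highest-priority pool (unknown-cell experiments
first), then temporarily removes all unobserved experiments sharing both its
types; when the pool empties, removed experiments return and a new pass
begins. Within a pass no two chosen experiments share a type cell, so each
batch maximizes type-pair diversity.

## Evaluation

A held-out experiment's images each inherit the phenotype of their nearest
observed image (Euclidean); the prediction is correct iff the predicted
phenotype has a strict plurality of inherited labels (ties and "unknown"
predictions count incorrect — conservative). Overall accuracy equals
generalization accuracy on the unobserved fraction plus the observed
fraction counted correct.

Coverage histograms record the fractions of quads sampled 0–4 times.
Ordinary least squares with no intercept (the five bins lie on a simplex)
regresses per-round generalization accuracy on the histogram; rank-deficient
designs are flagged and solved by pseudo-inverse. The random baseline draws
experiments uniformly without replacement in matched per-round batches and
scores each simulated round's histogram through the fit, averaging over
simulations (default 1000).

Novel targets are matched to the reference clone with the nearest
vehicle-condition feature mean (ties to the lowest id, logged) and inherit
its Target-type predictions; the no-change baseline (vehicle phenotype for
every condition) is emitted alongside. Perturbation degree is the Euclidean
distance between an experiment's mean feature vector and its clone's vehicle
control mean, optionally normalized within clone groups by the group
maximum.

## Occupancy combinatorics

The ideal-case minimum is closed-form: with duplication hidden but known to
exist, observing the leading `n × n` block plus two duplicate-band diagonals
(`n² + 2n` of `4n²` experiments) suffices for a perfect model.

The non-randomness test treats all capacity-respecting assignments of `z`
indistinguishable experiments to `b` distinguishable quads (≤ 4 each) as
equiprobable — the null the generating-function formula defines, not a
multinomial throwing process — and computes `P(f) = C(b,f)·N(z,f) / Σ_g
C(b,g)·N(z,g)` where `N(z,f)` counts compositions of `z` into `f` parts in
1..4 via the recurrence `N(z,f) = Σ_{k=1..4} N(z−k, f−1)`. All terms are
nonnegative, so the default log-space dynamic program (logsumexp) is
cancellation-free and handles `z = 2697, b = 2304` in under a second; an
exact big-integer/rational mode is provided for validation and agrees with
the log-space mode to better than 1e-9 relative probability up to `z = 500`.

## Campaigns, determinism, problem sizes

A campaign fans one master seed out to per-stage generators
(`numpy.random.SeedSequence`), so replaying a persisted log reproduces every
artifact exactly; the learner receives only visible id pairs and phenotype
labels. Round 0 observes all targets under one vehicle condition; each
subsequent round performs the batch, pools all QC-passing data, re-fits the
feature transform, re-clusters, rebuilds the model from scratch, and selects
the next batch (uniform-random selection in baseline mode, which may defer
clustering to the final round since its selection never consults a model).
After the last round a completion sweep collects every never-observed
experiment (QC not simulated for the sweep — it stands in for post-hoc data
collection) so that each model can be scored on data it never saw.

Defaults mirror the full-scale campaign (48×48 latent, duplication 2, batch
96, 30 rounds, clustering with 5 draws / 500 points / 5 splits / 0.90
coclustering). Tests and the examples run desk-scale configurations chosen
once as realistic smaller analogues: a 4×4 latent space (2×2 groups, 3
phenotypes, 16 images per experiment, batch 8, 5 rounds) for end-to-end
behavior, and an 8×8 latent space (6×6 groups, 8 phenotypes, 16 images,
batch 16, 4 rounds, image QC failure 0.1) for the 20-seed paired comparison
of active versus random selection; clustering there uses 3 splits and caps
draws at 80 points to keep the agglomeration tractable at hundreds of
leaves. With many groups relative to the budget, uniform sampling leaves
type cells unpredicted while the active learner probes exactly those cells —
the mechanism by which active selection wins.

## Known limitations

* Phenotype over-splitting of peripheral experiments (see above) can cost a
  few held-out predictions even on cleanly separated truth.
* The exact condition-type solver is worst-case exponential; above the size
  cap the greedy fallback does not guarantee minimality (verified against
  exhaustive search only at small sizes).
* The random-baseline estimate inherits whatever bias the coverage
  regression has; it is a proxy, not a simulation of random data
  acquisition.
* Replay compares persisted metrics by exact recomputation, which assumes
  the same numerical environment (BLAS, numpy version) as the original run.
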