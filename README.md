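# phenolearn

Closed-loop active machine learning for phenotype discovery in high-content
screens, rebuilt at desk scale around a synthetic screen simulator.

## The problem

A screening campaign wants to know how each of many protein targets (tagged
cell clones) responds to each of many chemical conditions — but running every
combination is infeasible. An active learner can instead run a small batch of
experiments per round, cluster the resulting image feature vectors into
*phenotypes*, group targets and conditions that so far behave identically, and
use those groupings both to predict the unmeasured combinations and to choose
the next batch. In the original robotic campaign the targets and conditions
were secretly *duplicated* — two opaque ids per real clone and per real drug —
so that every real (clone, drug) pair corresponds to a hidden *quad* of four
logically equivalent experiments, giving an after-the-fact yardstick for how
well the learner discovered equivalences.

`phenolearn` re-creates that entire loop in software:

* **simspace** — generates the duplicated experiment grid and, on request,
  fresh bags of image-level feature vectors (spherical Gaussian phenotypes,
  per-quad variance inflation, stochastic image QC; an experiment whose images
  all fail QC counts as not performed).
* **preprocess** — per-round column centering (zero mean, unit population SD)
  and Gram–Schmidt selection of a linearly independent feature subset.
* **phenoclust** — set-based agglomerative clustering of experiments. The
  distance between two experiments (sets of feature vectors) is an
  *intermingling score*: balanced samples from both sets are pooled and
  classified leave-one-out by the nearest Euclidean neighbor; accuracy `acc`
  maps to `score = clamp(2(1 − acc), 0, 1)`, so chance-level classification
  (totally intermingled sets) scores 1 and perfect separability scores 0.
  The cluster cutoff is calibrated by splitting each experiment's images into
  two halves and finding the finest tree level where ≥ 90% of halves rejoin.
* **learner** — the Target-type / Condition-type model: targets that share
  the same measured phenotype for every condition they were both measured in
  are merged greedily (largest shared-condition overlap first); condition
  types are then minimized exactly (branch and bound) up to a size cap.
  Batches prioritize type-pair cells with no prediction and never pick two
  experiments from the same cell within a selection pass.
* **evaluation** — nearest-neighbor plurality assessment of predictions,
  five-bin quad-coverage histograms, the coverage→accuracy regression, the
  random-sampling baseline scored through that regression, novel-target
  generalization, and perturbation-degree matrices.
* **occupancy** — exact combinatorics: the ideal-case minimum experiment
  count `n² + 2n` out of `4n²`, and the capacity-4 balls-into-bins occupancy
  distribution `P(f) ∝ C(b,f)·[x^z](x+⋯+x⁴)^f` used to test whether the
  learner's quad coverage could have arisen by chance.
* **campaign** — orchestrates full simulated campaigns (active or random
  batch selection), persists per-round logs, and replays them bit-for-bit.

## Worked example

```bash
python examples/03_run_campaign.py
```

runs a 5-round active campaign on a 4×4 latent space (8×8 visible after
duplication, 3 hidden phenotypes) and prints:

```
per-round coverage of the 16 hidden quads (fractions sampled 0..4x):
  round 0: observed   8  phenotypes  2  [0.75, 0.00, 0.25, 0.00, 0.00]
  ...
  round 5: observed  48  phenotypes  3  [0.00, 0.06, 0.31, 0.19, 0.44]

final generalization accuracy (unobserved experiments): 1.000
observed fraction 0.75 -> overall accuracy 1.000
```

The coverage vector is the fraction of quads sampled 0–4 times; the learner
recovers the 3 planted phenotypes and predicts every never-observed
experiment correctly (generalization accuracy counts a prediction correct
only when the predicted phenotype wins a strict plurality of
nearest-neighbor votes from that experiment's held-out images). The other
examples demonstrate the simulator, clustering, the occupancy p-value (for a
full-scale campaign of 2697 experiments covering 1670 of 2304 quads the
upper-tail probability is ≈ 8·10⁻⁸⁶ — wildly non-random), and the coverage
regression.

A thin CLI wraps the same library:

```bash
phenolearn occupancy --z 2697 --b 2304 --f-observed 1670
phenolearn run --config campaign.yaml --out runs/demo
phenolearn replay --log runs/demo
```

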