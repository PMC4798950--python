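"""Relate quad-coverage histograms to accuracy; estimate a random baseline.

Each round's sampling pattern is summarized by the fractions of quads sampled
0..4 times; regressing per-round generalization accuracy on these five
fractions (no intercept, the bins sum to 1) yields coefficients in accuracy
units.  The same fit scores simulated uniform-random campaigns, giving a
random-selection learning curve without re-simulating data acquisition.
"""

import numpy as np

from phenolearn import (
    CoverageHistogram,
    make_ground_truth,
    predict_accuracy_from_coverage,
    simulate_random_baseline,
)

# a published-style round summary: quads never/once/../4x observed
h = CoverageHistogram.from_counts([1529, 575, 164, 36, 0])
print("coverage fractions:", np.round(h.fractions, 2).tolist())

beta = np.array([0.42, 1.0, -0.57, 6.4, -21.0])  # accuracy per unit bin fraction
pred = predict_accuracy_from_coverage(beta, h)
print(f"predicted generalization accuracy from coverage alone: {pred:.3f}")

space, _ = make_ground_truth(8, 8, 3, 3, 6, feature_dim=4, seed=0)
baseline = simulate_random_baseline(
    per_round_batch_sizes=[16] * 8, space=space, fit=beta, n_sims=500, seed=1
)
print("\nrandom-selection baseline (coverage-model estimate per round):")
for _, row in baseline.iterrows():
    print(f"  round {int(row['round'])}: "
          f"{row['mean_estimated_accuracy']:.3f} "
          f"± {row['sd_estimated_accuracy']:.3f}")
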