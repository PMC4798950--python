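"""Build a duplicated experiment space and draw data for one experiment.

The simulator hides a latent group structure (clone groups x drug groups ->
phenotype) behind shuffled visible ids, duplicating every latent target and
condition into two visible ids so that logically equivalent "quads" of four
experiments exist without the learner knowing.
"""

import numpy as np

from phenolearn import make_ground_truth, perform_experiment

space, truth = make_ground_truth(
    n_latent_targets=8,
    n_latent_conditions=8,
    n_clone_groups=3,
    n_drug_groups=3,
    n_phenotypes=6,
    feature_dim=6,
    hypervariable_fraction=0.1,
    seed=7,
)

print(f"visible space: {len(space.visible_targets)} targets x "
      f"{len(space.visible_conditions)} conditions "
      f"({space.n_quads} hidden quads of 4)")
print(f"vehicle condition ids: {sorted(space.vehicle_condition_ids)}")

t, c = space.visible_targets[0], sorted(space.vehicle_condition_ids)[0]
obs = perform_experiment(space, truth, t, c, n_images=6,
                         qc_image_fail_prob=0.2, seed=1)
print(f"\nexperiment (target {t}, condition {c}): "
      f"{len(obs.images)} images passed QC (qc_passed={obs.qc_passed})")
print("first image feature vector:", np.round(obs.images[0], 3))

# the two visible ids of one latent target give fresh, unshared draws
lt = space.visible_target_map[t]
twin = next(v for v, l in space.visible_target_map.items() if l == lt and v != t)
obs2 = perform_experiment(space, truth, twin, c, n_images=6, seed=2)
print(f"\nduplicate target {twin} draws distinct values from the same "
      f"distribution (no image sharing): first vector "
      f"{np.round(obs2.images[0], 3)}")
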