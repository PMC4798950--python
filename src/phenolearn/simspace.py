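"""Synthetic duplicated screen: experiment space, hidden truth, data generation.

Emulates a high-content screen in which each of ``n`` latent targets (tagged
clones) and ``n`` latent conditions (drugs, including a no-drug vehicle) is
secretly duplicated into two visible ids, presenting the learner with a
``2n x 2n`` grid of opaque experiments.  The hidden generative model groups
clones and drugs; each (clone group, drug group) cell elicits one phenotype,
realized as a spherical Gaussian in feature space.  Some quads are
hypervariable (variance multiplier > 1), and each image independently fails
quality control with a configurable probability — an experiment whose images
all fail counts as not performed.

Every experiment request draws fresh feature vectors, so the two visible ids
of one latent pair produce statistically identical but numerically distinct
data: duplication cannot be detected by exact matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentSpace",
    "GroundTruth",
    "ObservationSet",
    "make_ground_truth",
    "perform_experiment",
    "observations_to_frame",
    "frame_to_point_sets",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class ExperimentSpace:
    """The visible grid of experiments presented to the learner.

    Visible ids are dense integers whose order carries no information about
    the hidden duplication.
    """

    n_latent_targets: int
    n_latent_conditions: int
    duplication_factor: int
    visible_target_map: dict[int, int]  # visible target id -> latent target id
    visible_condition_map: dict[int, int]
    vehicle_condition_ids: frozenset[int]  # visible ids of the no-drug condition

    @property
    def visible_targets(self) -> list[int]:
        return sorted(self.visible_target_map)

    @property
    def visible_conditions(self) -> list[int]:
        return sorted(self.visible_condition_map)

    @property
    def n_quads(self) -> int:
        return self.n_latent_targets * self.n_latent_conditions

    def all_experiments(self) -> list[tuple[int, int]]:
        return [(t, c) for t in self.visible_targets for c in self.visible_conditions]

    def quad_of(self, visible_target: int, visible_condition: int) -> tuple[int, int]:
        """Latent (target, condition) pair of a visible experiment."""
        try:
            return (
                self.visible_target_map[visible_target],
                self.visible_condition_map[visible_condition],
            )
        except KeyError as exc:
            raise LookupError(f"unknown visible id: {exc}") from exc

    def __post_init__(self) -> None:
        for name, mapping, n in (
            ("target", self.visible_target_map, self.n_latent_targets),
            ("condition", self.visible_condition_map, self.n_latent_conditions),
        ):
            counts = np.bincount(list(mapping.values()), minlength=n)
            if len(mapping) != n * self.duplication_factor or not (
                counts == self.duplication_factor
            ).all():
                raise ValueError(
                    f"every latent {name} must have exactly "
                    f"{self.duplication_factor} visible ids"
                )
        if not self.vehicle_condition_ids:
            raise ValueError("at least one vehicle condition is required")


@dataclass(frozen=True)
class GroundTruth:
    """Hidden generative model the learner must rediscover.

    ``phenotype_of[(clone_group, drug_group)]`` names the phenotype elicited;
    phenotype ``p`` is a Gaussian with mean ``phenotype_mean[p]`` and
    per-feature spread ``phenotype_scale[p]``, inflated per quad by
    ``sqrt(quad_variance_multiplier)``.
    """

    clone_group: dict[int, int]  # latent target -> group
    drug_group: dict[int, int]  # latent condition -> group
    phenotype_of: dict[tuple[int, int], int]
    phenotype_mean: np.ndarray  # (n_phenotypes, d)
    phenotype_scale: np.ndarray  # (n_phenotypes, d)
    quad_variance_multiplier: np.ndarray  # (n_latent_targets, n_latent_conditions)
    feature_dim: int
    vehicle_drug_group: int

    def phenotype_of_quad(self, latent_target: int, latent_condition: int) -> int:
        return self.phenotype_of[
            (self.clone_group[latent_target], self.drug_group[latent_condition])
        ]


@dataclass
class ObservationSet:
    """One performed experiment: its visible ids, images, and QC outcome."""

    visible_target: int
    visible_condition: int
    round_index: int
    images: np.ndarray  # (n_kept_images, d); empty iff QC failed
    qc_passed: bool

    def __post_init__(self) -> None:
        if self.qc_passed != (len(self.images) > 0):
            raise ValueError("images must be nonempty iff qc_passed")

    @property
    def experiment(self) -> tuple[int, int]:
        return (self.visible_target, self.visible_condition)


def _balanced_groups(n_items: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random assignment of items to groups with every group nonempty."""
    labels = np.arange(n_items) % n_groups
    return rng.permutation(labels)


def _separated_means(
    n: int, dim: int, min_separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n mean vectors with all pairwise distances >= min_separation."""
    scale = max(min_separation, 1.0)
    for _ in range(200):
        means = rng.normal(0.0, scale, size=(n, dim))
        if n == 1:
            return means
        d2 = np.sum((means[:, None, :] - means[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.sqrt(d2.min()) >= min_separation:
            return means
        scale *= 1.3
    raise RuntimeError("failed to place separated phenotype means")


def make_ground_truth(
    n_latent_targets: int,
    n_latent_conditions: int,
    n_clone_groups: int,
    n_drug_groups: int,
    n_phenotypes: int,
    feature_dim: int,
    duplication_factor: int = 2,
    hypervariable_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
    min_separation: float = 6.0,
    base_scale: float = 1.0,
    hyper_multiplier: tuple[float, float] = (2.0, 4.0),
) -> tuple[ExperimentSpace, GroundTruth]:
    """Build a duplicated experiment space and its hidden generative model.

    Clones and drugs are partitioned into balanced groups; drug group 0 is the
    vehicle (no-drug) group and each clone group gets its own unperturbed
    phenotype so the vehicle round is informative.  Remaining (clone group,
    drug group) cells are assigned phenotypes so that all ``n_phenotypes`` are
    used.  Phenotype means are separated by at least ``min_separation``.
    Visible ids are a seeded permutation, hiding the duplication.
    """
    rng = np.random.default_rng(seed)
    if n_clone_groups > n_latent_targets or n_drug_groups > n_latent_conditions:
        raise ValueError("group counts must not exceed latent counts")
    if n_clone_groups < 1 or n_drug_groups < 1:
        raise ValueError("need at least one clone group and one drug group")
    if n_phenotypes > n_clone_groups * n_drug_groups:
        raise ValueError("n_phenotypes must be <= n_clone_groups * n_drug_groups")
    if n_phenotypes < n_clone_groups:
        raise ValueError(
            "n_phenotypes must be >= n_clone_groups "
            "(each clone group has a distinct unperturbed phenotype)"
        )
    if duplication_factor < 1:
        raise ValueError("duplication_factor must be >= 1")
    if not 0.0 <= hypervariable_fraction <= 1.0:
        raise ValueError("hypervariable_fraction must be in [0, 1]")

    clone_group = _balanced_groups(n_latent_targets, n_clone_groups, rng)
    drug_group = _balanced_groups(n_latent_conditions, n_drug_groups, rng)

    # vehicle column: clone group g keeps phenotype g unperturbed
    phenotype_of: dict[tuple[int, int], int] = {
        (g, 0): g for g in range(n_clone_groups)
    }
    other_cells = [
        (cg, dg)
        for cg in range(n_clone_groups)
        for dg in range(1, n_drug_groups)
    ]
    rng.shuffle(other_cells)
    unused = list(range(n_clone_groups, n_phenotypes))
    for i, cell in enumerate(other_cells):
        if i < len(unused):
            phenotype_of[cell] = unused[i]
        else:
            phenotype_of[cell] = int(rng.integers(0, n_phenotypes))

    means = _separated_means(n_phenotypes, feature_dim, min_separation, rng)
    scales = np.full((n_phenotypes, feature_dim), base_scale, dtype=float)

    mult = np.ones((n_latent_targets, n_latent_conditions))
    n_quads = n_latent_targets * n_latent_conditions
    n_hyper = int(round(hypervariable_fraction * n_quads))
    if n_hyper:
        flat = rng.choice(n_quads, size=n_hyper, replace=False)
        mult.flat[flat] = rng.uniform(*hyper_multiplier, size=n_hyper)

    def _visible_map(n_latent: int) -> dict[int, int]:
        latent_seq = np.repeat(np.arange(n_latent), duplication_factor)
        visible_ids = rng.permutation(n_latent * duplication_factor)
        return {int(v): int(l) for v, l in zip(visible_ids, latent_seq)}

    vt_map = _visible_map(n_latent_targets)
    vc_map = _visible_map(n_latent_conditions)
    vehicle_latents = {lc for lc, g in enumerate(drug_group) if g == 0}
    vehicle_ids = frozenset(v for v, l in vc_map.items() if l in vehicle_latents)

    space = ExperimentSpace(
        n_latent_targets=n_latent_targets,
        n_latent_conditions=n_latent_conditions,
        duplication_factor=duplication_factor,
        visible_target_map=vt_map,
        visible_condition_map=vc_map,
        vehicle_condition_ids=vehicle_ids,
    )
    truth = GroundTruth(
        clone_group={i: int(g) for i, g in enumerate(clone_group)},
        drug_group={i: int(g) for i, g in enumerate(drug_group)},
        phenotype_of=phenotype_of,
        phenotype_mean=means,
        phenotype_scale=scales,
        quad_variance_multiplier=mult,
        feature_dim=feature_dim,
        vehicle_drug_group=0,
    )
    return space, truth


def perform_experiment(
    space: ExperimentSpace,
    truth: GroundTruth,
    visible_target: int,
    visible_condition: int,
    n_images: int = 6,
    qc_image_fail_prob: float = 0.0,
    seed: int | np.random.Generator | None = None,
    round_index: int = 0,
) -> ObservationSet:
    """Run one experiment: fresh feature draws plus stochastic image QC.

    Each of the ``n_images`` fields is drawn i.i.d. from the quad's phenotype
    Gaussian (spread inflated by the quad's variance multiplier) and then
    independently dropped with probability ``qc_image_fail_prob``.  If all
    images are dropped the experiment counts as not performed
    (``qc_passed=False``, empty image array).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    lt, lc = space.quad_of(visible_target, visible_condition)
    pid = truth.phenotype_of_quad(lt, lc)
    sd = truth.phenotype_scale[pid] * np.sqrt(truth.quad_variance_multiplier[lt, lc])
    images = truth.phenotype_mean[pid] + sd * rng.standard_normal(
        (n_images, truth.feature_dim)
    )
    keep = rng.random(n_images) >= qc_image_fail_prob
    kept = images[keep]
    return ObservationSet(
        visible_target=visible_target,
        visible_condition=visible_condition,
        round_index=round_index,
        images=kept,
        qc_passed=bool(len(kept)),
    )


# ---------------------------------------------------------------------------
# feature-table I/O (CSV, one row per image)


def observations_to_frame(observations: list[ObservationSet]) -> pd.DataFrame:
    """Tidy per-image feature table: round, ids, image_index, f0..fd-1."""
    rows = []
    for obs in observations:
        for i, vec in enumerate(obs.images):
            rows.append(
                (obs.round_index, obs.visible_target, obs.visible_condition, i, *vec)
            )
    if not rows:
        raise ValueError("no images to tabulate")
    d = len(rows[0]) - 4
    cols = ["round", "visible_target", "visible_condition", "image_index"] + [
        f"f{i}" for i in range(d)
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_point_sets(frame: pd.DataFrame) -> dict[tuple[int, int], np.ndarray]:
    """Group a feature table into per-experiment image arrays."""
    fcols = [c for c in frame.columns if c.startswith("f")]
    out: dict[tuple[int, int], np.ndarray] = {}
    for (t, c), grp in frame.groupby(["visible_target", "visible_condition"]):
        out[(int(t), int(c))] = grp[fcols].to_numpy(dtype=float)
    return out


def save_ground_truth(path: str | Path, space: ExperimentSpace, truth: GroundTruth) -> None:
    """Persist the space and hidden truth as a JSON sidecar (never shown to the learner)."""
    payload = {
        "space": {
            "n_latent_targets": space.n_latent_targets,
            "n_latent_conditions": space.n_latent_conditions,
            "duplication_factor": space.duplication_factor,
            "visible_target_map": {str(k): v for k, v in space.visible_target_map.items()},
            "visible_condition_map": {
                str(k): v for k, v in space.visible_condition_map.items()
            },
            "vehicle_condition_ids": sorted(space.vehicle_condition_ids),
        },
        "truth": {
            "clone_group": {str(k): v for k, v in truth.clone_group.items()},
            "drug_group": {str(k): v for k, v in truth.drug_group.items()},
            "phenotype_of": [
                {"clone_group": cg, "drug_group": dg, "phenotype": p}
                for (cg, dg), p in sorted(truth.phenotype_of.items())
            ],
            "phenotype_mean": truth.phenotype_mean.tolist(),
            "phenotype_scale": truth.phenotype_scale.tolist(),
            "quad_variance_multiplier": truth.quad_variance_multiplier.tolist(),
            "feature_dim": truth.feature_dim,
            "vehicle_drug_group": truth.vehicle_drug_group,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: str | Path) -> tuple[ExperimentSpace, GroundTruth]:
    payload = json.loads(Path(path).read_text())
    s, t = payload["space"], payload["truth"]
    space = ExperimentSpace(
        n_latent_targets=s["n_latent_targets"],
        n_latent_conditions=s["n_latent_conditions"],
        duplication_factor=s["duplication_factor"],
        visible_target_map={int(k): v for k, v in s["visible_target_map"].items()},
        visible_condition_map={int(k): v for k, v in s["visible_condition_map"].items()},
        vehicle_condition_ids=frozenset(s["vehicle_condition_ids"]),
    )
    truth = GroundTruth(
        clone_group={int(k): v for k, v in t["clone_group"].items()},
        drug_group={int(k): v for k, v in t["drug_group"].items()},
        phenotype_of={
            (rec["clone_group"], rec["drug_group"]): rec["phenotype"]
            for rec in t["phenotype_of"]
        },
        phenotype_mean=np.array(t["phenotype_mean"], dtype=float),
        phenotype_scale=np.array(t["phenotype_scale"], dtype=float),
        quad_variance_multiplier=np.array(t["quad_variance_multiplier"], dtype=float),
        feature_dim=t["feature_dim"],
        vehicle_drug_group=t["vehicle_drug_group"],
    )
    return space, truth
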