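"""Scoring predictions and characterizing sampling efficiency.

Covers four analyses:

* **Nearest-neighbor plurality assessment** — each image of a held-out
  experiment inherits the phenotype of its Euclidean-nearest observed image;
  the experiment's prediction is correct iff the predicted phenotype holds a
  strict plurality of the inherited labels.
* **Quad-coverage histograms and regression** — a five-bin histogram records
  the fraction of quads (latent target x condition cells, each containing
  four duplicated experiments) sampled 0..4 times; per-round histograms are
  regressed (ordinary least squares, no intercept — the bins lie on a
  simplex) on generalization accuracy, so the fit's coefficients are in
  accuracy units per unit bin fraction.
* **Random-sampling baseline** — the expected learning curve of a learner
  choosing experiments uniformly without replacement, scored through the
  coverage regression rather than by simulating data acquisition.
* **Novel-target generalization and perturbation degree** — matching an
  unseen clone to the reference clone with the nearest vehicle-condition
  feature mean, and the Euclidean distance of each experiment's mean feature
  vector from its clone's vehicle control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .simspace import ExperimentSpace

__all__ = [
    "CoverageHistogram",
    "RegressionFit",
    "nn_plurality_assess",
    "quad_histogram",
    "fit_coverage_regression",
    "predict_accuracy_from_coverage",
    "simulate_random_baseline",
    "generalize_to_novel",
    "perturbation_degree",
]

logger = logging.getLogger(__name__)

Experiment = tuple[int, int]


@dataclass(frozen=True)
class CoverageHistogram:
    """Five-bin quad sampling multiplicity: fractions of quads hit 0..4 times."""

    counts: np.ndarray  # (5,) int, counts of quads sampled 0,1,2,3,4 times
    b: int  # total quads

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (5,) or (counts < 0).any():
            raise ValueError("counts must be 5 nonnegative integers")
        if counts.sum() != self.b:
            raise ValueError("counts must sum to the number of quads")

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "CoverageHistogram":
        counts = np.asarray(counts, dtype=int)
        return cls(counts=counts, b=int(counts.sum()))

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.b


def quad_histogram(
    observed_experiments: Sequence[Experiment], space: ExperimentSpace
) -> CoverageHistogram:
    """Histogram of how often the observed experiments fall in the same quad."""
    if space.duplication_factor != 2:
        raise ValueError("quad histograms assume duplication factor 2 (quads of 4)")
    mult = np.zeros((space.n_latent_targets, space.n_latent_conditions), dtype=int)
    for t, c in set(observed_experiments):
        lt, lc = space.quad_of(t, c)
        mult[lt, lc] += 1
    counts = np.bincount(mult.ravel(), minlength=5)
    return CoverageHistogram(counts=counts, b=space.n_quads)


@dataclass
class RegressionFit:
    """OLS fit of generalization accuracy on the five coverage-bin fractions."""

    beta: np.ndarray  # (5,) accuracy per unit bin fraction
    residuals: np.ndarray
    fitted: np.ndarray
    rank: int
    singular_values: np.ndarray


def fit_coverage_regression(
    histograms: Sequence[CoverageHistogram] | np.ndarray,
    accuracies: Sequence[float],
) -> RegressionFit:
    """Regress per-round generalization accuracy on quad-coverage histograms.

    No intercept is fitted: the five bin fractions sum to one, so an
    intercept would be redundant.  A rank-deficient design (e.g. constant
    histograms) is flagged with a warning and solved by pseudo-inverse
    (minimum-norm least squares).
    """
    H = np.array(
        [h.fractions if isinstance(h, CoverageHistogram) else h for h in histograms],
        dtype=float,
    )
    y = np.asarray(accuracies, dtype=float)
    if H.shape[0] < 5:
        raise ValueError("need at least 5 rounds, one per coefficient")
    if H.shape[0] != len(y):
        raise ValueError("one accuracy per histogram required")
    beta, _, rank, sv = np.linalg.lstsq(H, y, rcond=None)
    if rank < 5:
        warnings.warn(
            f"coverage design is rank deficient (rank {rank}); "
            "pseudo-inverse solution returned",
            stacklevel=2,
        )
    fitted = H @ beta
    return RegressionFit(
        beta=beta, residuals=y - fitted, fitted=fitted, rank=int(rank),
        singular_values=sv,
    )


def predict_accuracy_from_coverage(
    fit: RegressionFit | np.ndarray, histogram: CoverageHistogram | np.ndarray
) -> float:
    """Accuracy estimate h . beta for a coverage histogram."""
    beta = fit.beta if isinstance(fit, RegressionFit) else np.asarray(fit, dtype=float)
    h = (
        histogram.fractions
        if isinstance(histogram, CoverageHistogram)
        else np.asarray(histogram, dtype=float)
    )
    return float(h @ beta)


def simulate_random_baseline(
    per_round_batch_sizes: Sequence[int],
    space: ExperimentSpace,
    fit: RegressionFit | np.ndarray,
    n_sims: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expected learning curve of uniform random experiment selection.

    Per simulation, experiments are drawn without replacement from the full
    visible space in per-round batches matching ``per_round_batch_sizes``;
    after each round the quad histogram is scored through the coverage
    regression.  Returns a frame with per-round mean and SD of the estimated
    accuracy over ``n_sims`` simulations.
    """
    rng = np.random.default_rng(seed)
    beta = fit.beta if isinstance(fit, RegressionFit) else np.asarray(fit, dtype=float)
    experiments = space.all_experiments()
    total = len(experiments)
    sizes = list(per_round_batch_sizes)
    if sum(sizes) > total:
        raise ValueError("batch sizes exceed the experiment space")
    quad_idx = np.array(
        [
            space.quad_of(t, c)[0] * space.n_latent_conditions + space.quad_of(t, c)[1]
            for t, c in experiments
        ]
    )
    b = space.n_quads
    accs = np.empty((n_sims, len(sizes)))
    for s in range(n_sims):
        perm = rng.permutation(total)
        cum = 0
        for r, size in enumerate(sizes):
            cum += size
            mult = np.bincount(quad_idx[perm[:cum]], minlength=b)
            h = np.bincount(np.minimum(mult, 4), minlength=5) / b
            accs[s, r] = h @ beta
    return pd.DataFrame(
        {
            "round": np.arange(len(sizes)),
            "mean_estimated_accuracy": accs.mean(axis=0),
            "sd_estimated_accuracy": accs.std(axis=0, ddof=1) if n_sims > 1 else 0.0,
        }
    )


def nn_plurality_assess(
    predictions: Mapping[Hashable, int | None],
    observed_images: np.ndarray,
    observed_labels: Sequence[int],
    heldout_images: Mapping[Hashable, np.ndarray],
    chunk: int = 2048,
) -> tuple[dict[Hashable, bool], float, list[Hashable]]:
    """Score predictions for held-out experiments by nearest-neighbor plurality.

    Every held-out image inherits the phenotype label of the Euclidean-nearest
    observed image; a held-out experiment is counted correct iff its predicted
    phenotype received strictly more inherited labels than any other single
    phenotype.  Experiments predicted "unknown" (None) are counted incorrect
    and returned in the flagged list.

    Returns ``(per-experiment correctness, accuracy, flagged_unknown)``.
    """
    observed_images = np.asarray(observed_images, dtype=float)
    observed_labels = np.asarray(observed_labels)
    if len(observed_images) == 0:
        raise ValueError("observed pool is empty")
    if len(observed_images) != len(observed_labels):
        raise ValueError("one label per observed image required")

    keys = list(heldout_images)
    for k in keys:
        if k not in predictions:
            raise ValueError(f"held-out experiment {k!r} has no prediction")
        if len(heldout_images[k]) == 0:
            raise ValueError(f"held-out experiment {k!r} has no images")

    stacked = np.concatenate([np.atleast_2d(heldout_images[k]) for k in keys])
    bounds = np.cumsum([0] + [len(np.atleast_2d(heldout_images[k])) for k in keys])
    nn_labels = np.empty(len(stacked), dtype=observed_labels.dtype)
    for start in range(0, len(stacked), chunk):
        D = cdist(stacked[start : start + chunk], observed_images, "sqeuclidean")
        nn_labels[start : start + chunk] = observed_labels[D.argmin(axis=1)]

    correct: dict[Hashable, bool] = {}
    flagged: list[Hashable] = []
    for i, k in enumerate(keys):
        inherited = nn_labels[bounds[i] : bounds[i + 1]]
        pred = predictions[k]
        if pred is None:
            correct[k] = False
            flagged.append(k)
            continue
        values, counts = np.unique(inherited, return_counts=True)
        votes = dict(zip(values.tolist(), counts.tolist()))
        own = votes.get(pred, 0)
        others = max((v for lab, v in votes.items() if lab != pred), default=0)
        correct[k] = own > others
    accuracy = float(np.mean([v for v in correct.values()])) if correct else 0.0
    return correct, accuracy, flagged


def generalize_to_novel(
    model,
    novel_vehicle_features: Mapping[Hashable, np.ndarray],
    reference_vehicle_features: Mapping[int, np.ndarray],
    conditions: Sequence[int] | None = None,
) -> dict[Hashable, dict]:
    """Predict all conditions for novel clones from their vehicle pattern alone.

    Each novel clone is matched to the reference clone whose vehicle-condition
    feature mean is nearest (Euclidean; ties go to the lowest reference id and
    are logged), inherits that clone's Target-type, and reads predictions from
    the model's table.  The no-change baseline — predict the matched clone's
    unperturbed phenotype regardless of condition — is emitted alongside.
    """
    from .learner import predict  # local import to avoid cycle

    ref_ids = sorted(reference_vehicle_features)
    ref_means = np.array(
        [
            np.atleast_2d(reference_vehicle_features[r]).mean(axis=0)
            for r in ref_ids
        ]
    )
    if conditions is None:
        conditions = sorted(model.condition_type_of)
    # the baseline phenotype is the matched clone's vehicle prediction: use the
    # phenotype observed most often across its own conditions marked vehicle-like
    out: dict[Hashable, dict] = {}
    for novel, feats in novel_vehicle_features.items():
        mean = np.atleast_2d(np.asarray(feats, dtype=float)).mean(axis=0)
        d = np.linalg.norm(ref_means - mean, axis=1)
        order = np.argsort(d, kind="stable")
        matched = ref_ids[int(order[0])]
        ties = [ref_ids[int(i)] for i in order if d[i] == d[order[0]]]
        if len(ties) > 1:
            logger.info("novel clone %r: equidistant references %s; chose %s",
                        novel, ties, matched)
        preds = {c: predict(model, matched, c) for c in conditions}
        out[novel] = {
            "matched_reference": matched,
            "predictions": preds,
            "tied_references": ties,
        }
    return out


def perturbation_degree(
    feature_table: pd.DataFrame,
    vehicle_condition: int,
    clone_groups: Mapping[int, int] | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Degree of perturbation of each (clone, drug) pair from the vehicle control.

    Entry (clone, drug) is the Euclidean distance between the mean feature
    vector of the clone x drug experiment and the mean feature vector of that
    clone's vehicle-only control.  With ``normalize=True`` entries are divided
    within each clone group by the group's maximum entry, putting groups on a
    common (0, 1] scale; ``clone_groups`` maps clone id to group id (one group
    for all clones if omitted).

    ``feature_table`` is tidy: columns ``visible_target``,
    ``visible_condition`` and feature columns ``f*``.
    """
    fcols = [c for c in feature_table.columns if c.startswith("f")]
    means = feature_table.groupby(["visible_target", "visible_condition"])[
        fcols
    ].mean()
    clones = sorted(feature_table["visible_target"].unique())
    drugs = sorted(feature_table["visible_condition"].unique())
    deg = pd.DataFrame(index=clones, columns=drugs, dtype=float)
    for clone in clones:
        if (clone, vehicle_condition) not in means.index:
            raise ValueError(f"clone {clone} has no vehicle control data")
        control = means.loc[(clone, vehicle_condition)].to_numpy()
        for drug in drugs:
            if (clone, drug) in means.index:
                deg.loc[clone, drug] = float(
                    np.linalg.norm(means.loc[(clone, drug)].to_numpy() - control)
                )
    if normalize:
        groups = clone_groups or {c: 0 for c in clones}
        for g in set(groups.values()):
            rows = [c for c in clones if groups[c] == g]
            peak = np.nanmax(deg.loc[rows].to_numpy(dtype=float))
            if peak > 0:
                deg.loc[rows] = deg.loc[rows] / peak
    deg.index.name = "visible_target"
    deg.columns.name = "visible_condition"
    return deg
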