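"""Full closed-loop campaigns over the simulated screen.

A campaign starts with a bootstrap round observing every visible target under
one vehicle condition, then alternates: perform the requested batch (each
image subject to QC; an experiment whose images all fail counts as not
performed and returns to the unobserved pool) — pool all passing data —
condition features — cluster experiments into phenotypes — rebuild the
Target-/Condition-type model from scratch — select the next batch (actively,
or uniformly at random for the baseline mode).  After the last round the
never-observed experiments are collected in a completion sweep so that every
model can be scored against data it had not seen.

Everything is driven by one master seed, fanned out to per-stage child seeds
via ``numpy.random.SeedSequence`` so stages are independently reproducible;
re-running or replaying a persisted log reproduces every artifact exactly.
The learner is handed only visible id pairs and phenotype labels — never the
duplication maps or the generative truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import learner as _learner
from . import phenoclust as _pc
from .evaluation import nn_plurality_assess, quad_histogram
from .preprocess import fit_feature_transform
from .simspace import (
    ExperimentSpace,
    GroundTruth,
    ObservationSet,
    make_ground_truth,
    observations_to_frame,
    perform_experiment,
)

__all__ = ["CampaignConfig", "RoundRecord", "CampaignLog", "run_campaign", "replay",
           "IntegrityError"]


class IntegrityError(RuntimeError):
    """A persisted campaign log is incomplete or inconsistent."""


@dataclass
class CampaignConfig:
    """All knobs of a simulated campaign.

    Space/truth parameters mirror :func:`phenolearn.simspace.make_ground_truth`;
    clustering parameters mirror the phenoclust defaults; ``mode`` selects
    active or uniform-random batch selection.  ``n_rounds`` counts selection
    rounds after the bootstrap vehicle round.
    """

    n_latent_targets: int = 48
    n_latent_conditions: int = 48
    n_clone_groups: int = 8
    n_drug_groups: int = 8
    n_phenotypes: int = 12
    feature_dim: int = 8
    duplication_factor: int = 2
    hypervariable_fraction: float = 0.1
    min_separation: float = 6.0
    n_images: int = 6
    qc_image_fail_prob: float = 0.2
    batch_size: int = 96
    n_rounds: int = 30
    n_draws: int = 5
    max_points: int = 500
    n_splits: int = 5
    cocluster_frac: float = 0.90
    gs_tol: float = 1e-8
    exact_condition_cap: int = 20
    mode: str = "active"  # "active" | "random"
    seed: int = 0
    # evaluation / clustering cadence: "all" clusters+evaluates each round,
    # "final" clusters each round but evaluates only the last model,
    # "final-only" also defers clustering to the last round (valid for the
    # random mode, whose selection does not consult the model)
    evaluate: str = "final"

    def __post_init__(self) -> None:
        if self.mode not in ("active", "random"):
            raise ValueError("mode must be 'active' or 'random'")
        if self.evaluate not in ("all", "final", "final-only"):
            raise ValueError("evaluate must be 'all', 'final' or 'final-only'")
        if self.evaluate == "final-only" and self.mode == "active":
            raise ValueError("active selection needs a model every round")
        for name in ("batch_size", "n_rounds", "n_images"):
            if getattr(self, name) < 0 or (name != "n_rounds" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CampaignConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RoundRecord:
    """Everything one round produced."""

    index: int
    batch: list[tuple[int, int]]
    observations: list[ObservationSet]
    phenotypes: _pc.PhenotypeAssignment | None
    model: _learner.TypeModel | None
    metrics: dict[str, Any] = field(default_factory=dict)


@dataclass
class CampaignLog:
    """Append-only record of a campaign: per-round artifacts plus completion set."""

    config: CampaignConfig
    space: ExperimentSpace
    truth: GroundTruth
    rounds: list[RoundRecord]
    completion: list[ObservationSet]
    final_metrics: dict[str, Any]

    @property
    def observed_experiments(self) -> set[tuple[int, int]]:
        out = set()
        for rec in self.rounds:
            out |= {o.experiment for o in rec.observations if o.qc_passed}
        return out

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.rounds:
            row = {"round": rec.index}
            row.update(rec.metrics)
            rows.append(row)
        return pd.DataFrame(rows)

    # -- persistence (directory of CSV/JSON artifacts) ---------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(json.dumps(self.config.to_dict(), indent=1))
        from .simspace import save_ground_truth

        save_ground_truth(path / "ground_truth.json", self.space, self.truth)
        all_obs = [o for rec in self.rounds for o in rec.observations if o.qc_passed]
        observations_to_frame(all_obs).to_csv(
            path / "observations.csv", index=False, float_format="%.17g"
        )
        attempts = [
            {"round": rec.index, "visible_target": o.visible_target,
             "visible_condition": o.visible_condition, "qc_passed": o.qc_passed}
            for rec in self.rounds
            for o in rec.observations
        ]
        pd.DataFrame(attempts).to_csv(path / "attempts.csv", index=False)
        if self.completion:
            observations_to_frame(self.completion).to_csv(
                path / "completion.csv", index=False, float_format="%.17g"
            )
        pheno_rows = [
            {"round": rec.index, "visible_target": t, "visible_condition": c,
             "phenotype": lab}
            for rec in self.rounds
            if rec.phenotypes is not None
            for (t, c), lab in sorted(rec.phenotypes.labels.items())
        ]
        pd.DataFrame(pheno_rows).to_csv(path / "phenotypes.csv", index=False)
        models = {
            str(rec.index): {
                "target_types": rec.model.target_types,
                "condition_types": rec.model.condition_types,
                "table": [
                    {"target_type": i, "condition_type": j,
                     "phenotype": ("unknown" if p is None else p)}
                    for (i, j), p in sorted(rec.model.table.items())
                ],
                "condition_solver": rec.model.condition_solver,
            }
            for rec in self.rounds
            if rec.model is not None
        }
        (path / "models.json").write_text(json.dumps(models, indent=1))
        self.metrics_frame().to_csv(path / "metrics.csv", index=False, float_format="%.17g")
        (path / "final_metrics.json").write_text(
            json.dumps(self.final_metrics, indent=1, default=float)
        )


def _spawned_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _cluster_round(
    observed: dict[tuple[int, int], ObservationSet],
    config: CampaignConfig,
    rng: np.random.Generator,
    round_index: int,
):
    """Pool passing data, condition features, cluster, and label phenotypes."""
    frame = observations_to_frame(list(observed.values()))
    fcols = [c for c in frame.columns if c.startswith("f")]
    _, transform = fit_feature_transform(frame[fcols].to_numpy(), tol=config.gs_tol)
    point_sets = {
        exp: transform.apply(obs.images) for exp, obs in observed.items()
    }
    cutoff = _pc.determine_cutoff(
        point_sets,
        n_splits=config.n_splits,
        cocluster_frac=config.cocluster_frac,
        n_draws=config.n_draws,
        max_points=config.max_points,
        seed=rng,
    )
    root = _pc.build_cluster_tree(
        point_sets,
        n_draws=config.n_draws,
        max_points=config.max_points,
        seed=rng,
    )
    assignment = _pc.assign_phenotypes(root, cutoff, round_index=round_index)
    return assignment, point_sets, transform


def run_campaign(config: CampaignConfig) -> CampaignLog:
    """Run a full simulated campaign and return its log.

    Deterministic under ``config.seed``: the master seed is fanned out to the
    truth generator, the per-experiment data stream, clustering, and batch
    selection.
    """
    truth_rng, exp_rng, cluster_rng, select_rng, completion_rng = _spawned_rngs(
        config.seed, 5
    )
    space, truth = make_ground_truth(
        n_latent_targets=config.n_latent_targets,
        n_latent_conditions=config.n_latent_conditions,
        n_clone_groups=config.n_clone_groups,
        n_drug_groups=config.n_drug_groups,
        n_phenotypes=config.n_phenotypes,
        feature_dim=config.feature_dim,
        duplication_factor=config.duplication_factor,
        hypervariable_fraction=config.hypervariable_fraction,
        min_separation=config.min_separation,
        seed=truth_rng,
    )
    all_experiments = space.all_experiments()
    observed: dict[tuple[int, int], ObservationSet] = {}
    rounds: list[RoundRecord] = []

    def perform_batch(batch, round_index):
        obs_list = []
        for t, c in batch:
            obs = perform_experiment(
                space, truth, t, c,
                n_images=config.n_images,
                qc_image_fail_prob=config.qc_image_fail_prob,
                seed=exp_rng, round_index=round_index,
            )
            obs_list.append(obs)
            if obs.qc_passed:
                observed[(t, c)] = obs
        return obs_list

    batch = _learner.initial_round(space)
    transforms: dict[int, Any] = {}
    assignments: dict[int, _pc.PhenotypeAssignment] = {}
    for r in range(config.n_rounds + 1):
        obs_list = perform_batch(batch, r)
        last = r == config.n_rounds
        cluster_now = config.evaluate != "final-only" or last
        assignment = model = None
        if cluster_now and observed:
            assignment, point_sets, transform = _cluster_round(
                observed, config, cluster_rng, r
            )
            transforms[r] = (transform, point_sets)
            assignments[r] = assignment
            model = _learner.build_model(
                assignment.labels,
                targets=space.visible_targets,
                conditions=space.visible_conditions,
                seed=select_rng,
                exact_condition_cap=config.exact_condition_cap,
                round_index=r,
            )
        metrics = {
            "n_observed": len(observed),
            "n_phenotypes": assignment.n_phenotypes if assignment else 0,
        }
        if space.duplication_factor == 2:
            hist = quad_histogram(list(observed), space)
            metrics["coverage"] = hist.fractions.tolist()
        rounds.append(
            RoundRecord(index=r, batch=list(batch), observations=obs_list,
                        phenotypes=assignment, model=model, metrics=metrics)
        )
        if last:
            break
        remaining = [e for e in all_experiments if e not in observed]
        if config.mode == "active":
            batch = _learner.select_batch(
                model, set(observed), all_experiments, config.batch_size,
                seed=select_rng,
            )
        else:
            idx = select_rng.choice(
                len(remaining), size=min(config.batch_size, len(remaining)),
                replace=False,
            )
            batch = [remaining[i] for i in sorted(idx)]

    # completion sweep: collect every experiment never successfully observed
    # (post-hoc data collection; QC is not simulated for the sweep)
    completion = []
    for t, c in all_experiments:
        if (t, c) not in observed:
            completion.append(
                perform_experiment(
                    space, truth, t, c, n_images=config.n_images,
                    qc_image_fail_prob=0.0, seed=completion_rng,
                    round_index=config.n_rounds + 1,
                )
            )

    final_metrics = _evaluate_final(rounds, completion, observed, space, config)
    log = CampaignLog(
        config=config, space=space, truth=truth, rounds=rounds,
        completion=completion, final_metrics=final_metrics,
    )
    if config.evaluate == "all":
        _evaluate_all_rounds(log, transforms, assignments)
    return log


def _prediction_accuracy(model, assignment, observed, heldout_sets, transform, config):
    """Generalization accuracy of a model over held-out experiments."""
    if not heldout_sets:
        return None, {}
    pool_images = np.concatenate(
        [transform.apply(obs.images) for obs in observed.values()]
    )
    pool_labels = np.concatenate(
        [
            np.full(len(obs.images), assignment.labels[exp])
            for exp, obs in observed.items()
        ]
    )
    predictions = {
        exp: _learner.predict(model, *exp) for exp in heldout_sets
    }
    heldout_imgs = {
        exp: transform.apply(images) for exp, images in heldout_sets.items()
    }
    correct, accuracy, flagged = nn_plurality_assess(
        predictions, pool_images, pool_labels, heldout_imgs
    )
    return accuracy, {"n_heldout": len(heldout_sets), "n_unknown": len(flagged)}


def _evaluate_final(rounds, completion, observed, space, config):
    """Score the final model on the completion sweep (its unseen data)."""
    final = rounds[-1]
    if final.model is None or final.phenotypes is None or not observed:
        return {}
    frame = observations_to_frame(list(observed.values()))
    fcols = [c for c in frame.columns if c.startswith("f")]
    _, transform = fit_feature_transform(frame[fcols].to_numpy(), tol=config.gs_tol)
    heldout_sets = {obs.experiment: obs.images for obs in completion}
    accuracy, extra = _prediction_accuracy(
        final.model, final.phenotypes, observed, heldout_sets, transform, config
    )
    total = len(space.all_experiments())
    observed_frac = len(observed) / total
    out = {
        "generalization_accuracy": accuracy,
        "observed_fraction": observed_frac,
        "overall_accuracy": (
            None if accuracy is None
            else accuracy * (1 - observed_frac) + observed_frac
        ),
        "n_observed": len(observed),
        "n_phenotypes": final.phenotypes.n_phenotypes,
    }
    out.update(extra)
    return out


def _evaluate_all_rounds(log: CampaignLog, transforms, assignments) -> None:
    """Retrospective per-round generalization accuracy.

    The model of round r is scored on every experiment it had not observed,
    using the images eventually collected for those experiments (later rounds
    or the completion sweep), projected through round r's feature transform.
    """
    later_images: dict[tuple[int, int], np.ndarray] = {
        obs.experiment: obs.images for obs in log.completion
    }
    # walk rounds backwards so each round sees all data collected after it
    for rec in reversed(log.rounds):
        if rec.model is not None and rec.index in transforms:
            transform, point_sets = transforms[rec.index]
            observed_at_r = {
                exp: obs
                for earlier in log.rounds[: rec.index + 1]
                for obs in earlier.observations
                if obs.qc_passed
                for exp in [obs.experiment]
            }
            heldout = {
                exp: imgs for exp, imgs in later_images.items()
                if exp not in observed_at_r
            }
            accuracy, extra = _prediction_accuracy(
                rec.model, rec.phenotypes, observed_at_r, heldout, transform,
                log.config,
            )
            rec.metrics["generalization_accuracy"] = accuracy
            rec.metrics.update(extra)
        for obs in rec.observations:
            if obs.qc_passed:
                later_images[obs.experiment] = obs.images


def replay(
    log_path: str | Path, cutoff_override: float | None = None
) -> tuple[CampaignLog, bool]:
    """Recompute a campaign's derived artifacts from its persisted log.

    Re-runs the campaign under the stored config and seed and verifies that
    the recomputed metrics match the stored ones exactly.  With
    ``cutoff_override`` the clustering cutoff is replaced and the result is
    returned as a derived run (no integrity comparison of phenotypes).

    Returns ``(log, is_derived_run)``.
    """
    path = Path(log_path)
    cfg_file = path / "config.json"
    if not cfg_file.exists():
        raise IntegrityError(f"no config.json in {path}")
    config = CampaignConfig.from_dict(json.loads(cfg_file.read_text()))
    for required in ("observations.csv", "metrics.csv", "final_metrics.json"):
        if not (path / required).exists():
            raise IntegrityError(f"log is missing {required}")
    stored_metrics = pd.read_csv(path / "metrics.csv")
    expected_rounds = config.n_rounds + 1
    if len(stored_metrics) != expected_rounds:
        present = set(stored_metrics["round"])
        missing = sorted(set(range(expected_rounds)) - present)
        raise IntegrityError(f"log is truncated: missing rounds {missing}")

    if cutoff_override is not None:
        derived = _replay_with_cutoff(config, cutoff_override)
        return derived, True

    log = run_campaign(config)
    recomputed = log.metrics_frame()
    stored = pd.read_csv(path / "metrics.csv")
    if not _frames_equal(recomputed, stored):
        raise IntegrityError("recomputed metrics differ from stored metrics")
    return log, False


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        av, bv = a[col].tolist(), b[col].tolist()
        if [str(x) for x in av] != [str(x) for x in bv]:
            # CSV round-trips floats; compare parsed values instead of strings
            try:
                if not np.allclose(
                    pd.to_numeric(a[col], errors="coerce"),
                    pd.to_numeric(b[col], errors="coerce"),
                    rtol=0, atol=0, equal_nan=True,
                ):
                    return False
            except (TypeError, ValueError):
                return False
    return True


def _replay_with_cutoff(config: CampaignConfig, cutoff: float) -> CampaignLog:
    """Re-run the campaign forcing a fixed clustering cutoff (derived run)."""
    original = _pc.determine_cutoff

    def forced(*args, **kwargs):
        return cutoff

    _pc.determine_cutoff = forced
    try:
        return run_campaign(config)
    finally:
        _pc.determine_cutoff = original
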