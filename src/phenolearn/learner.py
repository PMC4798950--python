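"""Target-/Condition-type model building and diversity-maximizing batch selection.

The learner sees only opaque target and condition ids plus per-round phenotype
labels — never the hidden duplication or any ground truth.  Its inductive bias
is that there are fewer distinct Target-types than targets and fewer
Condition-types than conditions:

* a **Target-type** is a set of targets that share the same measured phenotype
  for every condition any two of them were both measured in;
* a **Condition-type** is a set of conditions between which no Target-type has
  differing phenotype predictions.

Target-types are built by greedy pairwise merging, collapsing the pair with
the greatest number of shared observed conditions first.  Condition-types are
then minimized subject to the consistency constraint: an exact branch-and-
bound search finds the smallest number of Condition-types when the condition
count is at most ``exact_condition_cap``; above the cap a greedy
largest-overlap merge (followed by opportunistic compression of types with
disjoint prediction domains) is used instead, and the solver mode is recorded
on the model.

Batch selection prioritizes experiments whose (Target-type, Condition-type)
cell has no prediction; within each selection pass at most one experiment per
cell is chosen, and when every cell has contributed one experiment the
removed ones are returned to consideration and a new pass begins.  A batch
therefore maximizes the diversity of type pairs it probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .simspace import ExperimentSpace

__all__ = ["TypeModel", "build_model", "predict", "select_batch", "initial_round"]

logger = logging.getLogger(__name__)

Experiment = tuple[int, int]  # (visible target id, visible condition id)


@dataclass
class TypeModel:
    """Partitions of targets and conditions with a type-pair prediction table.

    ``table[(i, j)]`` holds the phenotype label predicted for any experiment
    whose target lies in ``target_types[i]`` and condition in
    ``condition_types[j]``, or ``None`` ("unknown") if no member pair has been
    observed.
    """

    target_types: list[list[int]]
    condition_types: list[list[int]]
    table: dict[tuple[int, int], int | None]
    round_index: int = 0
    condition_solver: str = "exact"
    target_type_of: dict[int, int] = field(default_factory=dict)
    condition_type_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.target_type_of:
            self.target_type_of = {
                t: i for i, tt in enumerate(self.target_types) for t in tt
            }
        if not self.condition_type_of:
            self.condition_type_of = {
                c: j for j, ct in enumerate(self.condition_types) for c in ct
            }

    def cell_of(self, target: int, condition: int) -> tuple[int, int]:
        try:
            return self.target_type_of[target], self.condition_type_of[condition]
        except KeyError as exc:
            raise LookupError(f"unknown id: {exc}") from exc


def _merge_obs(
    a: dict[int, int], b: dict[int, int]
) -> dict[int, int] | None:
    """Union of two condition->phenotype maps, or None if they conflict."""
    for c, p in b.items():
        if a.get(c, p) != p:
            return None
    merged = dict(a)
    merged.update(b)
    return merged


def _greedy_partition(
    obs: dict[Hashable, dict[int, int]], rng: np.random.Generator
) -> list[list[Hashable]]:
    """Greedy largest-overlap consistent merging of singleton types.

    Pairs sharing the greatest number of observed conditions (with equal
    labels on all of them) are collapsed first; once no pair shares evidence,
    remaining mutually consistent pairs — including disjoint ones, which are
    vacuously consistent — are opportunistically compressed.
    """
    types: list[list[Hashable]] = [[k] for k in sorted(obs, key=repr)]
    type_obs: list[dict[int, int]] = [dict(obs[t[0]]) for t in types]
    while len(types) > 1:
        best_overlap = -1
        candidates: list[tuple[int, int]] = []
        for i in range(len(types)):
            oi = type_obs[i]
            for j in range(i + 1, len(types)):
                shared = oi.keys() & type_obs[j].keys()
                if len(shared) < best_overlap:
                    continue
                if any(oi[c] != type_obs[j][c] for c in shared):
                    continue
                if len(shared) > best_overlap:
                    best_overlap = len(shared)
                    candidates = [(i, j)]
                else:
                    candidates.append((i, j))
        if not candidates:
            return types
        i, j = candidates[rng.integers(len(candidates))]
        types[i] = types[i] + types.pop(j)
        type_obs[i] = _merge_obs(type_obs[i], type_obs.pop(j))
    return types


def _compatible_matrix(preds: list[dict[int, int]], items: list[int]) -> np.ndarray:
    """Pairwise condition compatibility: no key (target-type) with differing values."""
    n = len(items)
    ok = np.ones((n, n), dtype=bool)
    for a in range(n):
        pa = preds[a]
        for b in range(a + 1, n):
            pb = preds[b]
            shared = pa.keys() & pb.keys()
            good = all(pa[k] == pb[k] for k in shared)
            ok[a, b] = ok[b, a] = good
    return ok


def _exact_min_partition(items: list[int], ok: np.ndarray) -> list[list[int]]:
    """Smallest partition into mutually compatible groups, by branch and bound.

    Pairwise compatibility implies joint consistency here (a group is
    consistent iff every pair in it is), so this is a minimum clique cover of
    the compatibility graph.  Items are assigned in order of decreasing
    conflict degree; a partial assignment is pruned once it uses at least as
    many groups as the incumbent.
    """
    n = len(items)
    order = sorted(range(n), key=lambda i: (-int((~ok[i]).sum()), i))
    best: list[list[int]] = [[i] for i in order]  # singletons always feasible

    groups: list[list[int]] = []

    def walk(pos: int) -> None:
        nonlocal best
        if len(groups) >= len(best):
            return
        if pos == n:
            best = [list(g) for g in groups]
            return
        i = order[pos]
        for g in groups:
            if all(ok[i, j] for j in g):
                g.append(i)
                walk(pos + 1)
                g.pop()
        groups.append([i])
        walk(pos + 1)
        groups.pop()

    walk(0)
    return [[items[i] for i in g] for g in best]


def _greedy_condition_partition(
    items: list[int],
    preds: list[dict[int, int]],
    ok: np.ndarray,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Greedy largest-overlap merging, then compression of disjoint types."""
    groups = [[i] for i in range(len(items))]
    gpreds = [dict(preds[i]) for i in range(len(items))]

    def group_ok(a: int, b: int) -> bool:
        return all(ok[i, j] for i in groups[a] for j in groups[b])

    while True:
        best_overlap = 1
        cands: list[tuple[int, int]] = []
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                shared = gpreds[a].keys() & gpreds[b].keys()
                if len(shared) < best_overlap or not group_ok(a, b):
                    continue
                if len(shared) > best_overlap:
                    best_overlap = len(shared)
                    cands = [(a, b)]
                else:
                    cands.append((a, b))
        if not cands:
            break
        a, b = cands[rng.integers(len(cands))]
        groups[a] += groups.pop(b)
        gpreds[a].update(gpreds.pop(b))
    # opportunistic compression: merge types whose prediction domains are disjoint
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if not (gpreds[a].keys() & gpreds[b].keys()) and group_ok(a, b):
                    logger.debug(
                        "compressing disjoint condition-types %s and %s",
                        groups[a],
                        groups[b],
                    )
                    groups[a] += groups.pop(b)
                    gpreds[a].update(gpreds.pop(b))
                    changed = True
                    break
            if changed:
                break
    return [[items[i] for i in g] for g in groups]


def build_model(
    phenotypes: Mapping[Experiment, int] | Iterable[tuple[int, int, int]],
    targets: Sequence[int],
    conditions: Sequence[int],
    seed: int | np.random.Generator | None = None,
    exact_condition_cap: int = 20,
    round_index: int = 0,
) -> TypeModel:
    """Build the Target-/Condition-type model from observed phenotype labels.

    ``phenotypes`` maps observed (target, condition) experiments to phenotype
    labels (or is an iterable of ``(target, condition, label)`` records; a
    repeated experiment with two different labels is a contradiction and
    raises).  ``targets``/``conditions`` are all visible ids, observed or not;
    ids without observations remain singleton types with no predictions.
    """
    rng = np.random.default_rng(seed)
    if isinstance(phenotypes, Mapping):
        records = [(t, c, p) for (t, c), p in phenotypes.items()]
    else:
        records = [tuple(r) for r in phenotypes]
    labels: dict[Experiment, int] = {}
    for t, c, p in records:
        if labels.setdefault((t, c), p) != p:
            raise ValueError(f"contradictory labels for experiment {(t, c)}")

    condition_set = set(conditions)
    obs_by_target: dict[int, dict[int, int]] = {t: {} for t in targets}
    for (t, c), p in labels.items():
        if t not in obs_by_target:
            raise LookupError(f"unknown target id {t}")
        if c not in condition_set:
            raise LookupError(f"unknown condition id {c}")
        obs_by_target[t][c] = p

    target_types = _greedy_partition(obs_by_target, rng)
    target_types = [sorted(tt) for tt in target_types]

    # per target-type condition->phenotype observations
    tt_obs: list[dict[int, int]] = []
    for tt in target_types:
        merged: dict[int, int] = {}
        for t in tt:
            merged = _merge_obs(merged, obs_by_target[t])
            assert merged is not None, "inconsistent target-type"
        tt_obs.append(merged)

    # per condition: target-type -> predicted phenotype
    cond_list = sorted(conditions)
    cond_preds: list[dict[int, int]] = []
    for c in cond_list:
        cond_preds.append(
            {i: o[c] for i, o in enumerate(tt_obs) if c in o}
        )
    ok = _compatible_matrix(cond_preds, cond_list)
    if len(cond_list) <= exact_condition_cap:
        condition_types = _exact_min_partition(cond_list, ok)
        solver = "exact"
    else:
        condition_types = _greedy_condition_partition(cond_list, cond_preds, ok, rng)
        solver = "greedy"
    condition_types = [sorted(ct) for ct in condition_types]
    logger.debug("condition-type solver: %s (%d types)", solver, len(condition_types))

    table: dict[tuple[int, int], int | None] = {}
    for i, tt in enumerate(target_types):
        for j, ct in enumerate(condition_types):
            seen = {labels[(t, c)] for t in tt for c in ct if (t, c) in labels}
            if len(seen) > 1:
                raise AssertionError(
                    f"type pair ({i},{j}) has conflicting observations {seen}"
                )
            table[(i, j)] = seen.pop() if seen else None

    return TypeModel(
        target_types=target_types,
        condition_types=condition_types,
        table=table,
        round_index=round_index,
        condition_solver=solver,
    )


def predict(model: TypeModel, target: int, condition: int) -> int | None:
    """Phenotype label predicted for (target, condition), or None ("unknown")."""
    return model.table[model.cell_of(target, condition)]


def select_batch(
    model: TypeModel,
    observed: set[Experiment],
    all_experiments: Iterable[Experiment],
    batch_size: int,
    seed: int | np.random.Generator | None = None,
    return_passes: bool = False,
) -> list[Experiment] | tuple[list[Experiment], list[int]]:
    """Choose the next batch of unobserved experiments, maximizing type diversity.

    Repeatedly a random high-priority experiment is chosen — an experiment in
    a type-pair cell with no prediction outranks one in a predicted cell —
    and every other unobserved experiment in the same Target-type and
    Condition-type is temporarily removed from consideration.  When the
    remaining set is exhausted, the removed experiments are returned and a
    new pass begins.  Fewer than ``batch_size`` experiments are returned only
    if fewer remain unobserved.

    With ``return_passes=True`` also returns, per chosen experiment, the
    index of the selection pass it was chosen in.
    """
    rng = np.random.default_rng(seed)
    unobserved = [e for e in all_experiments if e not in observed]
    cells = {e: model.cell_of(*e) for e in unobserved}
    unknown_cell = {cell for cell, p in model.table.items() if p is None}

    batch: list[Experiment] = []
    passes: list[int] = []
    available = set(unobserved)
    removed: set[Experiment] = set()
    pass_index = 0
    while len(batch) < batch_size and (available or removed):
        if not available:
            available, removed = removed, set()
            pass_index += 1
        priority = [e for e in available if cells[e] in unknown_cell]
        pool = sorted(priority if priority else available)
        e = pool[rng.integers(len(pool))]
        batch.append(e)
        passes.append(pass_index)
        same_cell = {x for x in available if cells[x] == cells[e]}
        available -= same_cell
        removed |= same_cell - {e}
    if return_passes:
        return batch, passes
    return batch


def initial_round(space: ExperimentSpace) -> list[Experiment]:
    """The bootstrap batch: every visible target at one vehicle condition."""
    if not space.vehicle_condition_ids:
        raise ValueError("no vehicle condition designated")
    vc = min(space.vehicle_condition_ids)
    return [(t, vc) for t in space.visible_targets]
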