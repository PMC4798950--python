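"""Type-model building, prediction lookup, and diversity-maximizing selection."""

import itertools

import numpy as np
import pytest

from phenolearn.learner import (
    build_model,
    initial_round,
    predict,
    select_batch,
)
from phenolearn.simspace import make_ground_truth


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def target_consistent(group, obs):
    for c in set().union(*(obs[t].keys() for t in group)):
        if len({obs[t][c] for t in group if c in obs[t]}) > 1:
            return False
    return True


def minimal_consistent_size(obs):
    return min(
        len(p)
        for p in all_partitions(sorted(obs))
        if all(target_consistent(g, obs) for g in p)
    )


class TestBuildModel:
    def test_agreeing_targets_merge_conflicting_stays_apart(self):
        ph = {(1, c): c for c in range(3)}
        ph.update({(2, c): c for c in range(3)})
        ph.update({(3, 0): 0, (3, 1): 9})
        model = build_model(ph, targets=[1, 2, 3], conditions=[0, 1, 2, 3], seed=0)
        assert sorted(map(sorted, model.target_types)) == [[1, 2], [3]]

    def test_single_shared_condition_groups_all_targets(self):
        ph = {(t, 0): 5 for t in range(4)}
        model = build_model(ph, targets=range(4), conditions=range(3), seed=0)
        assert len(model.target_types) == 1

    def test_vehicle_only_round_predicts_no_change_everywhere(self):
        # only the vehicle column observed: the minimal condition partition
        # puts every drug with the vehicle, predicting unperturbed phenotypes
        ph = {(t, 0): (0 if t < 2 else 1) for t in range(4)}
        model = build_model(ph, targets=range(4), conditions=range(5), seed=0)
        assert len(model.condition_types) == 1
        for t in range(4):
            for c in range(5):
                assert predict(model, t, c) == (0 if t < 2 else 1)

    def test_contradictory_labels_raise(self):
        with pytest.raises(ValueError, match="contradictory"):
            build_model([(0, 0, 1), (0, 0, 2)], targets=[0], conditions=[0])

    def test_rebuild_is_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        ph = {
            (t, c): int(rng.integers(3))
            for t in range(6)
            for c in rng.choice(6, size=3, replace=False)
        }
        m1 = build_model(ph, targets=range(6), conditions=range(6), seed=7)
        m2 = build_model(ph, targets=range(6), conditions=range(6), seed=7)
        assert m1.target_types == m2.target_types
        assert m1.condition_types == m2.condition_types
        assert m1.table == m2.table

    def test_model_consistency_invariants_exhaustive_small_spaces(self):
        rng = np.random.default_rng(1)
        for trial in range(30):
            nt, nc = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            obs = {
                t: {
                    int(c): int(rng.integers(3))
                    for c in rng.choice(nc, size=int(rng.integers(1, nc + 1)),
                                        replace=False)
                }
                for t in range(nt)
            }
            ph = {(t, c): p for t, o in obs.items() for c, p in o.items()}
            model = build_model(ph, targets=range(nt), conditions=range(nc),
                                seed=trial)
            # partitions cover ids disjointly
            flat_t = sorted(t for tt in model.target_types for t in tt)
            assert flat_t == list(range(nt))
            flat_c = sorted(c for ct in model.condition_types for c in ct)
            assert flat_c == list(range(nc))
            # no target-type holds two targets conflicting on a shared condition
            for tt in model.target_types:
                assert target_consistent(tt, obs)
            # every observation is consistent with the table
            for (t, c), p in ph.items():
                assert predict(model, t, c) == p

    def test_greedy_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(2)
        for trial in range(40):
            nt, nc = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            obs = {
                t: {
                    int(c): int(rng.integers(3))
                    for c in rng.choice(nc, size=int(rng.integers(1, nc + 1)),
                                        replace=False)
                }
                for t in range(nt)
            }
            ph = {(t, c): p for t, o in obs.items() for c, p in o.items()}
            model = build_model(ph, targets=range(nt), conditions=range(nc),
                                seed=trial)
            assert len(model.target_types) == minimal_consistent_size(obs)


class TestPredict:
    @pytest.fixture
    def model(self):
        ph = {(0, 0): 1, (1, 0): 1, (0, 1): 2}
        return build_model(ph, targets=[0, 1], conditions=[0, 1, 2], seed=0)

    def test_observed_experiment_returns_its_label(self, model):
        assert predict(model, 0, 0) == 1
        assert predict(model, 0, 1) == 2

    def test_type_mate_inherits_observation(self, model):
        assert predict(model, 1, 1) == 2  # via shared target-type

    def test_unknown_id_raises(self, model):
        with pytest.raises(LookupError):
            predict(model, 99, 0)


class TestSelectBatch:
    def test_single_cell_model_replenishes_each_pick(self):
        ph = {(t, 0): 0 for t in range(3)}
        model = build_model(ph, targets=range(3), conditions=range(3), seed=0)
        assert len(model.target_types) == 1 and len(model.condition_types) == 1
        all_exps = [(t, c) for t in range(3) for c in range(3)]
        batch, passes = select_batch(
            model, set(ph), all_exps, batch_size=5, seed=0, return_passes=True
        )
        assert len(batch) == 5
        assert passes == [0, 1, 2, 3, 4]  # one pick per pass, forced replenishment

    def test_all_observed_returns_empty_batch(self):
        ph = {(t, c): 0 for t in range(2) for c in range(2)}
        model = build_model(ph, targets=range(2), conditions=range(2), seed=0)
        assert select_batch(model, set(ph), list(ph), 4, seed=0) == []

    def test_no_duplicates_and_only_unobserved(self):
        ph = {(t, 0): t % 2 for t in range(4)}
        model = build_model(ph, targets=range(4), conditions=range(4), seed=0)
        all_exps = [(t, c) for t in range(4) for c in range(4)]
        batch = select_batch(model, set(ph), all_exps, 10, seed=1)
        assert len(batch) == len(set(batch)) == 10
        assert not set(batch) & set(ph)

    def test_within_pass_cells_are_distinct(self):
        rng = np.random.default_rng(3)
        ph = {
            (t, c): int(rng.integers(2))
            for t in range(6)
            for c in rng.choice(6, size=2, replace=False)
        }
        model = build_model(ph, targets=range(6), conditions=range(6), seed=0)
        all_exps = [(t, c) for t in range(6) for c in range(6)]
        batch, passes = select_batch(
            model, set(ph), all_exps, 20, seed=2, return_passes=True
        )
        for p in set(passes):
            cells = [model.cell_of(*e) for e, q in zip(batch, passes) if q == p]
            assert len(cells) == len(set(cells))

    def test_unknown_cells_prioritized_within_pass(self):
        # two target-types x two condition-types; exactly one cell observed
        ph = {(0, 0): 0, (1, 0): 1}
        model = build_model(ph, targets=[0, 1], conditions=[0, 1], seed=0)
        all_exps = [(t, c) for t in (0, 1) for c in (0, 1)]
        unknown_cells = {cell for cell, p in model.table.items() if p is None}
        if unknown_cells:
            batch = select_batch(model, set(ph), all_exps, 1, seed=0)
            assert model.cell_of(*batch[0]) in unknown_cells


class TestInitialRound:
    def test_one_experiment_per_target_at_one_vehicle(self, small_space):
        space, _ = small_space
        batch = initial_round(space)
        assert len(batch) == len(space.visible_targets)
        conditions = {c for _, c in batch}
        assert len(conditions) == 1
        assert conditions <= space.vehicle_condition_ids

    def test_paper_scale_initial_round_has_96_experiments(self):
        space, _ = make_ground_truth(48, 48, 8, 8, 12, feature_dim=4, seed=9)
        assert len(initial_round(space)) == 96

    def test_duplicated_vehicle_ids_only_one_used(self, small_space):
        space, _ = small_space
        assert len(space.vehicle_condition_ids) >= 2  # duplicated vehicle
        batch = initial_round(space)
        assert len({c for _, c in batch}) == 1

    def test_missing_vehicle_raises(self, small_space):
        space, _ = small_space
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(space, vehicle_condition_ids=frozenset())
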