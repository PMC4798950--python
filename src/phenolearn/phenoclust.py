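"""Phenotype determination by set-based agglomerative clustering.

Each experiment is a *set* of image feature vectors.  Pairs of sets are
compared with an intermingling score derived from a leave-one-out 1-nearest-
neighbor classifier: balanced samples of equal size are drawn from the two
sets, the pooled sample is classified LOO by its nearest Euclidean neighbor,
and the accuracy ``acc`` is mapped to ``score = clamp(2 * (1 - acc), 0, 1)``.
Chance-level accuracy (0.5, totally intermingled sets) gives score 1; perfect
separability gives score 0.  The score is averaged over several independent
draws with at most ``max_points`` points per set per draw.

Experiments are merged greedily: the pair of nodes with the greatest score is
merged (ties broken at random), the new node holding the union of its
children's points; scores of untouched pairs are unaffected.  The cluster
cutoff is calibrated by data splitting: each experiment's images are split
randomly into two halves treated as separate leaves, and the cutoff is the
average (over splittings) of the merge score at the finest tree level where at
least 90% of the split halves have rejoined — i.e. experiments at least as
similar as within-experiment variation end up coclustered.  Pruning the tree
at the cutoff yields the phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterNode",
    "PhenotypeAssignment",
    "intermingling_score",
    "build_cluster_tree",
    "iter_merges",
    "merge_history",
    "determine_cutoff",
    "assign_phenotypes",
]


def _loo_nn_accuracy_batched(P: np.ndarray) -> np.ndarray:
    """Leave-one-out 1-NN accuracy per draw for a stack of pooled samples.

    P has shape (n_draws, 2k, d) with the first k points of each draw from set
    A and the rest from set B.  Returns per-draw accuracies.
    """
    n_draws, m, _ = P.shape
    k = m // 2
    sq = np.einsum("dij,dij->di", P, P)
    D = sq[:, :, None] + sq[:, None, :] - 2.0 * np.einsum("dik,djk->dij", P, P)
    idx = np.arange(m)
    D[:, idx, idx] = np.inf
    nn = D.argmin(axis=2)
    labels = np.repeat([0, 1], k)
    return (labels[nn] == labels[None, :]).mean(axis=1)


def _loo_nn_accuracy_single(P: np.ndarray, k: int) -> float:
    D = cdist(P, P, "sqeuclidean")
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(axis=1)
    labels = np.repeat([0, 1], k)
    return float((labels[nn] == labels).mean())


def _draw_indices(
    rng: np.random.Generator, n: int, k: int, n_draws: int
) -> np.ndarray:
    """n_draws independent samples of k indices from range(n), no replacement."""
    if k == n:
        return np.tile(np.arange(n), (n_draws, 1))
    rows = np.tile(np.arange(n), (n_draws, 1))
    return rng.permuted(rows, axis=1)[:, :k]


def intermingling_score(
    A: np.ndarray,
    B: np.ndarray,
    n_draws: int = 5,
    max_points: int = 500,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sample intermingling score in [0, 1] between point sets A and B.

    1 means totally intermingled (a 1-NN classifier does no better than
    chance), 0 means totally dissimilar (perfectly separable).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both point sets must be nonempty")
    rng = np.random.default_rng(seed)
    k = min(max_points, len(A), len(B))
    # k never exceeds either set size, so balanced draws can be taken without
    # replacement; this keeps the score's anchors exact (duplicate samples at
    # distance zero would otherwise bias LOO 1-NN accuracy toward their own set)
    ia = _draw_indices(rng, len(A), k, n_draws)
    ib = _draw_indices(rng, len(B), k, n_draws)
    if n_draws * (2 * k) ** 2 <= 4_000_000:
        P = np.concatenate([A[ia], B[ib]], axis=1)
        accs = _loo_nn_accuracy_batched(P)
    else:
        accs = np.array(
            [
                _loo_nn_accuracy_single(np.concatenate([A[ia[d]], B[ib[d]]]), k)
                for d in range(n_draws)
            ]
        )
    scores = np.clip(2.0 * (1.0 - accs), 0.0, 1.0)
    return float(scores.mean())


@dataclass(eq=False)
class ClusterNode:
    """Node of the merge tree; internal nodes pool their children's points."""

    members: frozenset
    points: np.ndarray
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    merge_score: float | None = None
    order: int = -1  # merge sequence number; -1 for leaves

    @property
    def is_leaf(self) -> bool:
        return self.children is None


def build_cluster_tree(
    observations: Mapping[Hashable, np.ndarray],
    n_draws: int = 5,
    max_points: int = 500,
    seed: int | np.random.Generator | None = None,
) -> ClusterNode:
    """Greedy set-based agglomeration of experiments into a binary merge tree.

    ``observations`` maps experiment ids to (n_images, d) arrays.  Leaves are
    experiments; at each step the pair of live nodes with the greatest
    intermingling score is merged (ties broken uniformly at random under the
    seed).  Only scores involving the newly formed node are recomputed.
    """
    if not observations:
        raise ValueError("need at least one observation")
    rng = np.random.default_rng(seed)
    nodes: dict[int, ClusterNode] = {}
    for nid, key in enumerate(sorted(observations, key=repr)):
        pts = np.atleast_2d(np.asarray(observations[key], dtype=float))
        if len(pts) == 0:
            raise ValueError(f"experiment {key!r} has no images")
        nodes[nid] = ClusterNode(members=frozenset([key]), points=pts)

    scores: dict[tuple[int, int], float] = {}
    ids = sorted(nodes)
    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1 :]:
            scores[(i, j)] = intermingling_score(
                nodes[i].points, nodes[j].points, n_draws, max_points, rng
            )

    next_id = len(nodes)
    order = 0
    while len(nodes) > 1:
        best = max(scores.values())
        candidates = [p for p, s in scores.items() if s == best]
        i, j = candidates[rng.integers(len(candidates))]
        a, b = nodes.pop(i), nodes.pop(j)
        merged = ClusterNode(
            members=a.members | b.members,
            points=np.concatenate([a.points, b.points]),
            children=(a, b),
            merge_score=best,
            order=order,
        )
        order += 1
        scores = {
            p: s for p, s in scores.items() if i not in p and j not in p
        }
        for other_id, other in nodes.items():
            scores[(other_id, next_id)] = intermingling_score(
                other.points, merged.points, n_draws, max_points, rng
            )
        nodes[next_id] = merged
        next_id += 1
    return next(iter(nodes.values()))


def iter_merges(root: ClusterNode) -> list[ClusterNode]:
    """Internal nodes of the tree in merge (formation) order."""
    out = []
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.append(node)
            stack.extend(node.children)
    return sorted(out, key=lambda n: n.order)


def merge_history(root: ClusterNode) -> list[dict]:
    """JSON-serializable audit trail of the merges, in formation order."""
    out = []
    for node in iter_merges(root):
        la, lb = node.children
        out.append(
            {
                "order": node.order,
                "score": node.merge_score,
                "members_a": sorted(map(repr, la.members)),
                "members_b": sorted(map(repr, lb.members)),
            }
        )
    return out


def determine_cutoff(
    observations: Mapping[Hashable, np.ndarray],
    n_splits: int = 5,
    cocluster_frac: float = 0.90,
    n_draws: int = 5,
    max_points: int = 500,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Data-splitting calibration of the cluster cutoff score.

    For each of ``n_splits`` splittings, every experiment's images are divided
    equally, randomly and disjointly into two leaves and a merge tree is built
    on the doubled leaves.  Walking levels from most to fewest clusters, the
    first level at which at least ``cocluster_frac`` of the experiments have
    both halves in one cluster is found, and that level's score recorded.
    Because greedy merge scores are not globally monotone, the score that
    characterizes a level is the threshold that reproduces it under pruning:
    the minimum merge score over all merges up to and including the one that
    formed the level.  The returned cutoff is the mean over splittings.

    Experiments with fewer than 2 images cannot be split and are excluded
    with a warning.  If the criterion is met before any merge (only possible
    when ``cocluster_frac <= 0``), the recorded score is 1.0, the maximum —
    the cutoff sits at the all-leaves level.
    """
    rng = np.random.default_rng(seed)
    eligible = {}
    for key, pts in observations.items():
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if len(pts) < 2:
            warnings.warn(
                f"experiment {key!r} has < 2 images; excluded from cutoff splitting",
                stacklevel=2,
            )
        else:
            eligible[key] = pts
    if not eligible:
        raise ValueError("no experiment has enough images to split")

    level_scores = []
    for _ in range(n_splits):
        leaves: dict[tuple, np.ndarray] = {}
        for key, pts in eligible.items():
            perm = rng.permutation(len(pts))
            half = len(pts) // 2
            leaves[(key, 0)] = pts[perm[:half]]
            leaves[(key, 1)] = pts[perm[half:]]
        n_exp = len(eligible)
        needed = cocluster_frac * n_exp
        if needed <= 0:
            level_scores.append(1.0)
            continue
        root = build_cluster_tree(leaves, n_draws, max_points, rng)
        joined = 0
        level_score = None
        for node in iter_merges(root):
            level_score = (
                node.merge_score
                if level_score is None
                else min(level_score, node.merge_score)
            )
            la, lb = node.children
            keys_a = {k for k, _ in la.members}
            keys_b = {k for k, _ in lb.members}
            joined += len(keys_a & keys_b)
            if joined >= needed:
                break
        level_scores.append(float(level_score))
    return float(np.mean(level_scores))


@dataclass
class PhenotypeAssignment:
    """Per-round mapping from experiment ids to contiguous phenotype labels."""

    labels: dict[Hashable, int]
    cutoff_score: float
    round_index: int = 0

    @property
    def n_phenotypes(self) -> int:
        return len(set(self.labels.values())) if self.labels else 0


def assign_phenotypes(
    root: ClusterNode, cutoff_score: float, round_index: int = 0
) -> PhenotypeAssignment:
    """Prune the merge tree at the cutoff and label the resulting clusters.

    Merges with score below the cutoff are cut (only merges at least as
    intermingled as within-experiment variation are kept).  Each kept merge
    joined two clusters wholly, so it connects every experiment under its two
    subtrees; the connected components of experiments under the kept merges
    become the phenotypes.  Because merge scores are not globally monotone
    along the greedy merge order, a noisy low-scoring merge deep in the tree
    does not fragment a cluster whose higher merges are kept.  Labels are
    renumbered by decreasing cluster size, ties by first-seen (smallest leaf
    order in the tree traversal).
    """
    # collect leaves in deterministic traversal order
    leaf_order: dict[Hashable, int] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            for key in node.members:
                leaf_order.setdefault(key, len(leaf_order))
        else:
            stack.extend(reversed(node.children))

    parent = {key: key for key in leaf_order}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for node in iter_merges(root):
        if node.merge_score is not None and node.merge_score >= cutoff_score:
            members = list(node.members)
            first = find(members[0])
            for other in members[1:]:
                r = find(other)
                if r != first:
                    parent[r] = first

    clusters: dict[Hashable, list] = {}
    for key in leaf_order:
        clusters.setdefault(find(key), []).append(key)
    clusters = {i: ms for i, ms in enumerate(clusters.values())}
    ordered = sorted(
        clusters.values(),
        key=lambda ms: (-len(ms), min(leaf_order[k] for k in ms)),
    )
    labels = {key: lab for lab, members in enumerate(ordered) for key in members}
    return PhenotypeAssignment(
        labels=labels, cutoff_score=cutoff_score, round_index=round_index
    )
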