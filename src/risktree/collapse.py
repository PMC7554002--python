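"""Collapse of terminal nodes into an ordinal 0-6 risk scale.

Terminal-node mean risks are clustered in one dimension, weighted by node
size, into at most seven groups maximizing between-group separation
(equivalently minimizing weighted within-cluster sum of squares).  Optimal
1-D clusters are contiguous in value, so the exact optimum is found by
dynamic programming — deterministic, with no seed dependence, unlike Lloyd
iteration.

A split is "over-branched" when both of its terminal children land in the
same collapsed group: the split adds tree complexity without changing the
scale.  Finalization iterates cluster -> flag -> prune (deepest flag first)
-> re-cluster until no over-branching remains, yielding a parsimonious
algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .items import ValidationError
from .tree import RiskTree, subtree_prune


@dataclass
class KMeans1DResult:
    """Exact weighted 1-D clustering: per-input labels in ascending-mean order."""

    labels: np.ndarray
    centers: np.ndarray  # weighted mean per cluster, strictly increasing
    wcss: float
    k_effective: int


def weighted_kmeans_1d(
    values: Sequence[float], weights: Sequence[float], k: int
) -> KMeans1DResult:
    """Optimal weighted k-means in one dimension by dynamic programming.

    Clusters are contiguous on the sorted distinct values (a property of the
    1-D optimum), labelled 0..k_eff-1 in ascending weighted-mean order.  If
    ``k`` exceeds the number of distinct values the result has one cluster
    per distinct value (with a warning) — WCSS 0.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.ndim != 1 or values.shape != weights.shape or len(values) == 0:
        raise ValidationError("values and weights must be equal-length non-empty 1-D")
    if np.any(weights <= 0):
        raise ValidationError("weights must be positive")
    if k < 1:
        raise ValidationError("k must be >= 1")

    # aggregate duplicates so cluster boundaries fall between distinct values
    distinct, inverse = np.unique(values, return_inverse=True)
    agg_w = np.zeros(len(distinct))
    np.add.at(agg_w, inverse, weights)
    m = len(distinct)
    if k > m:
        warnings.warn(
            f"k={k} exceeds {m} distinct values; returning {m} singleton clusters",
            stacklevel=2,
        )
    k_eff = min(k, m)

    # prefix sums for O(1) interval cost: weighted SSE of distinct[a..b]
    pw = np.concatenate([[0.0], np.cumsum(agg_w)])
    pwx = np.concatenate([[0.0], np.cumsum(agg_w * distinct)])
    pwx2 = np.concatenate([[0.0], np.cumsum(agg_w * distinct**2)])

    def cost(a: int, b: int) -> float:  # inclusive indices
        if a == b:
            return 0.0  # singleton: exactly zero, no cancellation residue
        w = pw[b + 1] - pw[a]
        sx = pwx[b + 1] - pwx[a]
        sx2 = pwx2[b + 1] - pwx2[a]
        return max(sx2 - sx * sx / w, 0.0)

    INF = float("inf")
    # dp[j][i]: min WCSS of distinct[0..i] in j+1 clusters; back[j][i]: start of last cluster
    dp = np.full((k_eff, m), INF)
    back = np.zeros((k_eff, m), dtype=int)
    for i in range(m):
        dp[0][i] = cost(0, i)
    for j in range(1, k_eff):
        for i in range(j, m):
            for a in range(j, i + 1):
                c = dp[j - 1][a - 1] + cost(a, i)
                if c < dp[j][i]:
                    dp[j][i] = c
                    back[j][i] = a
    # backtrack boundaries
    bounds = []
    i = m - 1
    for j in range(k_eff - 1, -1, -1):
        a = back[j][i] if j > 0 else 0
        bounds.append((a, i))
        i = a - 1
    bounds.reverse()

    distinct_label = np.empty(m, dtype=int)
    centers = np.empty(k_eff)
    for label, (a, b) in enumerate(bounds):
        distinct_label[a : b + 1] = label
        centers[label] = (pwx[b + 1] - pwx[a]) / (pw[b + 1] - pw[a])
    labels = distinct_label[inverse]
    return KMeans1DResult(
        labels=labels,
        centers=centers,
        wcss=float(dp[k_eff - 1][m - 1]),
        k_effective=k_eff,
    )


@dataclass
class GroupAssignment:
    """Map terminal node id -> ordinal group label, with group statistics.

    Labels are consecutive from 0 and group weighted mean risks strictly
    increase with label (higher label = higher risk).
    """

    node_to_group: dict[int, int]
    group_mean_risk: np.ndarray
    group_n: np.ndarray

    @property
    def k(self) -> int:
        return len(self.group_mean_risk)

    def check(self) -> None:
        labels = sorted(set(self.node_to_group.values()))
        if labels != list(range(self.k)):
            raise AssertionError("group labels are not consecutive from 0")
        if not np.all(np.diff(self.group_mean_risk) > 0):
            raise AssertionError("group weighted means are not strictly increasing")


def assign_groups(tree: RiskTree, k: int = 7) -> GroupAssignment:
    """Cluster the tree's terminal-node means (weighted by node n) into <= k groups."""
    leaves = sorted(tree.leaves(), key=lambda n: n.node_id)
    means = [leaf.mean_risk for leaf in leaves]
    ns = [leaf.n for leaf in leaves]
    result = weighted_kmeans_1d(means, ns, k)
    node_to_group = {
        leaf.node_id: int(lbl) for leaf, lbl in zip(leaves, result.labels)
    }
    group_n = np.zeros(result.k_effective)
    for leaf, lbl in zip(leaves, result.labels):
        group_n[lbl] += leaf.n
    return GroupAssignment(
        node_to_group=node_to_group,
        group_mean_risk=result.centers,
        group_n=group_n,
    )


def detect_overbranching(tree: RiskTree, assignment: GroupAssignment) -> list[int]:
    """Internal nodes whose two terminal children share a collapsed group."""
    missing = [lid for lid in tree.leaf_ids() if lid not in assignment.node_to_group]
    if missing:
        raise ValidationError(f"assignment does not cover terminal nodes {missing}")
    flagged = []
    for node in tree.internal_nodes():
        left, right = tree.nodes[node.left], tree.nodes[node.right]
        if left.is_leaf and right.is_leaf:
            if assignment.node_to_group[left.node_id] == assignment.node_to_group[right.node_id]:
                flagged.append(node.node_id)
    return sorted(flagged)


def collapse_until_parsimonious(
    tree: RiskTree,
    k: int = 7,
    rerank_hook: Callable[[RiskTree, int], RiskTree | None] | None = None,
    max_iter: int = 100,
) -> tuple[RiskTree, GroupAssignment]:
    """Iterate cluster -> detect over-branching -> prune -> re-cluster.

    Flags are resolved deepest-first (ties: lowest node id).  Before pruning
    a flagged node, ``rerank_hook(tree, node_id)`` may supply a replacement
    tree with an alternative split there; a hook returning None (or no hook)
    means prune.  Terminates because each prune removes one terminal node;
    ``max_iter`` guards against a logic bug in a hook.
    """
    current = tree.copy()
    for _ in range(max_iter):
        assignment = assign_groups(current, k)
        flagged = detect_overbranching(current, assignment)
        if not flagged:
            assignment.check()
            return current, assignment
        target = max(flagged, key=lambda nid: (current.nodes[nid].depth, -nid))
        replacement = rerank_hook(current, target) if rerank_hook is not None else None
        if replacement is not None and replacement.to_dict() != current.to_dict():
            current = replacement
        else:
            current = subtree_prune(current, target)
    raise RuntimeError(
        f"collapse did not reach a parsimonious tree within {max_iter} iterations"
    )
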