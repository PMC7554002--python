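"""Mean-risk regression tree growth over screener items.

The tree predicts the clinician's 0-4 danger-to-self rating.  Splits are
binary on ordinal order ("code <= t" vs "> t"); candidate splits are ranked
by the reduction in the sum of squared deviations of the rating (the
variance-reduction criterion for an interval target — equivalent to the
F-statistic ordering within a node).  Growth is best-first: at each step the
frontier leaf whose best admissible split yields the largest reduction is
split, until a terminal-node budget, depth limit, minimum leaf size or
significance floor stops it.

Analyst-guided tree construction is replayed deterministically via an
override map (node id -> item code) rather than live interaction, so a
derivation run is fully reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .items import ValidationError


class SplitCandidate(NamedTuple):
    """A candidate binary split: send ``item <= threshold`` left."""

    item: str
    threshold: int
    strength: float


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    mean_risk: float
    item: str | None = None
    threshold: int | None = None
    left: int | None = None
    right: int | None = None
    parent: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.item is None

    @property
    def split(self) -> tuple[str, int] | None:
        return None if self.item is None else (self.item, self.threshold)


@dataclass
class RiskTree:
    """Binary regression tree; nodes indexed by id, root id 0.

    Node ids are assigned in creation order during growth, so identical data
    and configuration yield identical ids — overrides and audits key on them.
    """

    nodes: dict[int, TreeNode] = field(default_factory=dict)
    root_id: int = 0

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def leaf_ids(self) -> list[int]:
        return sorted(n.node_id for n in self.nodes.values() if n.is_leaf)

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_leaf)

    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    def copy(self) -> "RiskTree":
        return RiskTree({i: replace(n) for i, n in self.nodes.items()}, self.root_id)

    # -- traversal ---------------------------------------------------------

    def traverse(self, lookup: Callable[[str], int]) -> tuple[int, list[tuple[str, int, str]]]:
        """Route one observation to a leaf.

        ``lookup(item)`` returns the (already policy-resolved) integer value.
        Returns (leaf id, path of (item, value, branch) steps).
        """
        node = self.root
        path: list[tuple[str, int, str]] = []
        while not node.is_leaf:
            value = int(lookup(node.item))
            branch = "left" if value <= node.threshold else "right"
            path.append((node.item, value, branch))
            node = self.nodes[node.left if branch == "left" else node.right]
        return node.node_id, path

    def assign_leaves(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorized leaf assignment: one leaf id per frame row."""
        leaf = np.full(len(frame), -1, dtype=int)
        stack = [(self.root_id, np.ones(len(frame), dtype=bool))]
        while stack:
            node_id, mask = stack.pop()
            node = self.nodes[node_id]
            if node.is_leaf:
                leaf[mask] = node_id
                continue
            go_left = frame[node.item].to_numpy() <= node.threshold
            stack.append((node.left, mask & go_left))
            stack.append((node.right, mask & ~go_left))
        return leaf

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "root_id": self.root_id,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "depth": n.depth,
                    "n": n.n,
                    "mean_risk": n.mean_risk,
                    "item": n.item,
                    "threshold": n.threshold,
                    "left": n.left,
                    "right": n.right,
                    "parent": n.parent,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RiskTree":
        nodes = {
            d["node_id"]: TreeNode(
                node_id=d["node_id"],
                depth=d["depth"],
                n=d["n"],
                mean_risk=d["mean_risk"],
                item=d["item"],
                threshold=d["threshold"],
                left=d["left"],
                right=d["right"],
                parent=d["parent"],
            )
            for d in data["nodes"]
        }
        return cls(nodes, data["root_id"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RiskTree":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class GrowthConfig:
    """Tree-growth controls.

    ``candidates`` lists admissible predictor codes (clinically acceptable
    items; demographic and school items are excluded upstream by the item
    dictionary's admissible flags).  ``min_leaf_size`` defaults to 50: the
    rarest published risk group held ~0.8% of a 60k cohort (~48 records), and
    small cells were an explicit concern during derivation.  ``max_leaves``
    defaults to 20, the size of the selected tree.  ``min_strength`` is the
    significance floor on the SSE reduction; with the optional F-test enabled
    (``alpha``), a split must additionally reach the Bonferroni-adjusted
    p-value across the node's candidate (item, threshold) pairs.
    """

    candidates: tuple[str, ...]
    min_leaf_size: int = 50
    max_leaves: int = 20
    max_depth: int | None = None
    min_strength: float = 0.0
    alpha: float | None = None
    forced_first_split: str | None = None
    overrides: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.min_leaf_size < 1:
            raise ValidationError("min_leaf_size must be >= 1")
        if self.max_leaves < 2:
            raise ValidationError("max_leaves must be >= 2")
        if not self.candidates:
            raise ValidationError("candidates must be non-empty")

    @property
    def override_map(self) -> dict[int, str]:
        return dict(self.overrides)


def rank_splits(
    frame: pd.DataFrame,
    candidates: Sequence[str],
    min_child_size: int,
    outcome: str = "danger",
) -> list[SplitCandidate]:
    """Rank every admissible (item, threshold) split at a node.

    Strength is the reduction in the outcome's sum of squared deviations,
    ``n_l * n_r / n * (mean_l - mean_r)^2``.  Splits leaving a child below
    ``min_child_size`` are excluded.  Ties break on (item code, threshold)
    lexicographically, so the ranking is independent of record order.
    """
    y = frame[outcome].to_numpy(dtype=float)
    n = len(y)
    out: list[SplitCandidate] = []
    for item in candidates:
        x = frame[item].to_numpy()
        max_code = int(x.max(initial=0))
        counts = np.bincount(x, minlength=max_code + 1)
        sums = np.bincount(x, weights=y, minlength=max_code + 1)
        cum_n = np.cumsum(counts)
        cum_s = np.cumsum(sums)
        total_s = cum_s[-1]
        # thresholds t: left = codes <= t, for t in 0..max_code-1
        for t in range(max_code):
            n_l = int(cum_n[t])
            n_r = n - n_l
            if n_l < min_child_size or n_r < min_child_size:
                continue
            mean_l = cum_s[t] / n_l
            mean_r = (total_s - cum_s[t]) / n_r
            strength = (n_l * n_r / n) * (mean_l - mean_r) ** 2
            out.append(SplitCandidate(item, t, float(strength)))
    out.sort(key=lambda c: (-c.strength, c.item, c.threshold))
    return out


def _split_p_value(strength: float, sse_node: float, n: int, n_comparisons: int) -> float:
    """Bonferroni-adjusted F-test p-value for one split at a node."""
    from scipy import stats

    if n <= 2:
        return 1.0
    resid = max(sse_node - strength, 0.0)
    if resid == 0.0:
        return 0.0 if strength > 0 else 1.0
    f = strength / (resid / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return min(1.0, p * max(n_comparisons, 1))


def grow_tree(
    frame: pd.DataFrame,
    config: GrowthConfig,
    outcome: str = "danger",
) -> RiskTree:
    """Grow a mean-risk tree best-first under the growth configuration.

    Raises on an empty record set or an override naming an item outside the
    candidate list.  Growth at a node stops when it is pure, too small, at
    the depth limit, or when its best split falls below the significance
    floor; overall growth stops at ``max_leaves`` terminal nodes.
    """
    if len(frame) == 0:
        raise ValidationError("cannot grow a tree on an empty record set")
    if frame[outcome].isna().any():
        raise ValidationError("all records must carry the outcome rating")
    override_map = config.override_map
    for node_id, item in override_map.items():
        if item not in config.candidates:
            raise ValidationError(
                f"override for node {node_id} names inadmissible item {item!r}"
            )
    if config.forced_first_split is not None and config.forced_first_split not in config.candidates:
        raise ValidationError(
            f"forced first split item {config.forced_first_split!r} is not a candidate"
        )

    y_all = frame[outcome].to_numpy(dtype=float)
    tree = RiskTree()
    tree.nodes[0] = TreeNode(
        node_id=0, depth=0, n=len(frame), mean_risk=float(y_all.mean())
    )
    next_id = 1
    # membership: node_id -> boolean mask over frame rows
    membership: dict[int, np.ndarray] = {0: np.ones(len(frame), dtype=bool)}
    # best admissible split per frontier leaf (None once exhausted)
    best: dict[int, SplitCandidate | None] = {}

    def compute_best(node_id: int) -> SplitCandidate | None:
        node = tree.nodes[node_id]
        if config.max_depth is not None and node.depth >= config.max_depth:
            return None
        if node.n < 2 * config.min_leaf_size:
            return None
        sub = frame.loc[membership[node_id]]
        ranked = rank_splits(sub, config.candidates, config.min_leaf_size, outcome)
        if not ranked:
            return None
        chosen_item: str | None = None
        if node_id == 0 and config.forced_first_split is not None:
            chosen_item = config.forced_first_split
        if node_id in override_map:
            chosen_item = override_map[node_id]
        if chosen_item is not None:
            ranked = [c for c in ranked if c.item == chosen_item]
            if not ranked:
                return None
        top = ranked[0]
        if top.strength <= config.min_strength:
            return None
        if config.alpha is not None:
            yv = sub[outcome].to_numpy(dtype=float)
            sse_node = float(((yv - yv.mean()) ** 2).sum())
            p = _split_p_value(top.strength, sse_node, len(yv), len(ranked))
            if p > config.alpha:
                return None
        return top

    best[0] = compute_best(0)

    while tree.n_leaves() < config.max_leaves:
        frontier = [(nid, c) for nid, c in best.items() if c is not None]
        if not frontier:
            break
        # best-first: largest strength, then lowest node id for determinism
        node_id, cand = min(frontier, key=lambda t: (-t[1].strength, t[0]))
        node = tree.nodes[node_id]
        mask = membership[node_id]
        go_left = (frame[cand.item].to_numpy() <= cand.threshold) & mask
        go_right = mask & ~go_left
        left_id, right_id = next_id, next_id + 1
        next_id += 2
        for child_id, child_mask in ((left_id, go_left), (right_id, go_right)):
            yv = y_all[child_mask]
            tree.nodes[child_id] = TreeNode(
                node_id=child_id,
                depth=node.depth + 1,
                n=int(child_mask.sum()),
                mean_risk=float(yv.mean()),
                parent=node_id,
            )
            membership[child_id] = child_mask
        node.item, node.threshold = cand.item, cand.threshold
        node.left, node.right = left_id, right_id
        del best[node_id], membership[node_id]
        best[left_id] = compute_best(left_id)
        best[right_id] = compute_best(right_id)
    return tree


def subtree_prune(tree: RiskTree, node_id: int) -> RiskTree:
    """Return a copy of ``tree`` with ``node_id`` made terminal.

    The node's n and mean are unchanged (they were computed from all records
    reaching it); descendants are dropped.  Pruning a terminal node warns and
    returns an unchanged copy.
    """
    if node_id not in tree.nodes:
        raise ValidationError(f"no node {node_id} in tree")
    pruned = tree.copy()
    node = pruned.nodes[node_id]
    if node.is_leaf:
        warnings.warn(f"node {node_id} is already terminal; prune is a no-op", stacklevel=2)
        return pruned
    doomed = [node.left, node.right]
    while doomed:
        did = doomed.pop()
        child = pruned.nodes.pop(did)
        if not child.is_leaf:
            doomed.extend([child.left, child.right])
    node.item = node.threshold = node.left = node.right = None
    return pruned


def check_conservation(tree: RiskTree, rel_tol: float = 1e-9) -> None:
    """Assert child-count and child-mean conservation at every internal node."""
    for node in tree.internal_nodes():
        left, right = tree.nodes[node.left], tree.nodes[node.right]
        if left.n + right.n != node.n:
            raise AssertionError(f"count conservation fails at node {node.node_id}")
        lhs = left.n * left.mean_risk + right.n * right.mean_risk
        rhs = node.n * node.mean_risk
        if abs(lhs - rhs) > rel_tol * max(1.0, abs(rhs)):
            raise AssertionError(f"mean conservation fails at node {node.node_id}")
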