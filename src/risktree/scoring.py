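"""Deployment surface: apply a finalized risk algorithm to new records.

A :class:`RiskAlgorithm` packages the parsimonious tree, the terminal-node ->
group (0-6) map with per-group statistics, the DSS definition, and a hash of
the item dictionary it was derived against.  The dependent rating never
appears as a predictor, so full-assessment records (which lack it) score
identically to screener records — the core deployment use case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collapse import GroupAssignment
from .items import (
    DSS_CODE,
    AssessmentRecord,
    DssDefinition,
    ItemDictionary,
    MissingItemError,
    ValidationError,
    compute_dss,
)
from .tree import RiskTree


@dataclass(frozen=True)
class GroupStats:
    label: int
    n: float
    mean_risk: float


@dataclass
class RiskAlgorithm:
    """A finalized, serializable risk-stratification algorithm."""

    tree: RiskTree
    node_to_group: dict[int, int]
    group_stats: tuple[GroupStats, ...]
    dss: DssDefinition | None = None
    item_dictionary_hash: str = ""
    version: str = "1"

    def __post_init__(self) -> None:
        uncovered = [
            lid for lid in self.tree.leaf_ids() if lid not in self.node_to_group
        ]
        if uncovered:
            raise ValidationError(f"group map misses terminal nodes {uncovered}")

    @property
    def k(self) -> int:
        return len(self.group_stats)

    def items_used(self) -> list[str]:
        """Item codes the tree traverses, with DSS expanded to its nine items."""
        codes: list[str] = []
        for node in self.tree.internal_nodes():
            if node.item == DSS_CODE:
                if self.dss is not None:
                    codes.extend(self.dss.item_codes)
            else:
                codes.append(node.item)
        return sorted(set(codes))

    @classmethod
    def from_derivation(
        cls,
        tree: RiskTree,
        assignment: GroupAssignment,
        dictionary: ItemDictionary,
        dss: DssDefinition | None = None,
    ) -> "RiskAlgorithm":
        stats = tuple(
            GroupStats(label=i, n=float(assignment.group_n[i]),
                       mean_risk=float(assignment.group_mean_risk[i]))
            for i in range(assignment.k)
        )
        return cls(
            tree=tree,
            node_to_group=dict(assignment.node_to_group),
            group_stats=stats,
            dss=dss,
            item_dictionary_hash=dictionary.content_hash(),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "item_dictionary_hash": self.item_dictionary_hash,
            "k": self.k,
            "tree": self.tree.to_dict(),
            "groups": {str(nid): g for nid, g in sorted(self.node_to_group.items())},
            "group_stats": [
                {"label": s.label, "n": s.n, "mean_risk": s.mean_risk}
                for s in self.group_stats
            ],
            "dss_items": None if self.dss is None else list(self.dss.item_codes),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "RiskAlgorithm":
        return cls(
            tree=RiskTree.from_dict(data["tree"]),
            node_to_group={int(k): int(v) for k, v in data["groups"].items()},
            group_stats=tuple(
                GroupStats(label=s["label"], n=s["n"], mean_risk=s["mean_risk"])
                for s in data["group_stats"]
            ),
            dss=None
            if data.get("dss_items") is None
            else DssDefinition(tuple(data["dss_items"])),
            item_dictionary_hash=data.get("item_dictionary_hash", ""),
            version=data.get("version", "1"),
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskAlgorithm":
        return cls.from_dict(json.loads(text))

    @classmethod
    def load(cls, path) -> "RiskAlgorithm":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class PathStep:
    node_id: int
    item: str
    value: int
    branch: str
    imputed: bool


@dataclass
class ScoredRecord:
    record_id: str
    level: int
    leaf_id: int
    path: tuple[PathStep, ...]

    @property
    def imputed_items(self) -> list[str]:
        return [s.item for s in self.path if s.imputed]


def score_record(
    record: AssessmentRecord,
    algo: RiskAlgorithm,
    missing_policy: str = "zero",
) -> ScoredRecord:
    """Route one record through the tree to its 0-6 level, with an audit path.

    A split on the DSS computes the nine-item sum on the fly.  Under the
    default policy a missing item is read as 0 and the path step flagged
    imputed; under ``strict`` it raises :class:`MissingItemError` naming the
    item and node.
    """
    node = algo.tree.root
    path: list[PathStep] = []
    while not node.is_leaf:
        imputed = False
        if node.item == DSS_CODE:
            if algo.dss is None:
                raise ValidationError("tree splits on DSS but algorithm has no DSS definition")
            missing = [c for c in algo.dss.item_codes if c not in record.items]
            if missing and missing_policy == "strict":
                raise MissingItemError(missing[0], where=f"node {node.node_id}")
            imputed = bool(missing)
            value = compute_dss(record, algo.dss, missing_policy="zero")
        else:
            raw = record.items.get(node.item)
            if raw is None:
                if missing_policy == "strict":
                    raise MissingItemError(node.item, where=f"node {node.node_id}")
                raw, imputed = 0, True
            value = int(raw)
        branch = "left" if value <= node.threshold else "right"
        path.append(PathStep(node.node_id, node.item, value, branch, imputed))
        node = algo.tree.nodes[node.left if branch == "left" else node.right]
    return ScoredRecord(
        record_id=record.record_id,
        level=algo.node_to_group[node.node_id],
        leaf_id=node.node_id,
        path=tuple(path),
    )


def score_cohort(
    records,
    algo: RiskAlgorithm,
    missing_policy: str = "zero",
    errors: str = "collect",
) -> pd.DataFrame:
    """Score many records; one output row per input, order preserved.

    Columns: record_id, level, leaf_id, imputed_items (';'-joined), path
    (JSON).  With ``errors='collect'`` a failing record yields a row with
    level -1 and the message in an ``error`` column; ``'raise'`` propagates.
    """
    rows = []
    for rec in records:
        try:
            scored = score_record(rec, algo, missing_policy=missing_policy)
            rows.append(
                {
                    "record_id": scored.record_id,
                    "level": scored.level,
                    "leaf_id": scored.leaf_id,
                    "imputed_items": ";".join(scored.imputed_items),
                    "path": json.dumps(
                        [
                            [s.node_id, s.item, s.value, s.branch, s.imputed]
                            for s in scored.path
                        ]
                    ),
                    "error": "",
                }
            )
        except (ValidationError, KeyError) as exc:
            if errors == "raise":
                raise
            rows.append(
                {
                    "record_id": rec.record_id,
                    "level": -1,
                    "leaf_id": -1,
                    "imputed_items": "",
                    "path": "[]",
                    "error": str(exc),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["record_id", "level", "leaf_id", "imputed_items", "path", "error"],
    )


def score_frame(frame: pd.DataFrame, algo: RiskAlgorithm) -> np.ndarray:
    """Vectorized scoring of a prepared frame (items as columns, DSS included
    when the tree uses it); returns one 0-6 level per row."""
    if algo.dss is not None and DSS_CODE not in frame.columns:
        needed = any(n.item == DSS_CODE for n in algo.tree.internal_nodes())
        if needed:
            frame = frame.copy()
            frame[DSS_CODE] = sum(frame[c] for c in algo.dss.item_codes)
    leaf_ids = algo.tree.assign_leaves(frame)
    lut = {nid: g for nid, g in algo.node_to_group.items()}
    return np.array([lut[l] for l in leaf_ids], dtype=int)
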