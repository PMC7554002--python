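"""End-to-end derivation: grow the mean-risk tree, collapse terminal nodes
into the ordinal scale, and package the result as a deployable algorithm."""

from __future__ import annotations

import pandas as pd

from .collapse import collapse_until_parsimonious
from .items import DSS_CODE, DssDefinition, ItemDictionary
from .scoring import RiskAlgorithm
from .tree import GrowthConfig, grow_tree


def default_growth_config(
    dictionary: ItemDictionary, dss: DssDefinition | None = None, **overrides
) -> GrowthConfig:
    """Growth config with candidates = the dictionary's admissible items plus
    the DSS (when defined), under the published-scale defaults (20 terminal
    nodes, minimum leaf 50)."""
    candidates = tuple(dictionary.admissible_codes())
    if dss is not None:
        candidates = candidates + (DSS_CODE,)
    return GrowthConfig(candidates=candidates, **overrides)


def derive_algorithm(
    frame: pd.DataFrame,
    dictionary: ItemDictionary,
    growth: GrowthConfig | None = None,
    dss: DssDefinition | None = None,
    k: int = 7,
) -> RiskAlgorithm:
    """Derive a risk algorithm from a prepared cohort frame.

    The frame must hold one integer column per item, a ``danger`` outcome
    column, and — when ``dss`` is given and absent from the frame — the DSS
    column is added.  Returns the parsimonious tree with its 0..k-1 group
    map.
    """
    if dss is not None and DSS_CODE not in frame.columns:
        frame = frame.copy()
        frame[DSS_CODE] = sum(frame[c] for c in dss.item_codes)
    if growth is None:
        growth = default_growth_config(dictionary, dss)
    tree = grow_tree(frame, growth)
    final_tree, assignment = collapse_until_parsimonious(tree, k=k)
    return RiskAlgorithm.from_derivation(final_tree, assignment, dictionary, dss)
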