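"""Synthetic screener cohorts with planted tree structure, and the published
stratum-calibrated weighted fixture.

The generator emulates the derivation setting: children and youth aged 4-18
(about half male, mean age ~11.8), ~20 binary/ordinal items, and a clinician
danger-to-self rating 0-4.  Ground truth is a planted decision tree whose
leaves carry latent risk values; the rating is drawn from a cumulative
(ordered) logit around that latent risk:

    P(Y >= j) = expit((eta - theta_j) / noise_scale),   j = 1..4,

which reduces to a deterministic threshold rule at ``noise_scale = 0`` and
gives closed-form cell probabilities for oracle checks.  Items not used by
the planted tree ("distractors", including the nine DSS items) are drawn
through a Gaussian copula sharing a latent symptom factor (default r = 0.2),
so split ranking is tested against correlated competition.

:func:`table1_fixture` encodes the published derivation strata — seven scale
levels with their sample shares, mean risks and severe-risk fractions — as a
small weighted record set, making the printed cut-point metrics reproducible
in closed form without the (undeposited) real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .items import (
    DSS_CODE,
    AssessmentRecord,
    DssDefinition,
    ItemDictionary,
    ItemSpec,
    ValidationError,
    default_dss_definition,
)
from .tree import GrowthConfig, RiskTree, TreeNode

AGE_BANDS = ((4, 7), (8, 11), (12, 18))
AGE_BAND_LABELS = ("<=7", "8-11", ">=12")

#: Ordinal frequency-coding marginal: most symptoms absent, rare at the top.
DEFAULT_ORDINAL_PROBS = (0.45, 0.25, 0.15, 0.10, 0.05)


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    ``planted_tree`` is a :class:`RiskTree` whose leaf ``mean_risk`` fields
    hold latent risk values (its n fields are unused).  ``thresholds`` are
    the four increasing ordered-logit cut points; ``noise_scale`` scales the
    logistic noise (0 = deterministic).  ``age_band_weights`` cover the bands
    <=7 / 8-11 / >=12 (defaults give mean age ~11.8); ``age_latent_slope``
    optionally adds an age trend to the latent risk (per year, centred at
    11.8) for subgroup experiments; ``age_item_slope`` does the same on the
    logit of planted binary item prevalences, so older children both carry
    more risk markers and receive higher ratings.
    """

    n: int
    seed: int = 0
    dictionary: ItemDictionary = None
    planted_tree: RiskTree = None
    thresholds: tuple[float, float, float, float] = (-1.2, 0.2, 2.2, 3.6)
    noise_scale: float = 1.0
    age_band_weights: tuple[float, float, float] = (0.15, 0.33, 0.52)
    p_male: float = 0.498
    dss: DssDefinition | None = None
    item_probs: dict[str, object] = field(default_factory=dict)
    distractor_r: float = 0.2
    age_latent_slope: float = 0.0
    age_item_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("cohort size n must be >= 0")
        if self.dictionary is None:
            self.dictionary = default_item_dictionary()
        if self.dss is None and all(c in self.dictionary for c in default_dss_definition().item_codes):
            self.dss = default_dss_definition()
        if self.planted_tree is None:
            self.planted_tree = default_planted_tree()
        t = self.thresholds
        if not (len(t) == 4 and all(t[i] < t[i + 1] for i in range(3))):
            raise ValidationError("thresholds must be 4 strictly increasing reals")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be non-negative")
        w = np.asarray(self.age_band_weights, dtype=float)
        if len(w) != 3 or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValidationError("age_band_weights must be 3 non-negative weights summing to 1")

    def planted_items(self) -> set[str]:
        return {n.item for n in self.planted_tree.internal_nodes() if n.item != DSS_CODE}

    def planted_splits(self) -> set[tuple[str, int]]:
        return {(n.item, n.threshold) for n in self.planted_tree.internal_nodes()}


def default_item_dictionary() -> ItemDictionary:
    """~20-item screener-like dictionary: five binary risk-history/family
    items, nine ordinal DSS items, four ordinal distractors, and one school
    item flagged inadmissible (not all screened children attend school)."""
    specs = [
        ItemSpec("considered_self_injury", "binary"),
        ItemSpec("prior_self_injury", "binary"),
        ItemSpec("suicide_attempt", "binary"),
        ItemSpec("others_concerned", "binary"),
        ItemSpec("family_overwhelmed", "binary"),
    ]
    specs += [ItemSpec(f"dss_{i:02d}", "ordinal", 5) for i in range(1, 10)]
    specs += [
        ItemSpec("anxiety_sx", "ordinal", 5),
        ItemSpec("sleep_problem", "ordinal", 5),
        ItemSpec("irritability", "ordinal", 5),
        ItemSpec("social_withdrawal", "ordinal", 5),
        ItemSpec("school_disengagement", "ordinal", 5, admissible=False),
    ]
    return ItemDictionary(specs)


DEFAULT_BINARY_P = {
    "considered_self_injury": 0.25,
    "prior_self_injury": 0.20,
    "suicide_attempt": 0.08,
    "others_concerned": 0.15,
    "family_overwhelmed": 0.30,
}


def _planted(nodes: list[TreeNode]) -> RiskTree:
    return RiskTree({n.node_id: n for n in nodes})


def default_planted_tree() -> RiskTree:
    """Five-leaf ground truth echoing the published predictors: ideation,
    family burden, attempt history and depressive symptom load, with latent
    risks calibrated (with the default thresholds) to a ~3% severe+ rate and
    ~33% mild+ rate."""
    return _planted(
        [
            TreeNode(0, 0, 0, 0.0, item="considered_self_injury", threshold=0, left=1, right=2),
            TreeNode(1, 1, 0, 0.0, item="family_overwhelmed", threshold=0, left=3, right=4, parent=0),
            TreeNode(2, 1, 0, 0.0, item="suicide_attempt", threshold=0, left=5, right=6, parent=0),
            TreeNode(3, 2, 0, -3.0, parent=1),
            TreeNode(4, 2, 0, -2.0, parent=1),
            TreeNode(5, 2, 0, 0.0, item=DSS_CODE, threshold=12, left=7, right=8, parent=2),
            TreeNode(6, 2, 0, 1.5, parent=2),
            TreeNode(7, 3, 0, -0.5, parent=5),
            TreeNode(8, 3, 0, 0.6, parent=5),
        ]
    )


def default_config(n: int, seed: int = 0, **overrides) -> CohortConfig:
    return CohortConfig(n=n, seed=seed, **overrides)


def toy_two_split_config(n: int, seed: int = 0, noise_scale: float = 0.0) -> CohortConfig:
    """Minimal two-split planted cohort used for exact-recovery experiments.

    Leaf latent risks sit strictly between the ordered-logit thresholds, so
    at ``noise_scale=0`` the rating is deterministic per leaf (0 / 2 / 4).
    """
    dictionary = ItemDictionary(
        [
            ItemSpec("risk_a", "binary"),
            ItemSpec("risk_b", "binary"),
            ItemSpec("noise_1", "ordinal", 5),
            ItemSpec("noise_2", "ordinal", 5),
        ]
    )
    tree = _planted(
        [
            TreeNode(0, 0, 0, 0.0, item="risk_a", threshold=0, left=1, right=2),
            TreeNode(1, 1, 0, -0.5, parent=0),
            TreeNode(2, 1, 0, 0.0, item="risk_b", threshold=0, left=3, right=4, parent=0),
            TreeNode(3, 2, 0, 2.0, parent=2),
            TreeNode(4, 2, 0, 4.5, parent=2),
        ]
    )
    return CohortConfig(
        n=n,
        seed=seed,
        dictionary=dictionary,
        planted_tree=tree,
        thresholds=(0.0, 1.0, 3.0, 4.0),
        noise_scale=noise_scale,
        item_probs={"risk_a": 0.3, "risk_b": 0.5},
        dss=None,
    )


def constant_risk_config(n: int, seed: int = 0, noise_scale: float = 0.0) -> CohortConfig:
    """Null model: a single-leaf planted tree, every record at the same latent risk."""
    cfg = toy_two_split_config(n, seed, noise_scale)
    cfg.planted_tree = _planted([TreeNode(0, 0, 0, 1.5)])
    return cfg


@dataclass
class SimulationResult:
    """Generated frame plus the generative ground truth per record."""

    frame: pd.DataFrame
    latent: np.ndarray
    planted_leaf: np.ndarray


def ordered_logit_cell_probs(
    eta: float, thresholds, noise_scale: float
) -> np.ndarray:
    """Closed-form P(Y = j), j = 0..4, for one latent risk value."""
    thresholds = np.asarray(thresholds, dtype=float)
    if noise_scale == 0:
        y = int(np.sum(eta > thresholds))
        probs = np.zeros(5)
        probs[y] = 1.0
        return probs
    ge = expit((eta - thresholds) / noise_scale)  # P(Y >= j), j=1..4
    ge = np.concatenate([[1.0], ge])
    probs = ge - np.concatenate([ge[1:], [0.0]])
    return probs


def _ordinal_cutoffs(probs) -> np.ndarray:
    """Standard-normal cut points mapping a latent normal to ordinal codes."""
    cum = np.cumsum(np.asarray(probs, dtype=float))[:-1]
    return ndtri(np.clip(cum, 1e-12, 1 - 1e-12))


def simulate_frame(config: CohortConfig) -> SimulationResult:
    """Generate a cohort frame (items, demographics, danger rating) plus the
    latent risk and planted leaf per record.  Deterministic in the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n
    dictionary = config.dictionary

    band_idx = rng.choice(3, size=n, p=np.asarray(config.age_band_weights, dtype=float))
    ages = np.empty(n, dtype=int)
    for b, (lo, hi) in enumerate(AGE_BANDS):
        mask = band_idx == b
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    male = rng.random(n) < config.p_male

    planted = config.planted_items()
    z = rng.standard_normal(n)  # shared symptom factor for distractors
    r = config.distractor_r
    data: dict[str, np.ndarray] = {}
    for code, spec in dictionary.items():
        if code in planted:
            p = config.item_probs.get(code, DEFAULT_BINARY_P.get(code, 0.3))
            if spec.kind == "binary":
                pv = float(p)
                if config.age_item_slope:
                    logit_p = np.log(pv / (1 - pv))
                    pv = expit(logit_p + config.age_item_slope * (ages - 11.8))
                data[code] = (rng.random(n) < pv).astype(int)
            else:
                probs = np.asarray(
                    p if np.ndim(p) else DEFAULT_ORDINAL_PROBS[: spec.levels], dtype=float
                )
                data[code] = rng.choice(spec.levels, size=n, p=probs / probs.sum())
        else:
            u = r * z + np.sqrt(1 - r * r) * rng.standard_normal(n)
            if spec.kind == "binary":
                p = float(config.item_probs.get(code, 0.2))
                data[code] = (u > ndtri(1 - p)).astype(int)
            else:
                probs = np.asarray(
                    config.item_probs.get(code, DEFAULT_ORDINAL_PROBS[: spec.levels]),
                    dtype=float,
                )
                cutoffs = _ordinal_cutoffs(probs / probs.sum())
                data[code] = np.searchsorted(cutoffs, u).astype(int)

    frame = pd.DataFrame(data)
    frame.insert(0, "person_id", [f"P{i:06d}" for i in range(n)])
    frame.insert(1, "record_id", [f"R{i:06d}" for i in range(n)])
    frame.insert(2, "age_years", ages)
    frame.insert(3, "sex", np.where(male, "male", "female"))
    frame.insert(4, "source", "screener")
    if config.dss is not None:
        frame[DSS_CODE] = sum(frame[c] for c in config.dss.item_codes)

    leaf_ids = config.planted_tree.assign_leaves(frame) if n else np.array([], dtype=int)
    eta = np.array(
        [config.planted_tree.nodes[l].mean_risk for l in leaf_ids], dtype=float
    )
    if config.age_latent_slope:
        eta = eta + config.age_latent_slope * (ages - 11.8)

    thresholds = np.asarray(config.thresholds)
    if config.noise_scale == 0:
        danger = (eta[:, None] > thresholds[None, :]).sum(axis=1)
    else:
        noise = rng.logistic(0.0, config.noise_scale, size=n)
        danger = ((eta + noise)[:, None] > thresholds[None, :]).sum(axis=1)
    frame["danger"] = danger.astype(float)
    return SimulationResult(frame=frame, latent=eta, planted_leaf=leaf_ids)


def generate_cohort(config: CohortConfig) -> list[AssessmentRecord]:
    """Generate screener records (identical seed -> identical cohort)."""
    sim = simulate_frame(config)
    records = []
    item_codes = list(config.dictionary)
    for row in sim.frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            AssessmentRecord(
                person_id=d["person_id"],
                record_id=d["record_id"],
                age_years=int(d["age_years"]),
                sex=d["sex"],
                source="screener",
                items={c: int(d[c]) for c in item_codes},
                danger_to_self=int(d["danger"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Published-strata weighted fixture

#: Derivation strata as printed: (% of sample, mean risk, % severe+) per level.
TABLE1_STRATA = (
    (46.3, 0.08, 0.1),
    (12.8, 0.30, 1.1),
    (14.2, 0.62, 1.5),
    (13.7, 0.85, 3.3),
    (6.6, 1.44, 9.5),
    (5.7, 1.74, 19.5),
    (0.8, 2.28, 42.6),
)


def table1_fixture(scale_for_n: int | None = None) -> pd.DataFrame:
    """Weighted pseudo-record set encoding the published derivation strata.

    Two rows per level (severe / not severe) with weights ``w*f`` and
    ``w*(1-f)``; the ``danger`` column carries the stratum mean risk so that
    weighted level summaries reproduce the printed means exactly.  Printed
    sample shares sum to 100.1%; weights are renormalized to 1 and the
    discrepancy recorded in ``frame.attrs['printed_weight_sum']``.
    """
    rows = []
    total = sum(w for w, _, _ in TABLE1_STRATA)
    for level, (pct, mean_risk, severe_pct) in enumerate(TABLE1_STRATA):
        w = pct / total
        f = severe_pct / 100.0
        rows.append({"level": level, "weight": w * f, "danger": mean_risk, "severe": True})
        rows.append({"level": level, "weight": w * (1 - f), "danger": mean_risk, "severe": False})
    frame = pd.DataFrame(rows)
    if scale_for_n is not None:
        frame["weight"] *= scale_for_n
    frame.attrs["printed_weight_sum"] = total
    return frame


# ---------------------------------------------------------------------------
# End-to-end parameter recovery

@dataclass
class RecoveryReport:
    planted_splits: set[tuple[str, int]]
    recovered_splits: set[tuple[str, int]]
    n_groups: int
    group_means: np.ndarray
    monotone_group_means: bool
    heldout_c: float | None
    oracle_c: float | None

    @property
    def split_recovery_fraction(self) -> float:
        if not self.planted_splits:
            return 1.0
        return len(self.planted_splits & self.recovered_splits) / len(self.planted_splits)


def parameter_recovery_experiment(
    config: CohortConfig,
    growth: GrowthConfig | None = None,
    k: int = 7,
    n_holdout: int | None = None,
    dichotomy_threshold: int = 3,
) -> RecoveryReport:
    """Derive an algorithm on a fresh cohort and measure how much of the
    planted structure it recovers, plus held-out concordance against the
    severe+ outcome and the generator's oracle concordance from true latent
    risks."""
    from .evaluation import c_statistic
    from .pipeline import derive_algorithm
    from .scoring import score_frame

    sim = simulate_frame(config)
    if growth is None:
        candidates = tuple(config.dictionary.admissible_codes())
        if config.dss is not None:
            candidates = candidates + (DSS_CODE,)
        growth = GrowthConfig(candidates=candidates)
    algo = derive_algorithm(sim.frame, config.dictionary, growth=growth, dss=config.dss, k=k)

    recovered = {
        (n.item, n.threshold) for n in algo.tree.internal_nodes()
    }
    group_means = np.array([s.mean_risk for s in algo.group_stats])
    monotone = bool(np.all(np.diff(group_means) > 0)) if len(group_means) > 1 else True

    heldout_c = oracle_c = None
    n_holdout = n_holdout if n_holdout is not None else max(config.n // 5, 1)
    hconfig = CohortConfig(**{**config.__dict__, "n": n_holdout, "seed": config.seed + 1})
    hsim = simulate_frame(hconfig)
    outcome = hsim.frame["danger"].to_numpy() >= dichotomy_threshold
    if outcome.any() and (~outcome).any():
        levels = score_frame(hsim.frame, algo)
        heldout_c = c_statistic(levels, outcome)
        oracle_c = c_statistic(hsim.latent, outcome)
    return RecoveryReport(
        planted_splits=config.planted_splits(),
        recovered_splits=recovered,
        n_groups=algo.k,
        group_means=group_means,
        monotone_group_means=monotone,
        heldout_c=heldout_c,
        oracle_c=oracle_c,
    )
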