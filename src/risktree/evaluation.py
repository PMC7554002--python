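"""Validation battery for a scored cohort: level summaries with odds ratios,
concordance statistics, cut-point diagnostic tables, and subgroup/diagnosis
breakdowns.

All metrics accept per-record weights so that printed-table strata (fractional
weights) evaluate in closed form without sampling.  A "scored cohort" is a
DataFrame with a ``level`` column (0-6), and either a ``danger`` column
(0-4 rating; may be a fractional stratum mean on weighted fixtures), a
boolean ``severe`` column, or both; an optional ``weight`` column defaults
to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .items import (
    DEFAULT_DICHOTOMIES,
    SEVERE_PLUS,
    OutcomeDichotomy,
    ValidationError,
)

OR_METHODS = ("crude_2x2", "cumulative_logit")


def _weights(frame: pd.DataFrame) -> np.ndarray:
    if "weight" in frame.columns:
        return frame["weight"].to_numpy(dtype=float)
    return np.ones(len(frame))


def _outcome_flags(frame: pd.DataFrame, dichotomy: OutcomeDichotomy) -> np.ndarray:
    """Dichotomized outcome per row; a pre-computed flag column wins for the
    severe+ outcome on weighted fixtures (their danger column is a stratum
    mean, not a rating)."""
    if dichotomy.name == "severe_plus" and "severe" in frame.columns:
        return frame["severe"].to_numpy(dtype=bool)
    if "danger" not in frame.columns:
        raise ValidationError(
            f"no danger column to dichotomize for {dichotomy.name}"
        )
    return frame["danger"].to_numpy(dtype=float) >= dichotomy.threshold


def c_statistic(levels, outcome, weights=None) -> float:
    """Concordance probability (area under the ROC curve) with ties half.

    P(score+ > score-) + 0.5 P(score+ = score-) over all (positive,
    negative) pairs, computed by weighted counting over score values.
    Raises when either outcome class is absent.
    """
    levels = np.asarray(levels, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    w = np.ones(len(levels)) if weights is None else np.asarray(weights, dtype=float)
    if len(levels) != len(outcome) or len(levels) != len(w):
        raise ValidationError("levels, outcome and weights must have equal length")
    w_pos_total = w[outcome].sum()
    w_neg_total = w[~outcome].sum()
    if w_pos_total == 0 or w_neg_total == 0:
        raise ValidationError("c-statistic undefined: one outcome class is absent")
    values = np.unique(levels)
    pos_w = np.array([w[(levels == v) & outcome].sum() for v in values])
    neg_w = np.array([w[(levels == v) & ~outcome].sum() for v in values])
    neg_below = np.concatenate([[0.0], np.cumsum(neg_w)[:-1]])
    concordant = float((pos_w * neg_below).sum())
    ties = float((pos_w * neg_w).sum())
    return (concordant + 0.5 * ties) / (w_pos_total * w_neg_total)


def confusion_at_cut(
    levels, outcome, cut: int, weights=None
) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV (percent) for the rule level >= cut.

    Undefined cells (no positives, no predicted positives, ...) are NaN, not
    zero.
    """
    levels = np.asarray(levels, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    w = np.ones(len(levels)) if weights is None else np.asarray(weights, dtype=float)
    pred = levels >= cut
    tp = w[pred & outcome].sum()
    fp = w[pred & ~outcome].sum()
    fn = w[~pred & outcome].sum()
    tn = w[~pred & ~outcome].sum()

    def pct(num, den):
        return float(100.0 * num / den) if den > 0 else float("nan")

    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def cutpoint_table(
    frame: pd.DataFrame,
    dichotomies=DEFAULT_DICHOTOMIES,
    cuts=(1, 2, 3, 4),
) -> pd.DataFrame:
    """Diagnostic-accuracy table: one row per (outcome dichotomy, cut-point).

    Columns: outcome, cut, sensitivity, specificity, ppv, npv (percent).
    """
    w = _weights(frame)
    levels = frame["level"].to_numpy()
    rows = []
    for dich in dichotomies:
        flags = _outcome_flags(frame, dich)
        for cut in cuts:
            metrics = confusion_at_cut(levels, flags, cut, w)
            rows.append({"outcome": dich.name, "cut": cut, **metrics})
    return pd.DataFrame(rows)


def _crude_or_row(a: float, b: float, c: float, d: float) -> dict[str, float]:
    """2x2 odds ratio (level row: a=+,b=-; reference: c=+,d=-) with Wald CI;
    Haldane-Anscombe 0.5 correction on any zero cell (flagged)."""
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "odds_ratio": float(or_),
        "ci_low": float(np.exp(np.log(or_) - 1.96 * se)),
        "ci_high": float(np.exp(np.log(or_) + 1.96 * se)),
        "zero_cell_corrected": corrected,
    }


def level_odds_ratios(
    frame: pd.DataFrame,
    dichotomy: OutcomeDichotomy = SEVERE_PLUS,
    method: str = "cumulative_logit",
) -> pd.DataFrame:
    """Per-level odds ratios versus level 0 with Wald 95% CIs.

    ``crude_2x2``: ad/bc on the dichotomized outcome, weights respected.
    ``cumulative_logit``: proportional-odds model of the ordinal 0-4 rating
    on level as a categorical predictor (unweighted records only).
    """
    if method not in OR_METHODS:
        raise ValidationError(f"method must be one of {OR_METHODS}")
    levels = frame["level"].to_numpy()
    present = np.unique(levels)
    if 0 not in present:
        raise ValidationError("reference level 0 is empty")
    if method == "crude_2x2":
        w = _weights(frame)
        flags = _outcome_flags(frame, dichotomy)
        ref_pos = w[(levels == 0) & flags].sum()
        ref_neg = w[(levels == 0) & ~flags].sum()
        rows = [{"level": 0, "odds_ratio": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "zero_cell_corrected": False}]
        for lv in present[present > 0]:
            a = w[(levels == lv) & flags].sum()
            b = w[(levels == lv) & ~flags].sum()
            rows.append({"level": int(lv), **_crude_or_row(a, b, ref_pos, ref_neg)})
        return pd.DataFrame(rows)

    if "weight" in frame.columns and not np.allclose(_weights(frame), 1.0):
        raise ValidationError(
            "cumulative_logit odds ratios do not support fractional weights; "
            "use method='crude_2x2'"
        )
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    danger = frame["danger"].to_numpy()
    if not np.allclose(danger, np.round(danger)):
        raise ValidationError("cumulative_logit requires integer danger ratings")
    dummies = pd.get_dummies(pd.Categorical(levels), prefix="level", dtype=float)
    X = dummies.drop(columns=dummies.columns[0])
    endog = pd.Categorical(danger.astype(int), ordered=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = OrderedModel(endog, X, distr="logit").fit(method="bfgs", disp=False)
    rows = [{"level": 0, "odds_ratio": np.nan, "ci_low": np.nan,
             "ci_high": np.nan, "zero_cell_corrected": False}]
    for lv, col in zip(present[present > 0], X.columns):
        beta = fit.params[col]
        se = fit.bse[col]
        rows.append(
            {
                "level": int(lv),
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
                "zero_cell_corrected": False,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LevelSummary:
    """Per-level summary (published derivation-table shape) plus overall C."""

    table: pd.DataFrame
    c_statistic: float
    dichotomy: OutcomeDichotomy

    def formatted(self) -> pd.DataFrame:
        """Round to printed precision: percents and ORs to 1 decimal, means to 2."""
        out = self.table.copy()
        for col in ("pct_of_sample", "pct_positive", "odds_ratio", "ci_low", "ci_high"):
            out[col] = out[col].round(1)
        out["mean_risk"] = out["mean_risk"].round(2)
        return out


def level_summary(
    frame: pd.DataFrame,
    dichotomy: OutcomeDichotomy = SEVERE_PLUS,
    or_method: str = "crude_2x2",
) -> LevelSummary:
    """Summarize a scored cohort per level: % of sample, mean danger rating,
    % positive on the dichotomy, OR vs level 0, plus the overall c-statistic
    for the dichotomized outcome."""
    w = _weights(frame)
    levels = frame["level"].to_numpy()
    flags = _outcome_flags(frame, dichotomy)
    total = w.sum()
    if total <= 0:
        raise ValidationError("cohort has no weight")
    max_level = int(levels.max())
    try:
        ors = level_odds_ratios(frame, dichotomy, method=or_method).set_index("level")
    except ValidationError as exc:
        warnings.warn(f"odds ratios unavailable: {exc}", stacklevel=2)
        ors = pd.DataFrame(
            columns=["odds_ratio", "ci_low", "ci_high"], index=pd.Index([], name="level")
        )
    rows = []
    for lv in range(max_level + 1):
        mask = levels == lv
        wl = w[mask].sum()
        if wl == 0:
            warnings.warn(f"level {lv} has zero weight; blank row", stacklevel=2)
            rows.append(
                {"level": lv, "pct_of_sample": np.nan, "mean_risk": np.nan,
                 "pct_positive": np.nan, "odds_ratio": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        mean_risk = (
            float((w[mask] * frame["danger"].to_numpy(dtype=float)[mask]).sum() / wl)
            if "danger" in frame.columns
            else np.nan
        )
        row = {
            "level": lv,
            "pct_of_sample": float(100.0 * wl / total),
            "mean_risk": mean_risk,
            "pct_positive": float(100.0 * w[mask & flags].sum() / wl),
        }
        if lv in ors.index:
            row.update(
                odds_ratio=ors.loc[lv, "odds_ratio"],
                ci_low=ors.loc[lv, "ci_low"],
                ci_high=ors.loc[lv, "ci_high"],
            )
        else:
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("level")
    c = c_statistic(levels, flags, w)
    return LevelSummary(table=table, c_statistic=c, dichotomy=dichotomy)


def mean_risk_ratio(summary: LevelSummary, hi: int | None = None, lo: int = 0) -> float:
    """Ratio of top-level to bottom-level mean risk, at 1-decimal precision
    (the inputs carry printed precision; full float precision would be
    spurious)."""
    hi = int(summary.table.index.max()) if hi is None else hi
    ratio = summary.table.loc[hi, "mean_risk"] / summary.table.loc[lo, "mean_risk"]
    return float(Decimal(repr(float(ratio))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round_half_up(x: float) -> int:
    """Nearest integer with halves away from zero (printed-table convention)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def age_band(age_years: int) -> str:
    if age_years <= 7:
        return "<=7"
    if age_years <= 11:
        return "8-11"
    return ">=12"


def subgroup_summary(
    frame: pd.DataFrame,
    by: str = "age_band",
    dichotomy: OutcomeDichotomy = SEVERE_PLUS,
    or_method: str = "crude_2x2",
) -> dict[str, LevelSummary]:
    """Level summaries within strata (``age_band`` over <=7 / 8-11 / >=12,
    or ``sex``); empty strata are omitted with a warning."""
    work = frame.copy()
    if by == "age_band":
        work["age_band"] = [age_band(a) for a in work["age_years"]]
        order = ["<=7", "8-11", ">=12"]
    elif by == "sex":
        order = ["male", "female"]
    else:
        order = sorted(work[by].unique())
    out: dict[str, LevelSummary] = {}
    for stratum in order:
        sub = work[work[by] == stratum]
        if len(sub) == 0:
            warnings.warn(f"stratum {stratum!r} is empty; omitted", stacklevel=2)
            continue
        out[stratum] = level_summary(sub, dichotomy, or_method=or_method)
    return out


def threshold_by_group(
    frame: pd.DataFrame,
    group_columns: list[str],
    thresholds=(2, 3),
) -> pd.DataFrame:
    """Among records with each boolean flag set (e.g. a diagnosis category),
    the weighted percent reaching each scale threshold.  Empty groups yield
    NaN."""
    w = _weights(frame)
    levels = frame["level"].to_numpy()
    rows = []
    for col in group_columns:
        flag = frame[col].to_numpy(dtype=bool)
        denom = w[flag].sum()
        row = {"group": col}
        for t in thresholds:
            num = w[flag & (levels >= t)].sum()
            row[f"pct_{t}_plus"] = float(100.0 * num / denom) if denom > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
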