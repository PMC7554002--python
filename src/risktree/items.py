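"""Assessment-record data model: item dictionary, records, the Depression
Symptoms Scale (DSS), and outcome dichotomizations.

A screener record is one row of an intake assessment: person/record ids,
age (4-18), sex, ~100 mostly binary/ordinal symptom and behaviour items, and
— on screener-type records only — a single clinician rating of "danger to
self" coded 0 (minimal) to 4 (very severe or imminent).  That rating is the
dependent variable of the derivation; full-assessment records lack it, which
is why a predictive scale is needed in the first place.

The DSS is a sum score over nine depression-symptom items used as one tree
predictor.  The three outcome dichotomizations (mild+/moderate+/severe+)
threshold the 0-4 rating at 1, 2 and 3 respectively by default.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import yaml

#: Reserved code for the derived Depression Symptoms Scale column.  It is not
#: an item in the dictionary; tree splits may reference it and the scoring
#: engine computes it on the fly from the nine constituent items.
DSS_CODE = "dss"

ITEM_KINDS = ("binary", "ordinal", "categorical")
SEXES = ("male", "female")
SOURCES = ("screener", "full_assessment")
MISSING_POLICIES = ("zero", "strict")


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


class MissingItemError(ValidationError):
    """A required item value is absent after the missing-data policy."""

    def __init__(self, item: str, where: str | None = None):
        self.item = item
        self.where = where
        msg = f"required item {item!r} is missing"
        if where:
            msg += f" ({where})"
        super().__init__(msg)


@dataclass(frozen=True)
class ItemSpec:
    """One screener item: code, measurement kind, and admissible codes 0..levels-1."""

    code: str
    kind: str = "binary"
    levels: int = 2
    admissible: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ITEM_KINDS:
            raise ValidationError(f"unknown item kind {self.kind!r} for {self.code!r}")
        if self.levels < 2:
            raise ValidationError(f"item {self.code!r} must have >= 2 levels")
        if self.kind == "binary" and self.levels != 2:
            raise ValidationError(f"binary item {self.code!r} must have exactly 2 levels")

    @property
    def max_code(self) -> int:
        return self.levels - 1

    def check_value(self, value: int) -> None:
        if not (0 <= int(value) <= self.max_code):
            raise ValidationError(
                f"value {value} out of range 0..{self.max_code} for item {self.code!r}"
            )


class ItemDictionary(Mapping[str, ItemSpec]):
    """Ordered mapping of item code -> :class:`ItemSpec`.

    Serializes to/from a YAML list of ``{code, kind, levels, admissible}``
    entries; :meth:`content_hash` gives a stable digest used to bind a
    derived algorithm to the dictionary it was built against.
    """

    def __init__(self, specs: Iterable[ItemSpec]):
        self._specs: dict[str, ItemSpec] = {}
        for spec in specs:
            if spec.code == DSS_CODE:
                raise ValidationError(f"item code {DSS_CODE!r} is reserved")
            if spec.code in self._specs:
                raise ValidationError(f"duplicate item code {spec.code!r}")
            self._specs[spec.code] = spec

    def __getitem__(self, code: str) -> ItemSpec:
        return self._specs[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def admissible_codes(self) -> list[str]:
        """Codes eligible as tree predictors."""
        return [c for c, s in self._specs.items() if s.admissible]

    def content_hash(self) -> str:
        payload = json.dumps(
            [
                [s.code, s.kind, s.levels, s.admissible]
                for s in self._specs.values()
            ],
            separators=(",", ":"),
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        data = {
            "items": [
                {
                    "code": s.code,
                    "kind": s.kind,
                    "levels": s.levels,
                    "admissible": s.admissible,
                }
                for s in self._specs.values()
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ItemDictionary":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            ItemSpec(
                code=e["code"],
                kind=e.get("kind", "binary"),
                levels=int(e.get("levels", 2)),
                admissible=bool(e.get("admissible", True)),
            )
            for e in data["items"]
        )


@dataclass(frozen=True)
class DssDefinition:
    """The nine depression-symptom items whose codes sum to the DSS."""

    item_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.item_codes) != 9:
            raise ValidationError(
                f"DSS requires exactly 9 items, got {len(self.item_codes)}"
            )
        if len(set(self.item_codes)) != 9:
            raise ValidationError("DSS item codes must be distinct")

    def validate_against(self, dictionary: ItemDictionary) -> None:
        for code in self.item_codes:
            if code not in dictionary:
                raise ValidationError(f"DSS item {code!r} not in item dictionary")

    def max_total(self, dictionary: ItemDictionary) -> int:
        return sum(dictionary[c].max_code for c in self.item_codes)


def default_dss_definition() -> DssDefinition:
    """Placeholder nine-item DSS (dss_01..dss_09); real deployments configure
    the instrument's actual depression items here."""
    return DssDefinition(tuple(f"dss_{i:02d}" for i in range(1, 10)))


@dataclass(frozen=True)
class OutcomeDichotomy:
    """Dichotomization of the 0-4 danger-to-self rating at ``threshold``."""

    name: str
    threshold: int

    def __post_init__(self) -> None:
        if not (1 <= self.threshold <= 4):
            raise ValidationError("dichotomy threshold must be in 1..4")


MILD_PLUS = OutcomeDichotomy("mild_plus", 1)
MODERATE_PLUS = OutcomeDichotomy("moderate_plus", 2)
SEVERE_PLUS = OutcomeDichotomy("severe_plus", 3)
DEFAULT_DICHOTOMIES = (MILD_PLUS, MODERATE_PLUS, SEVERE_PLUS)


def dichotomize(danger: int, dichotomy: OutcomeDichotomy) -> bool:
    """True iff the danger-to-self rating meets or exceeds the threshold."""
    danger = int(danger)
    if not (0 <= danger <= 4):
        raise ValidationError(f"danger-to-self rating {danger} outside 0..4")
    return danger >= dichotomy.threshold


@dataclass
class AssessmentRecord:
    """One assessment row.

    ``items`` maps item code -> integer code; absent keys are missing values,
    handled by the missing-data policy downstream.  ``danger_to_self`` is
    required on screener records and absent on full assessments.
    """

    person_id: str
    record_id: str
    age_years: int
    sex: str
    source: str = "screener"
    items: dict[str, int] = field(default_factory=dict)
    danger_to_self: int | None = None
    diagnoses: frozenset[str] = frozenset()


def validate_record(
    record: AssessmentRecord,
    dictionary: ItemDictionary,
    strict_items: bool = False,
) -> None:
    """Raise :class:`ValidationError` on any invariant violation."""
    if not (4 <= record.age_years <= 18):
        raise ValidationError(f"age {record.age_years} outside 4..18")
    if record.sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}, got {record.sex!r}")
    if record.source not in SOURCES:
        raise ValidationError(f"source must be one of {SOURCES}")
    if record.source == "screener":
        if record.danger_to_self is None:
            raise ValidationError("screener record lacks danger_to_self")
    if record.danger_to_self is not None and not (0 <= record.danger_to_self <= 4):
        raise ValidationError(
            f"danger_to_self {record.danger_to_self} outside 0..4"
        )
    for code, value in record.items.items():
        spec = dictionary.get(code)
        if spec is None:
            if strict_items:
                raise ValidationError(f"unknown item {code!r}")
            warnings.warn(f"ignoring unknown item {code!r}", stacklevel=2)
            continue
        spec.check_value(value)


def compute_dss(
    record: AssessmentRecord,
    dss: DssDefinition,
    missing_policy: str = "zero",
) -> int:
    """Sum the nine DSS item codes on a record.

    Under the default ``zero`` policy a missing item contributes 0 (symptom
    not observed); under ``strict`` a missing item raises
    :class:`MissingItemError` naming the item.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    total = 0
    for code in dss.item_codes:
        value = record.items.get(code)
        if value is None:
            if missing_policy == "strict":
                raise MissingItemError(code, where="DSS computation")
            value = 0
        total += int(value)
    return total


# ---------------------------------------------------------------------------
# CSV I/O

_META_COLUMNS = (
    "person_id",
    "record_id",
    "age_years",
    "sex",
    "source",
    "danger_to_self",
    "diagnoses",
)


def read_records(
    path,
    dictionary: ItemDictionary,
    strict_items: bool = False,
) -> list[AssessmentRecord]:
    """Read assessment records from a header-ed CSV.

    One column per item code plus the metadata columns; empty cells are
    missing values.  Rows violating invariants raise a
    :class:`ValidationError` naming the (1-based) data row.  Unknown item
    columns warn and are ignored unless ``strict_items``.
    """
    records: list[AssessmentRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError("empty CSV: no header row")
        item_cols = [c for c in reader.fieldnames if c not in _META_COLUMNS]
        unknown = [c for c in item_cols if c not in dictionary]
        if unknown:
            if strict_items:
                raise ValidationError(f"unknown item columns: {unknown}")
            warnings.warn(f"ignoring unknown item columns: {unknown}", stacklevel=2)
            item_cols = [c for c in item_cols if c in dictionary]
        for rownum, row in enumerate(reader, start=1):
            danger_raw = (row.get("danger_to_self") or "").strip()
            diagnoses_raw = (row.get("diagnoses") or "").strip()
            items = {}
            for code in item_cols:
                cell = (row.get(code) or "").strip()
                if cell != "":
                    items[code] = int(cell)
            record = AssessmentRecord(
                person_id=row["person_id"],
                record_id=row["record_id"],
                age_years=int(row["age_years"]),
                sex=row["sex"],
                source=row.get("source") or "screener",
                items=items,
                danger_to_self=int(danger_raw) if danger_raw != "" else None,
                diagnoses=frozenset(
                    d for d in diagnoses_raw.split(";") if d
                ),
            )
            try:
                validate_record(record, dictionary, strict_items=strict_items)
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from exc
            records.append(record)
    return records


def write_records(records: Iterable[AssessmentRecord], path, dictionary: ItemDictionary) -> None:
    """Write records as CSV, one column per dictionary item, deterministically."""
    item_cols = list(dictionary)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(_META_COLUMNS) + item_cols)
        for rec in records:
            row = [
                rec.person_id,
                rec.record_id,
                rec.age_years,
                rec.sex,
                rec.source,
                "" if rec.danger_to_self is None else rec.danger_to_self,
                ";".join(sorted(rec.diagnoses)),
            ]
            for code in item_cols:
                value = rec.items.get(code)
                row.append("" if value is None else value)
            writer.writerow(row)


def records_to_frame(
    records: Iterable[AssessmentRecord],
    dictionary: ItemDictionary,
    dss: DssDefinition | None = None,
    missing_policy: str = "zero",
):
    """Flatten records to a DataFrame for tree building and evaluation.

    Columns: record metadata, one integer column per dictionary item (missing
    recoded per policy), a ``danger`` column (NaN when absent), and a derived
    ``dss`` column when a DSS definition is supplied.
    """
    import numpy as np
    import pandas as pd

    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    records = list(records)
    data: dict[str, list] = {
        "person_id": [r.person_id for r in records],
        "record_id": [r.record_id for r in records],
        "age_years": [r.age_years for r in records],
        "sex": [r.sex for r in records],
        "source": [r.source for r in records],
    }
    for code in dictionary:
        col = []
        for r in records:
            value = r.items.get(code)
            if value is None:
                if missing_policy == "strict":
                    raise MissingItemError(code, where=f"record {r.record_id}")
                value = 0
            col.append(int(value))
        data[code] = col
    frame = pd.DataFrame(data)
    frame["danger"] = np.array(
        [np.nan if r.danger_to_self is None else float(r.danger_to_self) for r in records]
    )
    if dss is not None:
        dss.validate_against(dictionary)
        frame[DSS_CODE] = sum(frame[c] for c in dss.item_codes)
    return frame
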