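"""Per-fish record types, delimited-text I/O and validation.

Two table dialects are supported, mirroring the two kinds of source data the
analyses consume:

``mkt``
    A fully measured market-style sample: every fish carries capture date,
    length, weight, sex, colour morph and (optionally) otolith metrics and
    age readings.
``utpb``
    An observer-style catch record with only capture date and total length
    (1-cm precision); sex and morph are unknown.

Units follow field convention: fish lengths in cm, fish weights in g, otolith
lengths in mm, otolith weights in mg. Missing values are ``None`` in memory
and empty cells on disk — never sentinel numbers.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, fields as _dc_fields
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FishRecord",
    "ReadingPair",
    "SEXES",
    "MORPHS",
    "EDGE_TYPES",
    "CONFIDENCE_CODES",
    "read_fish_table",
    "write_fish_table",
    "records_to_frame",
    "frame_to_records",
    "validate_records",
    "ValidationReport",
    "TableParseError",
]

SEXES = ("female", "male", "unknown")
MORPHS = ("plain", "spotted", "unknown")
EDGE_TYPES = ("opaque", "translucent", "indeterminate")
AGE_SOURCES = ("read", "alk_assigned", "simulated")
#: Reader confidence index, best to worst (good, fair-good, fair, fair-poor, poor).
CONFIDENCE_CODES = ("G", "FG", "F", "FP", "P")


class TableParseError(ValueError):
    """Raised when a delimited table cannot be parsed into records."""


@dataclass
class FishRecord:
    """One sampled fish with its morphometric, otolith and age fields."""

    fish_id: str
    capture_date: _dt.date
    tl_cm: float
    tw_g: float | None = None
    sex: str = "unknown"
    morph: str = "unknown"
    oto_weight_mg: float | None = None
    oto_length_mm: float | None = None
    annulus_count: int | None = None
    edge_type: str | None = None
    marginal_increment_mm: float | None = None
    age_yr: int | None = None
    age_source: str | None = None

    @property
    def capture_month(self) -> int:
        return self.capture_date.month

    @property
    def capture_year(self) -> int:
        return self.capture_date.year


@dataclass
class ReadingPair:
    """Repeated integer age reads for one fish, with optional confidence code."""

    fish_id: str
    reads: Sequence[int]
    confidence_code: str | None = None

    def __post_init__(self) -> None:
        self.reads = tuple(int(r) for r in self.reads)
        if len(self.reads) < 2:
            raise ValueError(f"fish {self.fish_id}: need >= 2 reads, got {len(self.reads)}")
        if any(r < 0 for r in self.reads):
            raise ValueError(f"fish {self.fish_id}: negative age read")
        if self.confidence_code is not None and self.confidence_code not in CONFIDENCE_CODES:
            raise ValueError(
                f"fish {self.fish_id}: unknown confidence code {self.confidence_code!r}"
            )


# Column order used by the writer and expected (as superset) by the reader.
_MKT_COLUMNS = [
    "fish_id",
    "capture_date",
    "tl_cm",
    "tw_g",
    "sex",
    "morph",
    "oto_weight_mg",
    "oto_length_mm",
    "annulus_count",
    "edge_type",
    "marginal_increment_mm",
    "age_yr",
    "age_source",
]
_UTPB_REQUIRED = ["capture_date", "tl_cm"]

_FLOAT_FIELDS = {"tl_cm", "tw_g", "oto_weight_mg", "oto_length_mm", "marginal_increment_mm"}
_INT_FIELDS = {"annulus_count", "age_yr"}
_ENUM_FIELDS = {
    "sex": SEXES,
    "morph": MORPHS,
    "edge_type": EDGE_TYPES,
    "age_source": AGE_SOURCES,
}


def _parse_cell(name: str, raw: str, row_idx: int):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        if name == "capture_date":
            return _dt.date.fromisoformat(raw)
        if name in _FLOAT_FIELDS:
            return float(raw)
        if name in _INT_FIELDS:
            return int(raw)
    except ValueError as exc:
        raise TableParseError(f"row {row_idx}: cannot parse {name}={raw!r}: {exc}") from exc
    if name in _ENUM_FIELDS:
        if raw not in _ENUM_FIELDS[name]:
            raise TableParseError(
                f"row {row_idx}: unknown {name} value {raw!r}; "
                f"expected one of {_ENUM_FIELDS[name]}"
            )
        return raw
    return raw


def read_fish_table(path, dialect: str = "mkt") -> list[FishRecord]:
    """Read a CSV fish table into :class:`FishRecord` objects.

    Parameters
    ----------
    path : path-like
        CSV file with a header row (comma-separated, UTF-8).
    dialect : {"mkt", "utpb"}
        ``mkt`` requires the full measured-sample columns; ``utpb`` requires
        only ``capture_date`` and ``tl_cm`` (missing identity columns default
        to unknown).
    """
    if dialect not in ("mkt", "utpb"):
        raise ValueError(f"unknown dialect {dialect!r}")
    required = _MKT_COLUMNS[:3] if dialect == "mkt" else _UTPB_REQUIRED
    records: list[FishRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: empty file, header row required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise TableParseError(f"{path}: missing required columns {missing}")
        for i, row in enumerate(reader, start=1):
            kwargs = {}
            for name in _MKT_COLUMNS:
                if name in row and row[name] is not None:
                    val = _parse_cell(name, row[name], i)
                    if val is not None:
                        kwargs[name] = val
            if "capture_date" not in kwargs:
                raise TableParseError(f"row {i}: capture_date is required")
            if "tl_cm" not in kwargs:
                raise TableParseError(f"row {i}: tl_cm is required")
            if kwargs["tl_cm"] <= 0:
                raise TableParseError(
                    f"row {i}: tl_cm must be positive, got {kwargs['tl_cm']}"
                )
            if kwargs.get("age_yr", 0) < 0:
                raise TableParseError(f"row {i}: age_yr must be >= 0")
            kwargs.setdefault("fish_id", str(i))
            records.append(FishRecord(**kwargs))
    return records


def write_fish_table(records: Iterable[FishRecord], path) -> None:
    """Write records as CSV; missing fields become empty cells.

    ``read_fish_table(write_fish_table(x))`` reproduces ``x`` field-for-field.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MKT_COLUMNS)
        for rec in records:
            row = []
            for name in _MKT_COLUMNS:
                val = getattr(rec, name)
                if val is None:
                    row.append("")
                elif isinstance(val, _dt.date):
                    row.append(val.isoformat())
                else:
                    row.append(val)
            writer.writerow(row)


def records_to_frame(records: Iterable[FishRecord]) -> pd.DataFrame:
    """Canonical DataFrame view used by the modelling layers.

    Adds derived ``month``, ``year`` columns; categorical ``sex``/``morph``
    use *male* and *plain* as reference levels.
    """
    rows = [{f.name: getattr(r, f.name) for f in _dc_fields(FishRecord)} for r in records]
    df = pd.DataFrame(rows, columns=[f.name for f in _dc_fields(FishRecord)])
    if df.empty:
        return df
    df["capture_date"] = pd.to_datetime(df["capture_date"])
    df["month"] = df["capture_date"].dt.month
    df["year"] = df["capture_date"].dt.year
    df["sex"] = pd.Categorical(df["sex"], categories=list(SEXES))
    df["morph"] = pd.Categorical(df["morph"], categories=list(MORPHS))
    for col in ("tl_cm", "tw_g", "oto_weight_mg", "oto_length_mm", "marginal_increment_mm"):
        df[col] = pd.to_numeric(df[col])
    return df


def frame_to_records(df: pd.DataFrame) -> list[FishRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in _dc_fields(FishRecord):
            if f.name not in df.columns:
                continue
            val = row[f.name]
            if pd.isna(val):
                val = None
            elif f.name == "capture_date":
                val = pd.Timestamp(val).date()
            elif f.name in _INT_FIELDS:
                val = int(val)
            kwargs[f.name] = val
        records.append(FishRecord(**kwargs))
    return records


@dataclass
class ValidationReport:
    """Counts of invariant violations by rule, with offending fish ids."""

    violations: dict = field(default_factory=dict)  # rule -> list of fish_ids

    @property
    def n_violations(self) -> int:
        return sum(len(v) for v in self.violations.values())

    def ok(self) -> bool:
        return self.n_violations == 0

    def __str__(self) -> str:
        if self.ok():
            return "all records valid"
        lines = [f"{self.n_violations} violations:"]
        for rule, ids in sorted(self.violations.items()):
            shown = ", ".join(map(str, ids[:5])) + ("..." if len(ids) > 5 else "")
            lines.append(f"  {rule}: n={len(ids)} ({shown})")
        return "\n".join(lines)


def validate_records(records: Iterable[FishRecord]) -> ValidationReport:
    """Check record invariants; reports rather than raises."""
    report = ValidationReport()

    def flag(rule: str, fish_id: str) -> None:
        report.violations.setdefault(rule, []).append(fish_id)

    seen: set[str] = set()
    for rec in records:
        if rec.fish_id in seen:
            flag("duplicate fish_id", rec.fish_id)
        seen.add(rec.fish_id)
        if rec.tl_cm is None or rec.tl_cm <= 0:
            flag("tl_cm must be positive", rec.fish_id)
        for name in ("tw_g", "oto_weight_mg", "oto_length_mm", "marginal_increment_mm"):
            val = getattr(rec, name)
            if val is not None and val < 0:
                flag(f"{name} must be non-negative", rec.fish_id)
        for name in ("annulus_count", "age_yr"):
            val = getattr(rec, name)
            if val is not None and val < 0:
                flag(f"{name} must be non-negative", rec.fish_id)
        if rec.sex not in SEXES:
            flag("sex not in enumeration", rec.fish_id)
        if rec.morph not in MORPHS:
            flag("morph not in enumeration", rec.fish_id)
        if rec.edge_type is not None and rec.edge_type not in EDGE_TYPES:
            flag("edge_type not in enumeration", rec.fish_id)
        if rec.age_source is not None and rec.age_source not in AGE_SOURCES:
            flag("age_source not in enumeration", rec.fish_id)
    return report
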