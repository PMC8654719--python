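"""Effect-size records: data model, CSV input/output and cleaning rules.

One :class:`EffectRecord` is a single standardized mean difference (SMD)
extracted from a meta-analysis, carrying its metric label (Cohen's *d* or
Hedges' *g*), optional 95% confidence bounds and group sample sizes, and
study-level metadata (publication year, vessel bed, measurement modality,
biological category).  Records from the same parent meta-analysis share a
``meta_id`` cluster label, which downstream inference uses to account for
within-meta correlation.

Cleaning follows two rules applied in order: records flagged as duplicates
are removed first, then records whose absolute extracted value exceeds an
outlier threshold (default 8, applied on the metric as extracted, before any
d/g conversion, with strict inequality).
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ESMetric",
    "VesselBed",
    "Modality",
    "BioCategory",
    "EffectRecord",
    "CleanResult",
    "SchemaError",
    "RowError",
    "read_effects",
    "write_effects",
    "records_to_frame",
    "frame_to_records",
    "clean_effects",
    "magnitudes",
    "cleaning_audit",
]


class ESMetric(str, enum.Enum):
    """Label of the SMD metric as extracted from the source meta-analysis."""

    COHENS_D = "cohens_d"
    HEDGES_G = "hedges_g"


class VesselBed(str, enum.Enum):
    MACRO = "macro"
    MICRO = "micro"
    UNKNOWN = "unknown"


class Modality(str, enum.Enum):
    ULTRASOUND = "ultrasound"
    PLETHYSMOGRAPHY = "plethysmography"
    LASER_DOPPLER = "laser_doppler"
    OTHER = "other"
    UNKNOWN = "unknown"


class BioCategory(str, enum.Enum):
    EXERCISE = "exercise"
    SUPPLEMENT_DIET = "supplement_diet"
    PATHOPHYSIOLOGY = "pathophysiology"
    OTHER = "other"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """The input table is missing a required column."""


class RowError(ValueError):
    """A data row holds an unparseable or out-of-vocabulary cell.

    ``row`` is the 1-based index of the offending data row (header excluded).
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class EffectRecord:
    """A single signed SMD effect size with provenance metadata."""

    record_id: str
    meta_id: str
    es_value: float
    es_metric: ESMetric
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_treatment: int | None = None
    n_control: int | None = None
    year: int | None = None
    vessel_bed: VesselBed = VesselBed.UNKNOWN
    modality: Modality = Modality.UNKNOWN
    bio_category: BioCategory = BioCategory.UNKNOWN
    is_duplicate: bool = False
    unconverted_g: bool = False

    def __post_init__(self) -> None:
        if self.ci_lower is not None and self.ci_upper is not None:
            if not (self.ci_lower <= self.es_value <= self.ci_upper):
                raise ValueError(
                    f"record {self.record_id}: es_value {self.es_value} outside "
                    f"CI ({self.ci_lower}, {self.ci_upper})"
                )
        for name in ("n_treatment", "n_control"):
            n = getattr(self, name)
            if n is not None and n < 1:
                raise ValueError(f"record {self.record_id}: {name} must be >= 1")

    @property
    def n_total(self) -> int | None:
        """Combined sample size, or None if either group size is missing."""
        if self.n_treatment is None or self.n_control is None:
            return None
        return self.n_treatment + self.n_control

    @property
    def magnitude(self) -> float:
        return abs(self.es_value)


@dataclass(frozen=True)
class CleanResult:
    """Outcome of the cleaning rules with auditable removal counts."""

    retained: tuple[EffectRecord, ...]
    n_input: int
    n_duplicates_removed: int
    n_outliers_removed: int

    def __post_init__(self) -> None:
        if self.n_input != (
            len(self.retained) + self.n_duplicates_removed + self.n_outliers_removed
        ):
            raise ValueError("cleaning counts do not conserve the input count")

    @property
    def n_retained(self) -> int:
        return len(self.retained)


_REQUIRED_COLUMNS = ("es_value", "es_metric", "meta_id")
_OPTIONAL_COLUMNS = (
    "record_id",
    "ci_lower",
    "ci_upper",
    "n_treatment",
    "n_control",
    "year",
    "vessel_bed",
    "modality",
    "bio_category",
    "is_duplicate",
)

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"", "0", "false", "no", "n"}


def _parse_float(cell: str, row: int, col: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise RowError(row, f"column {col!r}: cannot parse {cell!r} as a number") from exc


def _parse_int(cell: str, row: int, col: str) -> int | None:
    v = _parse_float(cell, row, col)
    if v is None:
        return None
    if v != int(v):
        raise RowError(row, f"column {col!r}: {cell!r} is not an integer")
    return int(v)


def _parse_enum(cell: str, enum_cls, row: int, col: str):
    if cell == "":
        return enum_cls("unknown")
    try:
        return enum_cls(cell.strip().lower())
    except ValueError as exc:
        allowed = ", ".join(m.value for m in enum_cls)
        raise RowError(
            row, f"column {col!r}: {cell!r} is not one of ({allowed})"
        ) from exc


def _parse_bool(cell: str, row: int, col: str) -> bool:
    token = cell.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise RowError(row, f"column {col!r}: {cell!r} is not a boolean token")


def read_effects(path: str | Path, *, delimiter: str = ",") -> list[EffectRecord]:
    """Read an effects table from a UTF-8 delimited file with a header row.

    Required columns: ``es_value``, ``es_metric``, ``meta_id``.  Optional
    columns may be absent entirely; empty cells mean missing and map to
    ``None`` / ``unknown``.  Row order is preserved.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    RowError
        If a cell cannot be parsed; carries the 1-based data-row index.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise SchemaError(f"required column {col!r} missing from header")
        records: list[EffectRecord] = []
        for i, raw in enumerate(reader, start=1):
            row = {k: (v or "").strip() for k, v in raw.items() if k is not None}
            es_value = _parse_float(row["es_value"], i, "es_value")
            if es_value is None:
                raise RowError(i, "column 'es_value': empty cell")
            if not row["meta_id"]:
                raise RowError(i, "column 'meta_id': empty cell")
            try:
                metric = ESMetric(row["es_metric"].strip().lower())
            except ValueError as exc:
                raise RowError(
                    i,
                    f"column 'es_metric': {row['es_metric']!r} is not one of "
                    f"(cohens_d, hedges_g)",
                ) from exc
            try:
                rec = EffectRecord(
                    record_id=row.get("record_id", "") or f"row{i}",
                    meta_id=row["meta_id"],
                    es_value=es_value,
                    es_metric=metric,
                    ci_lower=_parse_float(row.get("ci_lower", ""), i, "ci_lower"),
                    ci_upper=_parse_float(row.get("ci_upper", ""), i, "ci_upper"),
                    n_treatment=_parse_int(row.get("n_treatment", ""), i, "n_treatment"),
                    n_control=_parse_int(row.get("n_control", ""), i, "n_control"),
                    year=_parse_int(row.get("year", ""), i, "year"),
                    vessel_bed=_parse_enum(row.get("vessel_bed", ""), VesselBed, i, "vessel_bed"),
                    modality=_parse_enum(row.get("modality", ""), Modality, i, "modality"),
                    bio_category=_parse_enum(
                        row.get("bio_category", ""), BioCategory, i, "bio_category"
                    ),
                    is_duplicate=_parse_bool(row.get("is_duplicate", ""), i, "is_duplicate"),
                )
            except RowError:
                raise
            except ValueError as exc:
                raise RowError(i, str(exc)) from exc
            records.append(rec)
    return records


def records_to_frame(records: Iterable[EffectRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with enum values as strings."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for key in ("es_metric", "vessel_bed", "modality", "bio_category"):
            d[key] = d[key].value
        rows.append(d)
    cols = [f.name for f in dataclasses.fields(EffectRecord)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(df: pd.DataFrame) -> list[EffectRecord]:
    """Inverse of :func:`records_to_frame` (NaN means missing)."""
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()

        def opt(key, cast):
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        out.append(
            EffectRecord(
                record_id=str(d.get("record_id") or f"row{i}"),
                meta_id=str(d["meta_id"]),
                es_value=float(d["es_value"]),
                es_metric=ESMetric(d["es_metric"]),
                ci_lower=opt("ci_lower", float),
                ci_upper=opt("ci_upper", float),
                n_treatment=opt("n_treatment", int),
                n_control=opt("n_control", int),
                year=opt("year", int),
                vessel_bed=VesselBed(d.get("vessel_bed") or "unknown"),
                modality=Modality(d.get("modality") or "unknown"),
                bio_category=BioCategory(d.get("bio_category") or "unknown"),
                is_duplicate=bool(d.get("is_duplicate", False)),
                unconverted_g=bool(d.get("unconverted_g", False)),
            )
        )
    return out


def write_effects(records: Iterable[EffectRecord], path: str | Path) -> None:
    """Write records to CSV in the same dialect :func:`read_effects` consumes."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def _exact_duplicate_mask(records: Sequence[EffectRecord]) -> list[bool]:
    # auto-detector keyed on the extracted numbers; later copies are flagged
    seen: set[tuple] = set()
    mask = []
    for r in records:
        key = (r.es_value, r.ci_lower, r.ci_upper, r.n_treatment, r.n_control)
        mask.append(key in seen)
        seen.add(key)
    return mask


def clean_effects(
    records: Sequence[EffectRecord],
    outlier_threshold: float = 8.0,
    *,
    detect_exact_duplicates: bool = False,
) -> CleanResult:
    """Apply the duplicate and outlier removal rules, in that order.

    Duplicates are removed by the ``is_duplicate`` flag (optionally augmented
    by an exact-tuple auto-detector over value, CI bounds and sample sizes).
    Among the remaining records, those with ``|es_value| > outlier_threshold``
    — on the metric as extracted, strict inequality — are removed.  Survivor
    order is preserved and the removal counts conserve the input count.
    """
    if outlier_threshold <= 0:
        raise ValueError("outlier_threshold must be positive")
    records = list(records)
    auto = _exact_duplicate_mask(records) if detect_exact_duplicates else [False] * len(records)
    after_dup = [r for r, a in zip(records, auto) if not (r.is_duplicate or a)]
    n_dup = len(records) - len(after_dup)
    retained = tuple(r for r in after_dup if abs(r.es_value) <= outlier_threshold)
    n_out = len(after_dup) - len(retained)
    return CleanResult(
        retained=retained,
        n_input=len(records),
        n_duplicates_removed=n_dup,
        n_outliers_removed=n_out,
    )


def magnitudes(records: Iterable[EffectRecord]) -> np.ndarray:
    """Absolute effect-size values, order preserved."""
    return np.abs(np.array([r.es_value for r in records], dtype=float))


def cleaning_audit(result: CleanResult, path: str | Path | None = None) -> dict:
    """JSON-serialisable audit of the cleaning step; optionally written to disk."""
    audit = {
        "n_input": result.n_input,
        "n_retained": result.n_retained,
        "n_duplicates_removed": result.n_duplicates_removed,
        "n_outliers_removed": result.n_outliers_removed,
    }
    if path is not None:
        Path(path).write_text(json.dumps(audit, indent=2) + "\n", encoding="utf-8")
    return audit
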