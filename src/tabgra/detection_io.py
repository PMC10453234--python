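"""Reading and cleaning of tabular food-safety detection records.

Raw surveillance records arrive one row per (sample, detection item) with
free-text result strings: plain numerals, left-censored values such as
``"<0.005"``, the literal ``"Not Detected"``, or several replicate plate
counts separated by semicolons (``"80; 70; 90;50; 180"``).  This module
parses those strings, imputes non-detects at half the assay's standard
detection limit, and pivots the records into a dense samples x indicators
matrix paired with per-indicator regulatory limit metadata.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NOT_DETECTED",
    "ParseError",
    "ConfigurationError",
    "UnitError",
    "EmptyInputError",
    "RawRecord",
    "IndicatorSpec",
    "ParsedValue",
    "DetectionMatrix",
    "AssembleResult",
    "parse_result_value",
    "impute_not_detected",
    "assemble_matrix",
    "flag_outliers",
    "read_raw_csv",
    "load_column_map",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_indicator_specs_csv",
    "read_indicator_specs_csv",
    "write_drop_report",
]


class ParseError(ValueError):
    """A detection-result token could not be interpreted."""


class ConfigurationError(ValueError):
    """Indicator metadata is missing or inconsistent with the requested operation."""


class UnitError(ValueError):
    """One indicator was reported in conflicting units."""


class EmptyInputError(ValueError):
    """No samples survive assembly."""


class _NotDetected:
    """Singleton sentinel for a 'Not Detected' assay result."""

    _instance: "_NotDetected | None" = None

    def __new__(cls) -> "_NotDetected":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_DETECTED"


NOT_DETECTED = _NotDetected()

# Strict decimal literal: "." radix, optional exponent, no thousands separators.
_NUMERAL = re.compile(r"^[+-]?(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?$")
_NOT_DETECTED_TOKENS = frozenset({"not detected", "undetected", "nd"})


@dataclass(frozen=True)
class RawRecord:
    """One row of a raw detection table (one sample x one detection item)."""

    record_no: int
    sample_no: str
    sampling_time: str
    product_name: str
    detection_item: str
    detection_result: str
    maximum_limit: str
    standard_detection_limit: float | None
    unit: str

    def __post_init__(self) -> None:
        if not str(self.detection_item).strip():
            raise ValueError(f"record {self.record_no}: empty detection_item")
        if not str(self.detection_result).strip():
            raise ValueError(f"record {self.record_no}: empty detection_result")


@dataclass(frozen=True)
class IndicatorSpec:
    """Identity and limit metadata for one risk indicator.

    ``max_limit`` is the regulatory maximum limit l_i used as the hazard-quotient
    denominator; ``limit_source`` records whether it came from a printed numeric
    limit or from the "shall not be used" fallback (the standard detection limit,
    so that any detected amount scores a hazard quotient >= 1 at the assay floor).
    """

    name: str
    max_limit: float
    detection_limit: float | None
    unit: str
    limit_source: str = "numeric"

    def __post_init__(self) -> None:
        if not self.max_limit > 0:
            raise ValueError(f"indicator {self.name!r}: max_limit must be > 0")
        if self.detection_limit is not None and not self.detection_limit > 0:
            raise ValueError(f"indicator {self.name!r}: detection_limit must be > 0")
        if self.limit_source not in ("numeric", "not-permitted-fallback"):
            raise ValueError(f"indicator {self.name!r}: bad limit_source {self.limit_source!r}")


@dataclass(frozen=True)
class ParsedValue:
    """A parsed detection result with its parsing provenance."""

    value: float | _NotDetected
    provenance: str  # plain | censored-stripped | multi-max | not-detected

    def __post_init__(self) -> None:
        if not isinstance(self.value, _NotDetected) and self.value < 0:
            raise ValueError("parsed detection values must be non-negative")

    @property
    def is_not_detected(self) -> bool:
        return isinstance(self.value, _NotDetected)


@dataclass
class DetectionMatrix:
    """Dense n x m grid of detection values (samples are rows, indicators columns).

    The grey-relational equations view the data as an m x n matrix X with
    x_i(k) = value of indicator i in sample k; that transpose is taken at the
    analysis boundary, never stored here.
    """

    samples: list[str]
    indicators: list[IndicatorSpec]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.indicators)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.indicators)} indicators"
            )
        if np.isnan(self.values).any():
            raise ValueError("DetectionMatrix may not contain missing cells")
        if (self.values < 0).any():
            raise ValueError("DetectionMatrix values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def indicator_names(self) -> list[str]:
        return [spec.name for spec in self.indicators]

    @property
    def max_limits(self) -> np.ndarray:
        return np.array([spec.max_limit for spec in self.indicators], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample_no"),
                            columns=self.indicator_names)


@dataclass
class AssembleResult:
    """Output of :func:`assemble_matrix`: the matrix plus the sample drop report."""

    matrix: DetectionMatrix
    specs: list[IndicatorSpec]
    dropped: dict[str, list[str]] = field(default_factory=dict)


def _parse_numeral(token: str, *, record: str = "") -> float:
    token = token.strip()
    if not _NUMERAL.match(token):
        where = f" (record {record})" if record else ""
        raise ParseError(f"unparseable detection-result token {token!r}{where}")
    value = float(token)
    if value < 0:
        where = f" (record {record})" if record else ""
        raise ParseError(f"negative detection value {token!r}{where}")
    return value


def parse_result_value(raw: str, *, record: str = "") -> ParsedValue:
    """Parse one free-text detection result.

    Rules, applied in order: the literal "Not Detected" (case-insensitive)
    yields the NOT_DETECTED sentinel; a leading "<" (left-censoring at the
    reporting bound) is stripped to the bound itself; semicolon-separated
    replicate values are reduced to their maximum; anything else must be a
    plain decimal numeral.  ``record`` is only used to label parse errors.
    """
    if raw is None or not str(raw).strip():
        raise ParseError(f"empty detection result (record {record})" if record
                         else "empty detection result")
    text = str(raw).strip()
    if text.lower() in _NOT_DETECTED_TOKENS:
        return ParsedValue(NOT_DETECTED, "not-detected")
    if ";" in text:
        parts = [p.strip() for p in text.split(";") if p.strip()]
        if not parts:
            raise ParseError(f"no values in multi-value result {raw!r} (record {record})")
        values = [_parse_numeral(p, record=record) for p in parts]
        return ParsedValue(max(values), "multi-max")
    if text.startswith("<"):
        return ParsedValue(_parse_numeral(text[1:], record=record), "censored-stripped")
    return ParsedValue(_parse_numeral(text, record=record), "plain")


def impute_not_detected(spec: IndicatorSpec) -> float:
    """Value substituted for a 'Not Detected' result: half the standard detection limit."""
    if spec.detection_limit is None:
        raise ConfigurationError(
            f"indicator {spec.name!r} has no standard detection limit; "
            "'Not Detected' results cannot be imputed"
        )
    return spec.detection_limit / 2.0


_NO_NUMERIC_LIMIT = frozenset({"shall not be used", "/", "", "not permitted"})


def _parse_limit(text: str) -> float | None:
    """Parse a maximum-limit cell; None when the substance is not permitted at all.

    Limits are printed with thousands separators in some source tables
    ("10,000"); those commas are stripped here.  Detection-result parsing
    stays strict and rejects them.
    """
    token = str(text).strip().lower()
    if token in _NO_NUMERIC_LIMIT:
        return None
    value = float(str(text).strip().replace(",", ""))
    if value <= 0:
        raise ConfigurationError(f"non-positive maximum limit {text!r}")
    return value


def _resolve_spec(
    name: str,
    records: Sequence[RawRecord],
    fallback_limits: Mapping[str, float] | None,
) -> IndicatorSpec:
    units = {str(r.unit).strip() for r in records if str(r.unit).strip()}
    if len(units) > 1:
        raise UnitError(f"indicator {name!r} reported in conflicting units: {sorted(units)}")
    unit = units.pop() if units else ""

    detection_limits = {r.standard_detection_limit for r in records
                        if r.standard_detection_limit is not None}
    if len(detection_limits) > 1:
        raise ConfigurationError(
            f"indicator {name!r} has conflicting standard detection limits: "
            f"{sorted(detection_limits)}"
        )
    detection_limit = detection_limits.pop() if detection_limits else None

    numeric_limits = {lim for r in records if (lim := _parse_limit(r.maximum_limit)) is not None}
    if len(numeric_limits) > 1:
        raise ConfigurationError(
            f"indicator {name!r} has conflicting maximum limits: {sorted(numeric_limits)}"
        )
    if numeric_limits:
        return IndicatorSpec(name, numeric_limits.pop(), detection_limit, unit, "numeric")

    # "shall not be used": fall back to a configured limit, default the detection
    # limit, so any detected amount has hazard quotient >= 1 at the assay floor.
    fallback = None
    if fallback_limits and name in fallback_limits:
        fallback = fallback_limits[name]
    elif detection_limit is not None:
        fallback = detection_limit
    if fallback is None:
        raise ConfigurationError(
            f"indicator {name!r} has no numeric maximum limit and no fallback "
            "(supply fallback_limits or a standard detection limit)"
        )
    return IndicatorSpec(name, fallback, detection_limit, unit, "not-permitted-fallback")


def assemble_matrix(
    records: Iterable[RawRecord],
    indicators: Sequence[str],
    *,
    fallback_limits: Mapping[str, float] | None = None,
) -> AssembleResult:
    """Pivot raw records into a DetectionMatrix over the requested indicators.

    Samples missing any requested indicator are dropped and reported.
    Duplicate (sample, indicator) records are reduced to the maximum parsed
    value, mirroring the within-string replicate rule.  'Not Detected'
    results are imputed at half the indicator's standard detection limit.
    """
    indicators = list(indicators)
    if not indicators:
        raise ConfigurationError("at least one indicator must be requested")

    by_indicator: dict[str, list[RawRecord]] = {name: [] for name in indicators}
    # (sample -> indicator -> parsed values); insertion order fixes sample order.
    cells: dict[str, dict[str, list[ParsedValue]]] = {}
    for rec in records:
        item = str(rec.detection_item).strip()
        if item not in by_indicator:
            continue  # detection items outside the indicator system are ignored
        by_indicator[item].append(rec)
        parsed = parse_result_value(
            rec.detection_result, record=f"{rec.record_no}/{rec.sample_no}"
        )
        cells.setdefault(str(rec.sample_no), {}).setdefault(item, []).append(parsed)

    specs = []
    for name in indicators:
        if not by_indicator[name]:
            raise ConfigurationError(f"indicator {name!r} appears in no record")
        specs.append(_resolve_spec(name, by_indicator[name], fallback_limits))
    spec_by_name = {s.name: s for s in specs}

    kept: list[str] = []
    dropped: dict[str, list[str]] = {}
    rows: list[list[float]] = []
    for sample, items in cells.items():
        missing = [name for name in indicators if name not in items]
        if missing:
            dropped[sample] = missing
            continue
        row = []
        for name in indicators:
            values = [
                impute_not_detected(spec_by_name[name]) if p.is_not_detected else p.value
                for p in items[name]
            ]
            row.append(max(values))
        kept.append(sample)
        rows.append(row)

    if not kept:
        raise EmptyInputError("no sample has complete records for all requested indicators")
    matrix = DetectionMatrix(kept, specs, np.array(rows, dtype=float))
    return AssembleResult(matrix=matrix, specs=specs, dropped=dropped)


def flag_outliers(
    matrix: DetectionMatrix,
    *,
    k: float = 50.0,
    rule: Callable[[DetectionMatrix], np.ndarray] | None = None,
) -> np.ndarray:
    """Boolean mask of samples to exclude as abnormal.

    The default rule is unit-aware and reproducible: a sample is abnormal if
    any indicator value exceeds ``k`` times that indicator's maximum limit.
    A custom ``rule`` callable (matrix -> boolean mask) may replace it.
    """
    if matrix.n_samples == 0:
        raise EmptyInputError("cannot flag outliers on an empty matrix")
    if rule is not None:
        mask = np.asarray(rule(matrix), dtype=bool)
        if mask.shape != (matrix.n_samples,):
            raise ValueError("outlier rule must return one flag per sample")
        return mask
    if not k > 0:
        raise ConfigurationError(f"outlier multiple k must be > 0, got {k}")
    thresholds = k * matrix.max_limits  # inf * limit -> inf: vacuous threshold
    return (matrix.values > thresholds[np.newaxis, :]).any(axis=1)


# ---------------------------------------------------------------------------
# CSV / JSON interchange

CANONICAL_COLUMNS = [
    "record_no",
    "sample_no",
    "sampling_time",
    "product_name",
    "detection_item",
    "detection_result",
    "maximum_limit",
    "standard_detection_limit",
    "unit",
]


def load_column_map(path: str) -> dict[str, str]:
    """Load a {canonical name: actual header} mapping from YAML or JSON."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"column map {path!r} must be a flat mapping")
    unknown = set(mapping) - set(CANONICAL_COLUMNS)
    if unknown:
        raise ConfigurationError(f"column map has unknown canonical names: {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


def read_raw_csv(
    path: str,
    *,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[RawRecord]:
    """Read raw detection records from CSV/TSV (delimiter sniffed unless given)."""
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "record_no"]
    if missing:
        raise ConfigurationError(f"raw table {path!r} lacks columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        data = dict(zip(df.columns, row))
        sdl_text = str(data.get("standard_detection_limit", "")).strip()
        sdl = None if sdl_text in ("", "/") else float(sdl_text)
        records.append(
            RawRecord(
                record_no=int(data.get("record_no") or i),
                sample_no=str(data["sample_no"]).strip(),
                sampling_time=str(data["sampling_time"]).strip(),
                product_name=str(data["product_name"]).strip(),
                detection_item=str(data["detection_item"]).strip(),
                detection_result=str(data["detection_result"]).strip(),
                maximum_limit=str(data["maximum_limit"]).strip(),
                standard_detection_limit=sdl,
                unit=str(data["unit"]).strip(),
            )
        )
    return records


def write_matrix_csv(matrix: DetectionMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, float_format="%.10g")


def read_matrix_csv(path: str, specs: Sequence[IndicatorSpec]) -> DetectionMatrix:
    df = pd.read_csv(path, index_col=0)
    spec_by_name = {s.name: s for s in specs}
    missing = [c for c in df.columns if c not in spec_by_name]
    if missing:
        raise ConfigurationError(f"matrix columns without indicator specs: {missing}")
    ordered = [spec_by_name[c] for c in df.columns]
    return DetectionMatrix([str(s) for s in df.index], ordered, df.to_numpy(dtype=float))


def write_indicator_specs_csv(specs: Sequence[IndicatorSpec], path: str) -> None:
    pd.DataFrame(
        {
            "name": [s.name for s in specs],
            "max_limit": [s.max_limit for s in specs],
            "detection_limit": [s.detection_limit for s in specs],
            "unit": [s.unit for s in specs],
            "limit_source": [s.limit_source for s in specs],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_indicator_specs_csv(path: str) -> list[IndicatorSpec]:
    df = pd.read_csv(path)
    specs = []
    for row in df.itertuples(index=False):
        dl = None if pd.isna(row.detection_limit) else float(row.detection_limit)
        unit = "" if pd.isna(row.unit) else str(row.unit)
        specs.append(IndicatorSpec(str(row.name), float(row.max_limit), dl, unit,
                                   str(row.limit_source)))
    return specs


def write_drop_report(result: AssembleResult, path: str) -> None:
    report = {
        "n_retained": result.matrix.n_samples,
        "n_dropped": len(result.dropped),
        "dropped": {sample: missing for sample, missing in sorted(result.dropped.items())},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
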