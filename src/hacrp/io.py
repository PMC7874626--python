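"""CSV interchange for cohorts, scored tables and comparison results.

The cohort schema is one row per hospital: ``hospital_id``, one column
per PSI code, one column per SIR measure key (blank = not reported),
and ``hai_exception`` coded 1/0.  Parsing is strict — duplicate ids,
negative values and malformed numerics are collected into one
:class:`CohortParseError` rather than coerced — and all writers emit
deterministic row/column order with fixed float precision so repeated
runs diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .compare import ComparisonResult
from .core import MEASURE_KEYS, PSI_CODES, HospitalRecord
from .penalty import SCORED_COLUMNS, ScoredCohort

__all__ = [
    "CohortTable",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "write_scored",
    "write_comparison",
]

logger = logging.getLogger("hacrp")

FLOAT_FORMAT = "%.6f"
_COHORT_COLUMNS = ("hospital_id", *PSI_CODES, *MEASURE_KEYS, "hai_exception")


class CohortParseError(ValueError):
    """All row-level problems found while parsing a cohort file."""

    def __init__(self, path, problems: Sequence[str]):
        self.problems = list(problems)
        msg = "\n  ".join(self.problems)
        super().__init__(f"{path}: {len(self.problems)} parse error(s):\n  {msg}")


@dataclass
class CohortTable:
    """Parsed cohort plus provenance metadata."""

    records: list[HospitalRecord]
    source: str
    n_rows: int
    unknown_columns: tuple[str, ...] = ()
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_value(raw, row_label: str, column: str, problems: list[str]) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        problems.append(f"row {row_label}, column {column}: malformed numeric {raw!r}")
        return None
    if value < 0:
        problems.append(f"row {row_label}, column {column}: negative value {value}")
        return None
    return value


def read_cohort(path) -> CohortTable:
    """Parse a cohort CSV strictly; every problem is reported with its
    row and column, and unknown columns are preserved in metadata."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "hospital_id" not in frame.columns:
        raise CohortParseError(path, ["missing required column 'hospital_id'"])
    unknown = tuple(c for c in frame.columns if c not in _COHORT_COLUMNS)
    warnings = []
    if unknown:
        warnings.append(f"unknown columns preserved but ignored: {list(unknown)}")
        logger.warning("%s: %s", path, warnings[-1])

    problems: list[str] = []
    seen: set[str] = set()
    records: list[HospitalRecord] = []
    for _, row in frame.iterrows():
        hid = str(row["hospital_id"]).strip()
        if not hid:
            problems.append("row with empty hospital_id")
            continue
        if hid in seen:
            problems.append(f"duplicate hospital_id {hid!r}")
            continue
        seen.add(hid)
        psi = {}
        for code in PSI_CODES:
            if code in frame.columns:
                v = _parse_value(row[code], hid, code, problems)
                if v is not None:
                    psi[code] = v
        sirs = {}
        for key in MEASURE_KEYS:
            if key in frame.columns:
                v = _parse_value(row[key], hid, key, problems)
                if v is not None:
                    sirs[key] = v
        exc = False
        if "hai_exception" in frame.columns:
            raw = str(row["hai_exception"]).strip().lower()
            if raw in ("1", "true", "yes"):
                exc = True
            elif raw not in ("", "0", "false", "no"):
                problems.append(f"row {hid}, column hai_exception: bad flag {raw!r}")
        records.append(HospitalRecord(hid, psi, sirs, hai_exception=exc))
    if problems:
        raise CohortParseError(path, problems)
    logger.info("read cohort %s: n=%d, unknown columns=%d",
                path, len(records), len(unknown))
    return CohortTable(records=records, source=str(path), n_rows=len(frame),
                       unknown_columns=unknown, warnings=warnings)


def write_cohort(records: Sequence[HospitalRecord], path) -> None:
    """Write records in the cohort CSV schema (rows sorted by id)."""
    rows = []
    for r in sorted(records, key=lambda r: r.hospital_id):
        row: dict[str, object] = {"hospital_id": r.hospital_id}
        for code in PSI_CODES:
            row[code] = r.psi_components.get(code)
        for key in MEASURE_KEYS:
            row[key] = r.sir_measures.get(key)
        row["hai_exception"] = int(r.hai_exception)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(_COHORT_COLUMNS))
    # round-trip float repr: lossless and deterministic
    frame.to_csv(path, index=False)


def write_scored(cohort: ScoredCohort, path) -> None:
    """One row per scored hospital, sorted by id; penalty flags coded 1/0."""
    frame = cohort.table.loc[:, list(SCORED_COLUMNS)].copy()
    frame = frame.sort_values("hospital_id", ignore_index=True)
    frame["penalized"] = frame["penalized"].astype(int)
    frame["domain2_imputed_max"] = frame["domain2_imputed_max"].astype(int)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_comparison(result: ComparisonResult, prefix) -> dict[str, Path]:
    """Write the overlap matrix (k x k CSV), the all-methodology summary
    and the pairwise rank-shift table under ``<prefix>_*.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "overlap": prefix.with_name(prefix.name + "_overlap.csv"),
        "rank_shifts": prefix.with_name(prefix.name + "_rank_shifts.csv"),
        "summary": prefix.with_name(prefix.name + "_summary.csv"),
    }
    result.overlap_matrix.round(6).to_csv(paths["overlap"], float_format=FLOAT_FORMAT)
    shift_rows = [
        {"methodology_a": a, "methodology_b": b, "spearman": s.spearman,
         "mean_abs_percentile_shift": s.mean_abs_percentile_shift,
         "max_abs_percentile_shift": s.max_abs_percentile_shift,
         "boundary_crossings": s.boundary_crossings, "n": s.n}
        for (a, b), s in sorted(result.pairwise_rank_stats.items())
    ]
    pd.DataFrame(shift_rows).to_csv(paths["rank_shifts"], index=False,
                                    float_format=FLOAT_FORMAT)
    summary = pd.DataFrame([
        {"quantity": "all_methodologies_overlap_pct", "value": result.all_years_pct},
    ])
    summary.to_csv(paths["summary"], index=False, float_format=FLOAT_FORMAT)
    return paths
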