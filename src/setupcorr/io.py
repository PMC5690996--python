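"""CSV interchange for per-fraction 6DoF match results.

Column layout (header required, units fixed)::

    patient_id,fraction,timepoint,tx_mm,ty_mm,tz_mm,pitch_deg,roll_deg,yaw_deg

``timepoint`` is one of ``post_setup``, ``post_correction``,
``post_treatment``; treatment courses are built from the ``post_setup``
rows, the other timepoints are returned as optional extra series.
Proprietary imaging-system exports are not parsed directly; rename their
columns to this layout (a ``column_map`` argument handles renames).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import AXES, SetupError6DoF, TreatmentCourse
from .protocols import ResidualCourse

__all__ = [
    "COLUMNS",
    "TIMEPOINTS",
    "MatchRecord",
    "read_match_table",
    "write_match_table",
    "write_residual_table",
]

logger = logging.getLogger(__name__)

COLUMNS = ("patient_id", "fraction", "timepoint") + AXES
TIMEPOINTS = ("post_setup", "post_correction", "post_treatment")


@dataclass(frozen=True)
class MatchRecord:
    """One CBCT match result: a 6DoF error at a (patient, fraction, timepoint)."""

    patient_id: str
    fraction: int
    timepoint: str
    error: SetupError6DoF

    def __post_init__(self) -> None:
        if self.fraction < 1:
            raise ValueError(f"fraction must be >= 1, got {self.fraction}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )


def _parse_row(
    row: Mapping[str, str], lineno: int
) -> MatchRecord:
    try:
        fraction = int(row["fraction"])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable fraction {row['fraction']!r}") from exc
    values = []
    for col in AXES:
        try:
            values.append(float(row[col]))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparseable number {row[col]!r} in {col}") from exc
    timepoint = row["timepoint"].strip()
    if timepoint not in TIMEPOINTS:
        raise ValueError(
            f"line {lineno}: unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}"
        )
    try:
        error = SetupError6DoF.from_array(values)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc
    return MatchRecord(row["patient_id"], fraction, timepoint, error)


def read_match_table(
    path, column_map: Optional[Mapping[str, str]] = None
) -> Tuple[List[TreatmentCourse], Dict[str, List[MatchRecord]]]:
    """Read a match table; return (courses from post_setup rows, extras).

    ``column_map`` maps file column names to the canonical :data:`COLUMNS`.
    Duplicate (patient, fraction, timepoint) keys and gaps in the
    post_setup fraction sequence are errors; missing optional timepoints
    only log a warning.
    """
    records: Dict[str, List[MatchRecord]] = {tp: [] for tp in TIMEPOINTS}
    seen: set = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file (header required)")
        fieldnames = list(reader.fieldnames)
        if column_map:
            fieldnames = [column_map.get(name, name) for name in fieldnames]
        missing = [c for c in COLUMNS if c not in fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for lineno, raw_row in enumerate(reader, start=2):
            row = dict(zip(fieldnames, (raw_row[orig] for orig in reader.fieldnames)))
            record = _parse_row(row, lineno)
            key = (record.patient_id, record.fraction, record.timepoint)
            if key in seen:
                raise ValueError(
                    f"line {lineno}: duplicate (patient_id, fraction, timepoint) = {key}"
                )
            seen.add(key)
            records[record.timepoint].append(record)

    if not records["post_setup"]:
        raise ValueError(f"{path}: no post_setup rows; cannot build treatment courses")
    for tp in ("post_correction", "post_treatment"):
        if not records[tp]:
            logger.warning("%s: no %s rows (optional timepoint missing)", path, tp)

    by_patient: Dict[str, List[MatchRecord]] = {}
    for record in records["post_setup"]:
        by_patient.setdefault(record.patient_id, []).append(record)

    courses = []
    for patient_id, patient_records in by_patient.items():
        patient_records.sort(key=lambda r: r.fraction)
        fractions = [r.fraction for r in patient_records]
        expected = list(range(1, fractions[-1] + 1))
        if fractions != expected:
            gaps = sorted(set(expected) - set(fractions))
            raise ValueError(
                f"patient {patient_id!r}: post_setup fractions are not contiguous "
                f"from 1; missing {gaps}"
            )
        courses.append(TreatmentCourse(patient_id, [r.error for r in patient_records]))

    extras = {tp: records[tp] for tp in ("post_correction", "post_treatment")}
    return courses, extras


def _format(value: float, decimals: Optional[int]) -> str:
    if decimals is None:
        return repr(float(value))  # full round-trip precision
    return f"{value:.{decimals}f}"


def write_match_table(
    courses: Sequence[TreatmentCourse],
    path,
    timepoint: str = "post_setup",
    decimals: Optional[int] = None,
) -> None:
    """Write courses in the canonical CSV layout.

    By default values are written at full precision so that
    write -> read round-trips bit-for-bit; pass ``decimals`` (e.g. 4) for
    human-oriented output.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(COLUMNS)
        for course in courses:
            for f, error in zip(course.fractions, course.errors):
                writer.writerow(
                    [course.patient_id, f, timepoint]
                    + [_format(v, decimals) for v in error.as_array()]
                )


def write_residual_table(
    residual_courses: Sequence[ResidualCourse], path, decimals: Optional[int] = None
) -> None:
    """Per-fraction residual dump with imaging/online flags and the
    correction in force (audit trail for protocol traces)."""
    header = (
        ["patient_id", "policy", "fraction", "imaged", "online_corrected"]
        + [f"residual_{axis}" for axis in AXES]
        + [f"correction_{axis}" for axis in AXES]
    )
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        for rc in residual_courses:
            for f in range(1, rc.n_fractions + 1):
                writer.writerow(
                    [
                        rc.patient_id,
                        rc.policy.name,
                        f,
                        int(rc.imaged[f - 1]),
                        int(rc.online_corrected[f - 1]),
                    ]
                    + [_format(v, decimals) for v in rc.residuals[f - 1]]
                    + [_format(v, decimals) for v in rc.corrections[f - 1]]
                )
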