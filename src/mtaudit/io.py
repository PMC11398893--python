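"""Readers, writers and validation for per-patient course files.

The canonical interchange format is a UTF-8 CSV with header
``patient_id,date,week,bsa,anc,plt,hb,mp_dose,mtx_dose`` and one row per
prescribing visit.  Workbook inputs (.xlsx) are mapped onto this dialect by
a header-matching adapter so that spreadsheet layouts used in the clinic can
be converted in bulk with :func:`convert_folder`.

Counts are converted to canonical units (10^9/L) on read via
``ProtocolRules.count_unit_scale``; e.g. counts recorded in cells/uL need
``count_unit_scale=0.001``.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import (
    CANONICAL_COLUMNS,
    PatientCourse,
    ProtocolRules,
    ValidationIssue,
    ValidationReport,
    VisitRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_course",
    "write_course",
    "convert_folder",
    "validate_course",
]


class FormatError(ValueError):
    """Input file does not match any supported layout."""


# Header synonyms for the workbook adapter (lower-cased, punctuation-insensitive).
_HEADER_SYNONYMS: dict[str, tuple[str, ...]] = {
    "patient_id": ("patient_id", "patient id", "upn", "id"),
    "date": ("date", "visit date", "dose advice date"),
    "week": ("week", "weeks", "mt week", "week number"),
    "bsa": ("bsa", "body surface area", "bsa m2"),
    "anc": ("anc", "absolute neutrophil count", "neutrophil count", "neutrophils"),
    "plt": ("plt", "platelet", "platelets", "platelet count"),
    "hb": ("hb", "hemoglobin", "haemoglobin"),
    "mp_dose": ("mp_dose", "mp dose", "6mp", "6mp dose", "mp mg week",
                "mercaptopurine", "6 mercaptopurine"),
    "mtx_dose": ("mtx_dose", "mtx dose", "mtx", "methotrexate", "mtx mg week"),
}

_REQUIRED = ("bsa", "mp_dose", "mtx_dose")


def _norm_header(h: object) -> str:
    s = str(h).strip().lower()
    for ch in "()[]/\\-_.,:":
        s = s.replace(ch, " ")
    return " ".join(s.split())


def _match_columns(columns) -> dict[str, str]:
    """Map canonical field names to actual column labels where recognisable."""
    normed = {_norm_header(c): c for c in columns}
    out: dict[str, str] = {}
    for field, synonyms in _HEADER_SYNONYMS.items():
        for syn in synonyms:
            if _norm_header(syn) in normed:
                out[field] = normed[_norm_header(syn)]
                break
    return out


def _read_table(path: Path, column_map: Optional[dict[str, str]] = None) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        df = pd.read_csv(path)
    elif suffix == ".xlsx":
        df = pd.read_excel(path, engine="openpyxl")
    elif suffix == ".xls":
        raise FormatError(
            f"{path.name}: legacy .xls workbooks are not supported; "
            "save as .xlsx or export to the canonical CSV"
        )
    else:
        raise FormatError(f"{path.name}: unsupported file type {suffix!r}")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    else:
        df = df.rename(columns={v: k for k, v in _match_columns(df.columns).items()})
    return df


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x):
        return None
    return float(x)


def read_course(
    path: str | Path,
    rules: Optional[ProtocolRules] = None,
    column_map: Optional[dict[str, str]] = None,
) -> PatientCourse:
    """Read one patient's course from a canonical CSV or a workbook.

    The patient id is taken from the ``patient_id`` column when present,
    otherwise from the file name stem.  When only dates are given, weeks are
    derived as ``floor(days since first visit / 7)``.  Counts are multiplied
    by ``rules.count_unit_scale`` to reach canonical 10^9/L.

    Raises
    ------
    FormatError
        If required columns are absent or the file type is unsupported.
    ValueError
        If dates/weeks are non-monotonic (row index is named).
    """
    path = Path(path)
    rules = rules or ProtocolRules()
    df = _read_table(path, column_map)

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if "week" not in df.columns and "date" not in df.columns:
        raise FormatError(f"{path.name}: needs a 'week' or a 'date' column")

    dates: list[Optional[_dt.date]] = [None] * len(df)
    if "date" in df.columns:
        parsed = pd.to_datetime(df["date"], errors="coerce")
        dates = [None if pd.isna(d) else d.date() for d in parsed]

    if "week" in df.columns and df["week"].notna().all():
        weeks = [float(w) for w in df["week"]]
    else:
        if any(d is None for d in dates):
            raise FormatError(f"{path.name}: missing week values and unparseable dates")
        origin = dates[0]
        for i in range(1, len(dates)):
            if dates[i] < dates[i - 1]:
                raise ValueError(f"{path.name}: non-monotonic dates at row {i}")
        weeks = [float((d - origin).days // 7) for d in dates]

    scale = rules.count_unit_scale
    if "patient_id" in df.columns and df["patient_id"].notna().any():
        patient_id = str(df["patient_id"].dropna().iloc[0])
    else:
        patient_id = path.stem

    visits = []
    for i in range(len(df)):
        row = df.iloc[i]

        def opt(col: str) -> Optional[float]:
            return _opt_float(row[col]) if col in df.columns else None

        anc = opt("anc")
        plt = opt("plt")
        visits.append(
            VisitRecord(
                week=weeks[i],
                date=dates[i],
                bsa=float(row["bsa"]),
                anc=None if anc is None else anc * scale,
                plt=None if plt is None else plt * scale,
                hb=opt("hb"),
                mp_dose=float(row["mp_dose"]),
                mtx_dose=float(row["mtx_dose"]),
            )
        )

    mt_end = max(rules.mt_length_weeks, weeks[-1] if weeks else 0.0)
    return PatientCourse(
        patient_id=patient_id,
        visits=visits,
        mt_end_week=mt_end,
        mt_start=dates[0] if dates and dates[0] else None,
    )


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return format(float(x), ".6g")


def write_course(course: PatientCourse, path: str | Path) -> Path:
    """Write a course as a canonical CSV (deterministic column order/formatting)."""
    path = Path(path)
    lines = [",".join(CANONICAL_COLUMNS)]
    for v in course.visits:
        row = [
            course.patient_id,
            v.date.isoformat() if v.date else "",
            _fmt(v.week),
            _fmt(v.bsa),
            _fmt(v.anc),
            _fmt(v.plt),
            _fmt(v.hb),
            _fmt(v.mp_dose),
            _fmt(v.mtx_dose),
        ]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def convert_folder(
    in_dir: str | Path,
    out_dir: str | Path,
    rules: Optional[ProtocolRules] = None,
    column_map: Optional[dict[str, str]] = None,
) -> tuple[list[Path], list[Path]]:
    """Convert every per-patient file in ``in_dir`` to a canonical CSV.

    Returns ``(written, skipped)``; unreadable files are skipped with a
    logged warning rather than aborting the batch.  Re-running overwrites
    the outputs identically.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    skipped: list[Path] = []
    for src in sorted(in_dir.iterdir()):
        if src.suffix.lower() not in (".csv", ".xlsx", ".xls"):
            continue
        try:
            course = read_course(src, rules, column_map)
        except Exception as exc:  # noqa: BLE001 - batch conversion must continue
            logger.warning("skipping %s: %s", src.name, exc)
            skipped.append(src)
            continue
        written.append(write_course(course, out_dir / f"{src.stem}.csv"))
    return written, skipped


_MAX_VISIT_GAP_WEEKS = 6.0


def validate_course(
    course: PatientCourse, rules: Optional[ProtocolRules] = None
) -> ValidationReport:
    """Check a course against the data-model invariants.

    Severity ``error`` blocks downstream analysis (non-monotone weeks,
    negative doses, non-positive BSA, course end before last visit);
    ``warning`` does not (missing counts at a visit, long visit gaps).
    """
    report = ValidationReport(patient_id=course.patient_id)

    def add(severity: str, idx: Optional[int], msg: str) -> None:
        report.issues.append(ValidationIssue(severity, idx, msg))

    prev_week = None
    for i, v in enumerate(course.visits):
        if v.week < 0:
            add("error", i, f"visit {i}: negative week {v.week}")
        if prev_week is not None:
            if v.week <= prev_week:
                add("error", i, f"visit {i}: week {v.week} not after {prev_week}")
            elif v.week - prev_week > _MAX_VISIT_GAP_WEEKS:
                add("warning", i,
                    f"visit {i}: {v.week - prev_week:g}-week gap since previous visit")
        prev_week = v.week
        if v.bsa is None or not v.bsa > 0:
            add("error", i, f"visit {i}: BSA must be > 0, got {v.bsa}")
        for name in ("mp_dose", "mtx_dose"):
            dose = getattr(v, name)
            if dose is None or dose < 0:
                add("error", i, f"visit {i}: {name} must be >= 0, got {dose}")
        for name in ("anc", "plt", "hb"):
            val = getattr(v, name)
            if val is not None and val < 0:
                add("error", i, f"visit {i}: {name} must be >= 0, got {val}")
        if not v.has_any_count():
            add("warning", i, f"visit {i}: no blood counts recorded")

    if course.mt_end_week < course.visits[-1].week:
        add("error", None,
            f"mt_end_week {course.mt_end_week} precedes last visit "
            f"week {course.visits[-1].week}")
    return report
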