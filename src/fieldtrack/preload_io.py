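"""Read, validate, write, and archive the preload and visit-log CSV files.

All persistent campaign state lives in two flat CSV files: the preload
(geocoded structures, one row each) and the visit log (one row per visit
record across all households). Files are UTF-8, comma-separated, with a
mandatory header row; timestamps are ISO 8601 local time.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .config import DEFAULT_CONFIG, StudyConfig
from .errors import (
    DuplicateIDError,
    FieldTrackError,
    IntegrityError,
    SchemaError,
    ValidationError,
)
from .model import AreaType, HouseholdLog, Structure, VisitRecord

PRELOAD_COLUMNS = ("HHID", "CLUSTER", "LAT", "LONG")

#: Visit-log schema, in canonical column order.
LOG_COLUMNS = (
    "REF", "HHID", "CLUSTER", "LONG", "LAT", "VISIT", "STRUCTURE",
    "STATUS", "DETAILS", "VISIT_DATETIME", "FU_DATE", "FU_NOTES", "INITIALS",
)

DATETIME_FMT = "%Y-%m-%dT%H:%M:%S"
DATE_FMT = "%Y-%m-%d"

MAIN_LOG_NAME = "visits.csv"


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    df.columns = [c.strip().upper() for c in df.columns]
    return df


def read_preload(
    path,
    area_type_map: Optional[Mapping[str, AreaType]] = None,
) -> list[Structure]:
    """Parse a preload CSV into validated structures.

    Parameters
    ----------
    path : path-like
        CSV with columns HHID, CLUSTER, LAT, LONG (any order, any case).
    area_type_map : mapping cluster -> AreaType, optional
        Recruitment modality per community; unmapped clusters default to
        NEIGHBORHOOD.

    Raises
    ------
    SchemaError
        Missing column or unreadable file.
    DuplicateIDError
        The same HHID appears on more than one row.
    ValidationError
        Out-of-range coordinate or empty field, reported with its row number.
    """
    df = _read_csv(path)
    missing = set(PRELOAD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")

    dupes = df["HHID"][df["HHID"].duplicated()].unique()
    if len(dupes):
        raise DuplicateIDError(dupes)

    area_type_map = area_type_map or {}
    structures = []
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is line 1
        try:
            lat, lon = float(row.LAT), float(row.LONG)
        except ValueError as exc:
            raise ValidationError(
                f"{path} row {rownum}: non-numeric coordinate"
            ) from exc
        try:
            structures.append(
                Structure(
                    hhid=row.HHID.strip(),
                    cluster=row.CLUSTER.strip(),
                    lat=lat,
                    lon=lon,
                    area_type=AreaType(
                        area_type_map.get(row.CLUSTER.strip(),
                                          AreaType.NEIGHBORHOOD)
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return structures


def write_preload(structures: Iterable[Structure], path) -> Path:
    """Write structures as a preload CSV in canonical column order."""
    path = Path(path)
    df = pd.DataFrame(
        [(s.hhid, s.cluster, s.lat, s.lon) for s in structures],
        columns=list(PRELOAD_COLUMNS),
    )
    df.to_csv(path, index=False)
    return path


def _parse_record(row, path, rownum) -> VisitRecord:
    def opt_dt(text):
        return datetime.strptime(text, DATETIME_FMT) if text else None

    def opt_date(text):
        return datetime.strptime(text, DATE_FMT).date() if text else None

    try:
        return VisitRecord(
            ref=int(row.REF),
            hhid=row.HHID.strip(),
            cluster=row.CLUSTER.strip(),
            lon=float(row.LONG),
            lat=float(row.LAT),
            visit=int(row.VISIT),
            structure=row.STRUCTURE,
            status=row.STATUS,
            details=row.DETAILS,
            visit_datetime=opt_dt(row.VISIT_DATETIME),
            fu_date=opt_date(row.FU_DATE),
            fu_notes=row.FU_NOTES,
            initials=row.INITIALS,
        )
    except (ValueError, ValidationError) as exc:
        if isinstance(exc, FieldTrackError):
            raise type(exc)(f"{path} row {rownum}: {exc}") from exc
        raise ValidationError(f"{path} row {rownum}: {exc}") from exc


def read_visit_log(
    path,
    config: StudyConfig = DEFAULT_CONFIG,
    area_type_map: Optional[Mapping[str, AreaType]] = None,
) -> dict[str, HouseholdLog]:
    """Parse a visit-log CSV into household logs keyed by HHID.

    Records are grouped by HHID and ordered by visit number; the visit
    numbers of each household must be contiguous ``0..k`` and each
    (STATUS, DETAILS) pair of a real visit must be in the configured
    vocabulary.
    """
    df = _read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")

    area_type_map = area_type_map or {}
    records: dict[str, list[VisitRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rec = _parse_record(row, path, i + 2)
        if rec.visit >= 1:
            config.validate_pair(rec.status, rec.details)
        records.setdefault(rec.hhid, []).append(rec)

    logs = {}
    for hhid, recs in records.items():
        recs.sort(key=lambda r: r.visit)
        logs[hhid] = HouseholdLog(
            hhid=hhid,
            records=tuple(recs),
            area_type=AreaType(
                area_type_map.get(recs[0].cluster, AreaType.NEIGHBORHOOD)
            ),
        )
    return logs


def _record_row(rec: VisitRecord) -> tuple:
    return (
        rec.ref,
        rec.hhid,
        rec.cluster,
        repr(rec.lon),
        repr(rec.lat),
        rec.visit,
        rec.structure,
        rec.status,
        rec.details,
        rec.visit_datetime.strftime(DATETIME_FMT) if rec.visit_datetime else "",
        rec.fu_date.strftime(DATE_FMT) if rec.fu_date else "",
        rec.fu_notes,
        rec.initials,
    )


def write_visit_log(logs: Mapping[str, HouseholdLog] | Iterable[HouseholdLog],
                    path) -> Path:
    """Serialize logs to a visit-log CSV (atomic: temp file + rename).

    Rows are ordered by (HHID, visit) for stable, diff-friendly output.
    Coordinates round-trip exactly (shortest-repr float formatting).
    """
    if isinstance(logs, Mapping):
        logs = logs.values()
    rows = [
        _record_row(rec)
        for log in sorted(logs, key=lambda lg: lg.hhid)
        for rec in log.records
    ]
    df = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".csv.part")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def save_with_archive(
    logs: Mapping[str, HouseholdLog] | Iterable[HouseholdLog],
    base_dir,
    today: date,
) -> tuple[Path, Path]:
    """Save the visit log plus a date-stamped archive snapshot.

    The main file ``visits.csv`` is overwritten atomically and a
    byte-identical copy is written to ``archive/visits_YYYY-MM-DD.csv``.
    Re-saving on the same date replaces that date's snapshot (one snapshot
    per date); snapshots of other dates are never touched.
    """
    base_dir = Path(base_dir)
    if not base_dir.is_dir():
        raise OSError(f"not a directory: {base_dir}")
    if not os.access(base_dir, os.W_OK):
        raise OSError(f"directory not writable: {base_dir}")

    main_path = write_visit_log(logs, base_dir / MAIN_LOG_NAME)
    archive_dir = base_dir / "archive"
    archive_dir.mkdir(exist_ok=True)
    archive_path = archive_dir / f"visits_{today.isoformat()}.csv"
    shutil.copyfile(main_path, archive_path)
    return main_path, archive_path


def epiinfo_link_key(hhid: str) -> str:
    """Deterministic key linking a household to its external questionnaire
    record. The convention is the identity mapping: the HHID itself."""
    if not hhid:
        raise ValidationError("hhid must be non-empty")
    return hhid
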