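"""Reading and writing mammography exposure records.

Records come either from DICOM file headers (header-only read; pixel data is
never touched) or from CSV exports with a configurable column-name dialect.
The canonical in-memory container is :class:`CohortTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per exposure (one mammographic
view acquisition) and a fixed, ordered column schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pydicom
import yaml

logger = logging.getLogger(__name__)

#: Canonical column order of a cohort table.
FIELDS: tuple[str, ...] = (
    "center_id",
    "exam_id",
    "patient_age",
    "view",
    "laterality",
    "cbt",
    "mas",
    "kvp",
    "compression_force",
    "implant_present",
    "agd",
    "exposure_control_mode",
    "anode_target",
    "filter_material",
    "manufacturer",
    "model_name",
)

NUMERIC_FIELDS: tuple[str, ...] = ("patient_age", "cbt", "mas", "kvp", "compression_force", "agd")
TEXT_FIELDS: tuple[str, ...] = tuple(
    f for f in FIELDS if f not in NUMERIC_FIELDS and f != "implant_present"
)

#: Fields a record must carry to be usable for DRL estimation.
MANDATORY_FIELDS: tuple[str, ...] = ("view", "cbt", "agd")

VALID_VIEWS = frozenset({"CC", "MLO"})
VALID_LATERALITIES = frozenset({"L", "R"})

#: Conversion factors from declared source units to mGy. The DICOM Organ Dose
#: attribute (0040,0316) is defined in decigray; some vendor private tags use
#: mGy directly, hence the per-source declaration.
DOSE_UNIT_TO_MGY: Mapping[str, float] = {
    "mGy": 1.0,
    "dGy": 100.0,
    "cGy": 10.0,
    "Gy": 1000.0,
    "uGy": 1e-3,
}


class EmptyInputError(ValueError):
    """No readable input records."""


class SchemaError(ValueError):
    """Input is missing a mandatory column."""


@dataclass(frozen=True)
class ExposureRecord:
    """One mammographic view acquisition with exposure factors and AGD."""

    center_id: str
    exam_id: str
    view: str
    laterality: str
    cbt: float
    agd: float
    patient_age: float = np.nan
    mas: float = np.nan
    kvp: float = np.nan
    compression_force: float = np.nan
    implant_present: bool = False
    exposure_control_mode: str = ""
    anode_target: str = ""
    filter_material: str = ""
    manufacturer: str = ""
    model_name: str = ""

    def __post_init__(self) -> None:
        if self.view not in VALID_VIEWS:
            raise ValueError(f"view must be one of {sorted(VALID_VIEWS)}, got {self.view!r}")
        if self.laterality not in VALID_LATERALITIES:
            raise ValueError(f"laterality must be L or R, got {self.laterality!r}")


@dataclass
class CohortTable:
    """Ordered collection of exposure records plus provenance.

    ``df`` always carries the canonical columns of :data:`FIELDS` in order;
    iteration order is stable for a given input.
    """

    df: pd.DataFrame
    provenance: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[ExposureRecord], provenance: str = "") -> "CohortTable":
        rows = [vars(r) for r in records]
        df = pd.DataFrame(rows, columns=list(FIELDS))
        return cls(df, provenance=provenance)

    def equals(self, other: "CohortTable") -> bool:
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


def _parse_float(v) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        return np.nan


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in FIELDS:
        if col not in out.columns:
            out[col] = "" if col in TEXT_FIELDS else (False if col == "implant_present" else np.nan)
    for col in NUMERIC_FIELDS:
        if out[col].dtype.kind in "fiu":
            out[col] = out[col].astype(float)
        else:
            # exact IEEE parsing (pd.to_numeric is not correctly rounded)
            out[col] = out[col].map(_parse_float)
    for col in TEXT_FIELDS:
        out[col] = out[col].fillna("").astype(str)
    out["implant_present"] = out["implant_present"].astype(bool)
    return out[list(FIELDS)].reset_index(drop=True)


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows that cannot support DRL estimation; return kept rows + drop count."""
    n0 = len(df)
    ok = df["view"].isin(VALID_VIEWS)
    for col in MANDATORY_FIELDS[1:]:
        ok &= df[col].notna()
    # physical non-negativity; NaN in optional numerics is allowed
    ok &= df["agd"] >= 0
    ok &= df["cbt"] >= 0
    for col in ("kvp", "mas", "compression_force"):
        ok &= df[col].isna() | (df[col] >= 0)
    ok &= df["laterality"].isin(VALID_LATERALITIES)
    return df[ok].reset_index(drop=True), n0 - int(ok.sum())


# ---------------------------------------------------------------------------
# DICOM extraction
# ---------------------------------------------------------------------------

_DICOM_MAP = {
    "center_id": "InstitutionName",
    "patient_age": "PatientAge",
    "view": "ViewPosition",
    "laterality": "ImageLaterality",
    "cbt": "BodyPartThickness",
    "mas": "Exposure",
    "kvp": "KVP",
    "compression_force": "CompressionForce",
    "implant_present": "BreastImplantPresent",
    "agd": "OrganDose",
    "exposure_control_mode": "ExposureControlMode",
    "anode_target": "AnodeTargetMaterial",
    "filter_material": "FilterMaterial",
    "manufacturer": "Manufacturer",
    "model_name": "ManufacturerModelName",
}


def _parse_age(value: object) -> float:
    """DICOM Age String '045Y' or plain number -> years."""
    if value is None:
        return np.nan
    s = str(value).strip()
    if not s:
        return np.nan
    if s[-1:].upper() in "DWMY":
        try:
            n = float(s[:-1])
        except ValueError:
            return np.nan
        return {"D": n / 365.25, "W": n / 52.18, "M": n / 12.0, "Y": n}[s[-1].upper()]
    try:
        return float(s)
    except ValueError:
        return np.nan


def extract_from_dicom(
    paths: Sequence[str | Path],
    organ_dose_unit: str = "dGy",
) -> CohortTable:
    """Read exposure metadata from DICOM file headers into a cohort table.

    Only header attributes are read (``stop_before_pixels``). Records missing
    any of view, CBT or organ dose — or with a view outside CC/MLO — are
    dropped and counted in the table provenance. ``organ_dose_unit`` declares
    the unit of the Organ Dose attribute at the source; the default follows
    the DICOM definition of (0040,0316) in decigray, converted to mGy.

    Raises
    ------
    EmptyInputError
        If no file could be read at all.
    """
    if organ_dose_unit not in DOSE_UNIT_TO_MGY:
        raise ValueError(f"unknown organ dose unit {organ_dose_unit!r}")
    factor = DOSE_UNIT_TO_MGY[organ_dose_unit]

    rows: list[dict] = []
    n_unreadable = 0
    for path in paths:
        try:
            ds = pydicom.dcmread(str(path), stop_before_pixels=True)
        except Exception:  # unreadable file: skip, never abort the batch
            logger.warning("skipping unreadable DICOM file: %s", path)
            n_unreadable += 1
            continue
        row: dict = {}
        for fieldname, keyword in _DICOM_MAP.items():
            row[fieldname] = ds.get(keyword, None)
        row["patient_age"] = _parse_age(row["patient_age"])
        row["implant_present"] = str(row["implant_present"] or "NO").upper() == "YES"
        if row["agd"] is not None:
            try:
                row["agd"] = float(row["agd"]) * factor
            except (TypeError, ValueError):
                row["agd"] = np.nan
        # exam grouping: AccessionNumber, else synthesized from patient + date
        acc = ds.get("AccessionNumber", None) or ds.get("StudyInstanceUID", None)
        if acc:
            row["exam_id"] = str(acc)
        else:
            row["exam_id"] = f"{row.get('center_id', '')}-{ds.get('PatientID', '')}-{ds.get('StudyDate', '')}"
        rows.append(row)

    if not rows:
        raise EmptyInputError(f"no readable DICOM files among {len(paths)} paths")

    df = _canonicalize(pd.DataFrame(rows))
    df, n_bad = _validate(df)
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    prov = (
        f"dicom:{len(paths)} paths; extracted {stamp}; "
        f"unreadable={n_unreadable}; dropped={n_bad}"
    )
    return CohortTable(df, provenance=prov, n_dropped=n_bad + n_unreadable)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


@dataclass
class CsvDialect:
    """Column-name mapping from a source CSV to canonical field names.

    ``columns`` maps canonical field name -> source column name. Omitted
    optional fields are filled with missing values; omitted mandatory fields
    raise :class:`SchemaError` at read time.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    organ_dose_unit: str = "mGy"

    @classmethod
    def identity(cls) -> "CsvDialect":
        return cls(columns={f: f for f in FIELDS})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CsvDialect":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            columns=cfg.get("columns", {}),
            organ_dose_unit=cfg.get("organ_dose_unit", "mGy"),
        )


def read_csv(path: str | Path, dialect: CsvDialect | None = None) -> CohortTable:
    """Read a cohort table from CSV using a column-name dialect.

    Rows whose mandatory numeric cells do not parse are dropped and counted.
    """
    dialect = dialect or CsvDialect.identity()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = dict(dialect.columns) or {f: f for f in FIELDS}
    for fieldname in MANDATORY_FIELDS:
        src = colmap.get(fieldname, fieldname)
        if src not in raw.columns:
            raise SchemaError(f"missing mandatory column {src!r} (for field {fieldname!r})")

    df = pd.DataFrame(index=raw.index)
    present: set[str] = set()
    for fieldname in FIELDS:
        src = colmap.get(fieldname, fieldname)
        if src in raw.columns:
            df[fieldname] = raw[src]
            present.add(fieldname)
        else:
            df[fieldname] = "" if fieldname in TEXT_FIELDS else np.nan
    # implant flag: tolerate booleans, YES/NO, 0/1
    df["implant_present"] = (
        df["implant_present"].astype(str).str.strip().str.upper().isin({"TRUE", "YES", "1"})
    )
    n0 = len(df)
    # a non-empty numeric cell that fails to parse invalidates its record
    bad = pd.Series(False, index=df.index)
    for col in NUMERIC_FIELDS:
        if col not in present:
            continue
        s = df[col].astype(str).str.strip()
        bad |= (s != "") & (s.str.lower() != "nan") & pd.to_numeric(s, errors="coerce").isna()
    df = df[~bad]
    df = _canonicalize(df)
    factor = DOSE_UNIT_TO_MGY[dialect.organ_dose_unit]
    if factor != 1.0:
        df["agd"] = df["agd"] * factor
    df, n_bad = _validate(df)
    n_drop = int(bad.sum()) + n_bad
    return CohortTable(
        df,
        provenance=f"csv:{path}; rows={n0}; dropped={n_drop}",
        n_dropped=n_drop,
    )


def write_csv(table: CohortTable, path: str | Path, force: bool = False) -> None:
    """Write a cohort table as canonical CSV (UTF-8, header, full precision)."""
    if len(table) == 0 and not force:
        raise ValueError("refusing to write empty cohort table (pass force=True to override)")
    out = table.df.copy()
    for col in NUMERIC_FIELDS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out["implant_present"] = out["implant_present"].map(lambda b: "True" if b else "False")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
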