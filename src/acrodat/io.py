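"""File formats: ratings CSV, patients CSV/JSON, deterministic reports.

Ratings files are long-format CSV with columns ``rater_id, scenario_id,
rating`` and the case-sensitive vocabulary S / M-DA / S-DA.  The survey's
green/yellow/red color aliases are accepted only when explicitly requested.
Patients files are one row per patient in a flat schema (see
:data:`PATIENT_COLUMNS`).  Reports are written with a deterministic column
order and a comment header carrying the tool version and a config hash, so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .agreement import CATEGORIES, RatingTable
from .errors import ParseError, ValidationError
from .scenario import N_SCENARIOS
from .severity import (
    AcroQoLResponse,
    ComorbidityProfile,
    IGFMeasurement,
    PatientRecord,
    SSSResponse,
    TumorAssessment,
)

COLOR_ALIASES = {"green": "S", "yellow": "M-DA", "red": "S-DA"}

PATIENT_COLUMNS = (
    "igf_value", "igf_lln", "igf_uln",
    "tumor_visible", "tumor_change_pct", "tumor_invasive", "vision_worse",
    "diabetes", "sleep_apnea", "cardiac",
    *[f"sss_{i}" for i in range(1, 6)],
    *[f"qol_{i}" for i in range(1, 23)],
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def read_ratings(path, allow_colors: bool = False) -> RatingTable:
    """Read and validate a long-format ratings CSV.

    Errors name the offending data row (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path, comment="#", dtype={"rating": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read ratings file {path}: {exc}") from exc
    required = ["rater_id", "scenario_id", "rating"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[required].copy()
    if allow_colors:
        df["rating"] = df["rating"].replace(COLOR_ALIASES)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.rating not in CATEGORIES:
            raise ParseError(
                f"{path}, row {i}: unknown rating token {row.rating!r} "
                f"(expected one of {CATEGORIES})"
            )
        sid = row.scenario_id
        if not (float(sid).is_integer() and 1 <= int(sid) <= N_SCENARIOS):
            raise ParseError(f"{path}, row {i}: scenario_id {sid!r} outside [1, {N_SCENARIOS}]")
    df["scenario_id"] = df["scenario_id"].astype(int)
    dup = df.duplicated(subset=["rater_id", "scenario_id"])
    if dup.any():
        i = int(dup.idxmax()) + 1
        raise ParseError(f"{path}, row {i}: duplicate (rater, scenario) pair")
    return RatingTable(df.reset_index(drop=True))


def write_ratings(rt: RatingTable, path) -> None:
    rt.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# patients

def _as_bool(value, field: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) in (0.0, 1.0):
            return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse boolean {field}={value!r}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def patients_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Parse the flat patients schema into :class:`PatientRecord` objects."""
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"patients table missing columns {missing}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            visible = _as_bool(row["tumor_visible"], "tumor_visible", i)
            change = row["tumor_change_pct"]
            tumor = TumorAssessment(
                visible=visible,
                size_change_pct=None if _is_missing(change) else float(change),
                invasiveness_increased=_as_bool(row["tumor_invasive"], "tumor_invasive", i),
                vision_worsened=_as_bool(row["vision_worse"], "vision_worse", i),
            )
            rec = PatientRecord(
                igf=IGFMeasurement(
                    value=float(row["igf_value"]),
                    lln=float(row["igf_lln"]),
                    uln=float(row["igf_uln"]),
                ),
                tumor=tumor,
                comorbidity=ComorbidityProfile(
                    diabetes=str(row["diabetes"]).strip(),
                    sleep_apnea=str(row["sleep_apnea"]).strip(),
                    cardiac=str(row["cardiac"]).strip(),
                ),
                sss=SSSResponse(tuple(int(row[f"sss_{k}"]) for k in range(1, 6))),
                acroqol=AcroQoLResponse(tuple(int(row[f"qol_{k}"]) for k in range(1, 23))),
            )
        except ValidationError:
            raise
        except (ValueError, TypeError, KeyError) as exc:
            raise ParseError(f"patients table, row {i}: {exc}") from exc
        records.append(rec)
    return records


def read_patients(path) -> list[PatientRecord]:
    """Read patients from CSV or JSON (list of flat objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        df = pd.DataFrame(data)
    else:
        df = pd.read_csv(path, comment="#")
    return patients_from_frame(df)


# ---------------------------------------------------------------------------
# reports

def _config_hash(config: Optional[dict]) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _format_float(x) -> str:
    return f"{x:.6g}"


def write_report(results: pd.DataFrame, path, format: str = "csv",
                 config: Optional[dict] = None) -> None:
    """Write an analysis report deterministically.

    Columns keep their given order; floats print to 6 significant digits;
    a header records the tool version and a hash of the run configuration.
    """
    if format not in ("csv", "json"):
        raise ValidationError(f"unknown report format {format!r}")
    meta = {"tool": "acrodat", "version": __version__, "config_hash": _config_hash(config)}
    path = Path(path)
    if format == "csv":
        body = results.copy()
        for col in body.columns:
            if pd.api.types.is_float_dtype(body[col]):
                body[col] = body[col].map(_format_float)
        with open(path, "w", newline="") as fh:
            fh.write(f"# acrodat {__version__} config_hash={meta['config_hash']}\n")
            body.to_csv(fh, index=False)
    else:
        rows = json.loads(results.to_json(orient="records"))
        for row in rows:
            for k, v in row.items():
                if isinstance(v, float):
                    row[k] = float(_format_float(v))
        with open(path, "w") as fh:
            json.dump({"meta": meta, "results": rows}, fh, indent=1, sort_keys=True)
            fh.write("\n")
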