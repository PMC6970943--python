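"""Cohort CSV input/output and run metadata.

CSV dialect is fixed (comma separator, '.' decimal, UTF-8, header row) to
avoid locale ambiguity.  On read, the derived FFR and FFR_C columns are
revalidated against the pressure columns; a mismatch beyond 1e-6 raises a
warning, and rows with PD above PA carry the non-physiological warning.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import pandas as pd

from .companion_metrics import NonPhysiologicalPressureWarning
from .synthetic_cohort import CohortRecord, cohort_to_frame

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_metadata",
    "read_config_file",
]

COHORT_COLUMNS = [
    "id", "location", "alpha_true", "S_pct", "PA",
    "PD_base", "PD_hyper", "FFR", "FFR_C", "clipped",
]

_NUMERIC = ["alpha_true", "S_pct", "PA", "PD_base", "PD_hyper", "FFR", "FFR_C"]


def write_cohort_csv(records, path) -> None:
    """Write a cohort (record list or DataFrame) to CSV, fixed column order."""
    frame = cohort_to_frame(records)[COHORT_COLUMNS]
    frame.to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read a cohort CSV back into records, validating as it goes.

    Raises on missing columns, empty files and malformed rows (with the
    1-based line number of the offender); warns when stored FFR/FFR_C
    disagree with the pressures or when a row has PD_hyper > PA.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort file") from exc
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    if len(frame) == 0:
        raise ValueError(f"{path}: no data rows")

    records = []
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            values = {c: float(row[c]) for c in _NUMERIC}
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed numeric value on line {line_no}") from exc
        if any(math.isnan(x) for x in values.values()):
            raise ValueError(f"{path}: missing value on line {line_no}")
        if values["PD_hyper"] > values["PA"]:
            warnings.warn(
                f"{path}: line {line_no}: PD_hyper > PA (FFR > 1)",
                NonPhysiologicalPressureWarning,
            )
        ffr_check = values["PD_hyper"] / values["PA"]
        ffrc_check = math.hypot(values["PA"], values["PD_hyper"])
        if abs(ffr_check - values["FFR"]) > 1e-6 or abs(ffrc_check - values["FFR_C"]) > 1e-6:
            warnings.warn(
                f"{path}: line {line_no}: stored FFR/FFR_C disagree with pressures"
            )
        records.append(
            CohortRecord(
                id=str(row["id"]),
                location=str(row["location"]),
                clipped=bool(row["clipped"]),
                **values,
            )
        )
    return records


def write_metadata(path, config: dict, seed: int | None = None) -> None:
    """Write a JSON metadata record (config echo + seed + package version)."""
    from . import __version__

    payload = {"package": "ffrsim", "version": __version__, "config": config}
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_config_file(path) -> dict:
    """Parse a flat key-value config file (``key = value`` per line).

    Values are coerced to int, then float, then left as strings; blank
    lines and ``#`` comments are ignored.
    """
    out: dict = {}
    for raw_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {raw_no}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            out[key] = value
    return out
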