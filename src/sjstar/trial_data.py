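"""Patient-level two-visit trial data: domain types and CSV I/O.

A trial is a flat table with one row per patient carrying the arm label,
baseline and follow-up values of the eight STAR instruments, and arbitrary
numeric baseline covariates.  Missing measurements are genuinely missing
(``None``), never sentinel zeros — zero is a meaningful value for several
instruments (e.g. unstimulated salivary flow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "INSTRUMENTS",
    "VisitMeasurements",
    "PatientRecord",
    "TrialDataset",
    "TrialValidationError",
    "TrialParseError",
    "read_trial_csv",
    "write_trial_csv",
    "load_column_map",
]

#: Canonical instrument field names, in table order.
INSTRUMENTS = (
    "clin_essdai",
    "esspri",
    "schirmer_mm",
    "oss",
    "uwsf_ml_min",
    "hocevar",
    "igg_g_l",
    "rf_iu_ml",
)

# (low, high, low_inclusive) validation ranges; high=None means unbounded.
_RANGES = {
    "clin_essdai": (0.0, None, True),
    "esspri": (0.0, 10.0, True),
    "schirmer_mm": (0.0, None, True),
    "oss": (0.0, 12.0, True),
    "uwsf_ml_min": (0.0, None, True),
    "hocevar": (0.0, 48.0, True),
    "igg_g_l": (0.0, None, False),  # strictly positive
    "rf_iu_ml": (0.0, None, True),
}

ARMS = ("treatment", "placebo")


class TrialValidationError(ValueError):
    """A value or structural invariant of trial data is violated."""


class TrialParseError(ValueError):
    """A CSV cell could not be parsed; names the offending row/column."""


def _check_range(name: str, value: float) -> None:
    low, high, low_incl = _RANGES[name]
    if low_incl:
        if value < low:
            raise TrialValidationError(f"{name}={value!r} below minimum {low}")
    elif value <= low:
        raise TrialValidationError(f"{name}={value!r} must be > {low}")
    if high is not None and value > high:
        raise TrialValidationError(f"{name}={value!r} above maximum {high}")


@dataclass(frozen=True)
class VisitMeasurements:
    """Instrument values recorded at one visit; every field optional.

    Units: clinESSDAI points; ESSPRI 0–10; Schirmer mm of wetting (mean of
    both eyes); ocular staining score 0–12 (mean of both eyes); UWSF mL/min;
    Hocevar ultrasound score 0–48; serum IgG g/L; RF IU/mL.
    """

    clin_essdai: float | None = None
    esspri: float | None = None
    schirmer_mm: float | None = None
    oss: float | None = None
    uwsf_ml_min: float | None = None
    hocevar: float | None = None
    igg_g_l: float | None = None
    rf_iu_ml: float | None = None

    def __post_init__(self) -> None:
        for name in INSTRUMENTS:
            value = getattr(self, name)
            if value is not None:
                _check_range(name, float(value))

    def get(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: arm assignment, two visits, baseline covariates."""

    patient_id: str
    arm: str
    baseline: VisitMeasurements
    followup: VisitMeasurements
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise TrialValidationError(
                f"arm must be one of {ARMS}, got {self.arm!r}"
            )


@dataclass(frozen=True)
class TrialDataset:
    """A labelled randomised trial with its patient records.

    ``expert_class`` is the panel's verdict on the trial's treatment effect
    (positive / in_between / negative) used to split the meta-analyses.
    """

    trial_id: str
    expert_class: str
    records: tuple[PatientRecord, ...]
    evaluation_week: int = 24

    def __post_init__(self) -> None:
        if self.expert_class not in ("positive", "in_between", "negative"):
            raise TrialValidationError(
                f"unknown expert_class {self.expert_class!r}"
            )
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrialValidationError(f"duplicate patient_id(s): {dupes}")
        arms = {r.arm for r in self.records}
        if arms != set(ARMS):
            raise TrialValidationError(
                "both treatment and placebo arms must be non-empty; "
                f"found arms {sorted(arms)}"
            )

    @property
    def n(self) -> int:
        return len(self.records)

    def arm_records(self, arm: str) -> tuple[PatientRecord, ...]:
        return tuple(r for r in self.records if r.arm == arm)


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

_BASE_PREFIX = "baseline_"
_FU_PREFIX = "followup_"
_COV_PREFIX = "cov_"
# Per-eye alternatives averaged on read (mean of both eyes).
_PER_EYE = {"schirmer_mm": "schirmer_mm", "oss": "oss"}


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a canonical-name → file-column mapping from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        mapping = yaml.safe_load(text)
    else:
        mapping = json.loads(text)
    if not isinstance(mapping, dict):
        raise TrialValidationError("column map must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _parse_cell(raw: object, row: int, column: str) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return None
    try:
        return float(text)
    except ValueError:
        raise TrialParseError(
            f"cannot parse {column!r} at row {row}: {text!r}"
        ) from None


def _visit_from_row(
    row: Mapping[str, object], prefix: str, rownum: int
) -> VisitMeasurements:
    values: dict[str, float | None] = {}
    for name in INSTRUMENTS:
        col = prefix + name
        value = _parse_cell(row.get(col), rownum, col) if col in row else None
        # optional per-eye columns, averaged when the pre-averaged cell is absent
        if value is None and name in _PER_EYE:
            left = row.get(f"{prefix}{name}_left")
            right = row.get(f"{prefix}{name}_right")
            lv = _parse_cell(left, rownum, f"{prefix}{name}_left")
            rv = _parse_cell(right, rownum, f"{prefix}{name}_right")
            if lv is not None and rv is not None:
                value = (lv + rv) / 2.0
        values[name] = value
    return VisitMeasurements(**values)


def read_trial_csv(
    path: str | Path,
    trial_id: str,
    expert_class: str,
    evaluation_week: int = 24,
    column_map: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Read a one-row-per-patient CSV into a validated :class:`TrialDataset`.

    ``column_map`` maps canonical column names (``patient_id``, ``arm``,
    ``baseline_esspri`` ...) to the names used in the file, so arbitrary
    trial exports can be ingested without rewriting them.  Empty cells are
    missing values, never zeros.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        reverse = {v: k for k, v in column_map.items()}
        frame = frame.rename(columns=reverse)
    required = ("patient_id", "arm")
    for col in required:
        if col not in frame.columns:
            raise TrialValidationError(f"missing required column {col!r}")

    records = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        pid = str(row["patient_id"]).strip()
        arm = str(row["arm"]).strip().lower()
        if arm not in ARMS:
            raise TrialValidationError(
                f"unknown arm label {row['arm']!r} at row {i}"
            )
        covariates = {
            col[len(_COV_PREFIX):]: parsed
            for col in frame.columns
            if col.startswith(_COV_PREFIX)
            and (parsed := _parse_cell(row.get(col), i, col)) is not None
        }
        records.append(
            PatientRecord(
                patient_id=pid,
                arm=arm,
                baseline=_visit_from_row(row, _BASE_PREFIX, i),
                followup=_visit_from_row(row, _FU_PREFIX, i),
                covariates=covariates,
            )
        )
    return TrialDataset(
        trial_id=trial_id,
        expert_class=expert_class,
        records=tuple(records),
        evaluation_week=evaluation_week,
    )


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    """Write a dataset as CSV; missing values become empty cells.

    ``read_trial_csv(write_trial_csv(d))`` reproduces every field of ``d``
    including the missingness pattern (trial-level metadata is passed back
    by the caller).
    """
    cov_names = sorted({k for r in dataset.records for k in r.covariates})
    rows = []
    for r in dataset.records:
        row: dict[str, str] = {"patient_id": r.patient_id, "arm": r.arm}
        for name in INSTRUMENTS:
            row[_BASE_PREFIX + name] = _fmt(r.baseline.get(name))
            row[_FU_PREFIX + name] = _fmt(r.followup.get(name))
        for cov in cov_names:
            value = r.covariates.get(cov)
            row[_COV_PREFIX + cov] = _fmt(value)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
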