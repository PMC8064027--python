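"""Cohort data model, readers/writers, and validation.

A cohort is a wide table: one row per participant (patients with posterior
cerebral artery stroke plus healthy controls), one column per
``test__measure`` pair from a declared test battery, with demographic
covariates (age, education) and, for patients, lesion volume and time since
stroke.  Missing score cells are permitted and tracked in an explicit
boolean mask so that downstream imputation never confuses "missing" with
"zero".
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Group",
    "Direction",
    "Measure",
    "TestSpec",
    "ParticipantRecord",
    "CohortTable",
    "CohortValidationError",
    "load_battery",
    "default_battery",
    "read_cohort",
    "write_cohort",
    "summarize_missingness",
    "write_results",
]

COVARIATE_COLUMNS = ("age", "education", "lesion_volume", "time_since_stroke")


class CohortValidationError(ValueError):
    """Raised when a cohort violates a structural invariant; the message
    carries row/column coordinates where applicable."""


class Group(str, enum.Enum):
    CONTROL = "control"
    LEFT = "left"
    RIGHT = "right"
    BILATERAL = "bilateral"

    @classmethod
    def parse(cls, label: str) -> "Group":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise CohortValidationError(
                f"unknown group label {label!r}; expected one of "
                f"{[g.value for g in cls]} (case-insensitive)"
            ) from None


class Direction(str, enum.Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


COMPOSITE_DOMAINS = ("word", "object", "face")
DOMAINS = COMPOSITE_DOMAINS + ("low_level", "mixed")


@dataclass(frozen=True)
class Measure:
    measure_id: str
    direction: Direction

    def __post_init__(self):
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class TestSpec:
    """One neuropsychological test: its domain, measures and whether it
    enters the domain composite scores."""

    test_id: str
    domain: str
    measures: tuple[Measure, ...]
    in_composite: bool = False

    __test__ = False  # keep pytest from collecting this dataclass

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise CohortValidationError(
                f"test {self.test_id!r}: unknown domain {self.domain!r}"
            )
        if len(self.measures) == 0:
            raise CohortValidationError(
                f"test {self.test_id!r}: at least one measure required"
            )
        if self.in_composite and self.domain not in COMPOSITE_DOMAINS:
            raise CohortValidationError(
                f"test {self.test_id!r}: in_composite requires domain in "
                f"{COMPOSITE_DOMAINS}, got {self.domain!r}"
            )
        object.__setattr__(self, "measures", tuple(self.measures))

    @property
    def measure_ids(self) -> tuple[str, ...]:
        return tuple(m.measure_id for m in self.measures)


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: Group
    age: float
    education: float | None = None
    lesion_volume: float | None = None
    time_since_stroke: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "group", Group(self.group))
        if not (self.age is not None and np.isfinite(self.age) and self.age > 0):
            raise CohortValidationError(
                f"participant {self.participant_id!r}: age must be positive, "
                f"got {self.age!r}"
            )
        if self.group is Group.CONTROL:
            if self.lesion_volume is not None or self.time_since_stroke is not None:
                raise CohortValidationError(
                    f"participant {self.participant_id!r}: controls must not "
                    "carry lesion_volume or time_since_stroke"
                )

    @property
    def is_patient(self) -> bool:
        return self.group is not Group.CONTROL


@dataclass
class CohortTable:
    """Participants x (test, measure) score matrix with missingness mask.

    ``values[i, j]`` holds participant i's score on column j, where columns
    enumerate every (test, measure) pair in battery order.  ``observed``
    is a same-shape boolean mask; values are only meaningful where observed.
    """

    participants: list[ParticipantRecord]
    tests: list[TestSpec]
    values: np.ndarray
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.observed is None:
            self.observed = np.isfinite(self.values)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.validate()

    # -- structure -------------------------------------------------------
    @property
    def columns(self) -> list[tuple[str, str]]:
        return [(t.test_id, m.measure_id) for t in self.tests for m in t.measures]

    @property
    def column_labels(self) -> list[str]:
        return [f"{t}__{m}" for t, m in self.columns]

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def group_mask(self, *groups: Group | str) -> np.ndarray:
        wanted = {Group(g) for g in groups}
        return np.array([p.group in wanted for p in self.participants])

    @property
    def is_patient(self) -> np.ndarray:
        return np.array([p.is_patient for p in self.participants])

    def subset(self, row_mask: np.ndarray) -> "CohortTable":
        row_mask = np.asarray(row_mask, dtype=bool)
        return CohortTable(
            participants=[p for p, keep in zip(self.participants, row_mask) if keep],
            tests=list(self.tests),
            values=self.values[row_mask].copy(),
            observed=self.observed[row_mask].copy(),
        )

    def with_values(self, values: np.ndarray, observed: np.ndarray | None = None) -> "CohortTable":
        return CohortTable(
            participants=list(self.participants),
            tests=list(self.tests),
            values=np.asarray(values, dtype=float),
            observed=self.observed.copy() if observed is None else observed,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = self.participant_ids
        seen: set[str] = set()
        for pid in ids:
            if pid in seen:
                raise CohortValidationError(f"duplicate participant_id {pid!r}")
            seen.add(pid)
        n_cols = len(self.columns)
        if self.values.shape != (len(self.participants), n_cols):
            raise CohortValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.participants)} participants x {n_cols} columns"
            )
        if self.observed.shape != self.values.shape:
            raise CohortValidationError(
                f"observed mask shape {self.observed.shape} does not match "
                f"values shape {self.values.shape}"
            )
        bad = ~np.isfinite(self.values) & self.observed
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise CohortValidationError(
                f"non-finite value marked observed at participant "
                f"{ids[i]!r}, column {self.column_labels[j]!r}"
            )

    def require_analysable(self) -> None:
        """At least 2 controls and 1 patient are needed downstream."""
        n_controls = int((~self.is_patient).sum())
        n_patients = int(self.is_patient.sum())
        if n_controls < 2 or n_patients < 1:
            raise CohortValidationError(
                f"analysis requires >=2 controls and >=1 patient; got "
                f"{n_controls} controls, {n_patients} patients"
            )

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "group": [p.group.value for p in self.participants],
                "age": [p.age for p in self.participants],
                "education": [p.education for p in self.participants],
                "lesion_volume": [p.lesion_volume for p in self.participants],
                "time_since_stroke": [p.time_since_stroke for p in self.participants],
            }
        )
        scores = pd.DataFrame(
            np.where(self.observed, self.values, np.nan), columns=self.column_labels
        )
        return pd.concat([meta, scores], axis=1)


# ---------------------------------------------------------------------------
# Battery schema IO
# ---------------------------------------------------------------------------

def _battery_from_mapping(doc: Mapping) -> list[TestSpec]:
    tests = []
    for entry in doc["tests"]:
        measures = tuple(
            Measure(m["measure_id"], Direction(m["direction"]))
            for m in entry["measures"]
        )
        tests.append(
            TestSpec(
                test_id=entry["test_id"],
                domain=entry["domain"],
                measures=measures,
                in_composite=bool(entry.get("in_composite", False)),
            )
        )
    if len({t.test_id for t in tests}) != len(tests):
        raise CohortValidationError("duplicate test_id in battery schema")
    return tests


def load_battery(path: str | Path) -> list[TestSpec]:
    """Load a test battery schema from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _battery_from_mapping(yaml.safe_load(fh))


def default_battery() -> list[TestSpec]:
    """The packaged 22-test battery over low-level vision, words, objects
    and faces; the bold composite subset is flagged ``in_composite``."""
    ref = resources.files("caseseries").joinpath("data/default_battery.yaml")
    return _battery_from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Cohort CSV IO
# ---------------------------------------------------------------------------

def _parse_optional_float(raw, pid: str, col: str) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise CohortValidationError(
            f"non-numeric value {raw!r} for participant {pid!r}, column {col!r}"
        ) from None


def read_cohort(path: str | Path, spec: Sequence[TestSpec]) -> CohortTable:
    """Read a wide-format cohort CSV against a battery schema.

    Columns are ``participant_id, group, age, education, lesion_volume,
    time_since_stroke`` followed by one ``<test>__<measure>`` column per
    measure in the schema.  Empty score cells are recorded as missing.
    Score columns not named in the schema are rejected.
    """
    spec = list(spec)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "participant_id" not in df.columns or "group" not in df.columns:
        raise CohortValidationError("cohort CSV must have participant_id and group columns")

    expected = [f"{t.test_id}__{m}" for t in spec for m in t.measure_ids]
    known_meta = {"participant_id", "group", *COVARIATE_COLUMNS}
    unknown = [c for c in df.columns if c not in known_meta and c not in expected]
    if unknown:
        raise CohortValidationError(f"score columns not in battery schema: {unknown}")
    absent = [c for c in expected if c not in df.columns]
    if absent:
        raise CohortValidationError(f"battery columns missing from CSV: {absent}")

    participants: list[ParticipantRecord] = []
    n = len(df)
    values = np.full((n, len(expected)), np.nan)
    observed = np.zeros((n, len(expected)), dtype=bool)
    for i in range(n):
        rec = df.iloc[i]
        pid = str(rec["participant_id"])
        group = Group.parse(rec["group"])
        age = _parse_optional_float(rec.get("age"), pid, "age")
        if age is None:
            raise CohortValidationError(f"participant {pid!r}: age is required")
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                group=group,
                age=age,
                education=_parse_optional_float(rec.get("education"), pid, "education"),
                lesion_volume=_parse_optional_float(
                    rec.get("lesion_volume"), pid, "lesion_volume"
                ),
                time_since_stroke=_parse_optional_float(
                    rec.get("time_since_stroke"), pid, "time_since_stroke"
                ),
            )
        )
        for j, col in enumerate(expected):
            raw = str(rec[col]).strip()
            if raw == "":
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise CohortValidationError(
                    f"non-numeric score {raw!r} at row {i + 1} "
                    f"(participant {pid!r}), column {col!r}"
                ) from None
            observed[i, j] = True

    return CohortTable(participants=participants, tests=spec, values=values, observed=observed)


def _FLOAT_FMT(v) -> str:  # shortest exact round-trip representation
    return repr(float(v))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to wide CSV; missing cells are written empty.
    ``read_cohort(write_cohort(c))`` round-trips values, mask and metadata."""
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# Missingness summary and result bundles
# ---------------------------------------------------------------------------

def summarize_missingness(cohort: CohortTable) -> pd.DataFrame:
    """Per-test and overall missing fractions.

    Returns a table with one row per test plus an ``__overall__`` row; the
    cell-count-weighted mean of per-test fractions equals the overall
    fraction exactly.
    """
    rows = []
    col_tests = [t for t in cohort.tests for _ in t.measures]
    miss = ~cohort.observed
    for t in cohort.tests:
        cols = [j for j, ct in enumerate(col_tests) if ct.test_id == t.test_id]
        block = miss[:, cols]
        rows.append(
            {
                "test_id": t.test_id,
                "n_cells": block.size,
                "n_missing": int(block.sum()),
                "missing_fraction": block.mean() if block.size else 0.0,
            }
        )
    rows.append(
        {
            "test_id": "__overall__",
            "n_cells": miss.size,
            "n_missing": int(miss.sum()),
            "missing_fraction": miss.mean() if miss.size else 0.0,
        }
    )
    return pd.DataFrame(rows)


def write_results(bundle: Mapping[str, pd.DataFrame], path: str | Path) -> dict:
    """Write a bundle of result tables as CSV plus a JSON manifest.

    File names are deterministic (``<name>.csv`` in sorted-name order), CSVs
    are RFC 4180 UTF-8 with '.' decimal, and the manifest records a SHA-256
    content hash per file.  Writing the same bundle twice is byte-identical.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(bundle):
        fname = f"{name}.csv"
        fpath = outdir / fname
        bundle[name].to_csv(
            fpath, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        entries.append({"name": name, "file": fname, "sha256": digest})
    manifest = {"files": entries}
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
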