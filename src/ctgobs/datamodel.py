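"""Domain types, validation and I/O for observer-performance annotation studies.

A study consists of three tables:

* **cases** — one row per delivery: an opaque ``case_id``, the umbilical cord
  blood pH measured at birth, and the binary ground-truth outcome derived from
  it (``hypoxia`` when pH is strictly below the threshold, 7.15 by default).
* **participants** — one row per annotator: profession, years of experience
  since diploma (with a derived experience band), practice setting and country.
* **annotations** — one row per prediction event: which participant labelled
  which case, the predicted outcome, and the 1-based position of the case in
  that participant's presentation sequence.

All tables are plain UTF-8 CSV with a header row. ``read_study`` validates
referential integrity, uniqueness, pH plausibility and the derived columns;
``write_study`` round-trips a study back to disk field-for-field.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HYPOXIA",
    "NORMAL",
    "OUTCOMES",
    "PROFESSIONS",
    "SETTINGS",
    "EXPERIENCE_BANDS",
    "PH_MIN",
    "PH_MAX",
    "DEFAULT_PH_THRESHOLD",
    "StudyValidationError",
    "CaseRecord",
    "ParticipantRecord",
    "AnnotationRecord",
    "Study",
    "derive_outcome",
    "assign_experience_band",
    "read_study",
    "write_study",
]

HYPOXIA = "hypoxia"
NORMAL = "normal"
OUTCOMES = (HYPOXIA, NORMAL)

PROFESSIONS = ("resident", "midwife", "obstetrician_gynecologist")
SETTINGS = ("university_hospital", "general_hospital")

#: Experience bands are left-closed, right-open: [0, 2), [2, 4), [4, 8), [8, inf).
EXPERIENCE_BANDS = ("0-2", "2-4", "4-8", ">8")
_BAND_EDGES = (2.0, 4.0, 8.0)

#: Plausible umbilical cord blood pH range; values outside are treated as data errors.
PH_MIN, PH_MAX = 6.50, 7.60

#: pH below this threshold defines (moderate) fetal hypoxia.
DEFAULT_PH_THRESHOLD = 7.15


class StudyValidationError(ValueError):
    """Raised when an input table violates a study invariant.

    The message carries row-level context (table, row index, offending values).
    """


def derive_outcome(ph: float, threshold: float = DEFAULT_PH_THRESHOLD) -> str:
    """Binary outcome from cord pH: ``hypoxia`` iff ``ph < threshold``.

    pH exactly equal to the threshold is classed ``normal`` (strict inequality).
    """
    if not (PH_MIN <= ph <= PH_MAX):
        raise StudyValidationError(
            f"pH {ph!r} outside plausible range [{PH_MIN}, {PH_MAX}]"
        )
    return HYPOXIA if ph < threshold else NORMAL


def assign_experience_band(years_experience: float) -> str:
    """Map years of experience to one of the four bands ``0-2, 2-4, 4-8, >8``.

    Intervals are left-closed and right-open, so 2.0 years falls in ``2-4``
    and 8.0 years in ``>8``.
    """
    if years_experience < 0 or not np.isfinite(years_experience):
        raise StudyValidationError(
            f"years_experience must be a finite non-negative number, got {years_experience!r}"
        )
    return EXPERIENCE_BANDS[bisect.bisect_right(_BAND_EDGES, years_experience)]


@dataclass(frozen=True)
class CaseRecord:
    """One delivery: cord pH and the outcome derived from it."""

    case_id: str
    ph: float
    true_outcome: str = field(default="")

    def __post_init__(self):
        derived = derive_outcome(self.ph)
        if self.true_outcome == "":
            object.__setattr__(self, "true_outcome", derived)
        elif self.true_outcome != derived:
            raise StudyValidationError(
                f"case {self.case_id}: stored outcome {self.true_outcome!r} "
                f"contradicts pH {self.ph} (expected {derived!r})"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """One annotator; ``experience_band`` is always derived from the years."""

    participant_id: str
    profession: str
    years_experience: float
    setting: str
    country: str
    is_student: bool = False

    def __post_init__(self):
        if self.profession not in PROFESSIONS:
            raise StudyValidationError(
                f"participant {self.participant_id}: unknown profession {self.profession!r}"
            )
        if self.setting not in SETTINGS:
            raise StudyValidationError(
                f"participant {self.participant_id}: unknown setting {self.setting!r}"
            )
        assign_experience_band(self.years_experience)  # range check

    @property
    def experience_band(self) -> str:
        return assign_experience_band(self.years_experience)


@dataclass(frozen=True)
class AnnotationRecord:
    """One prediction event by one participant on one case."""

    participant_id: str
    case_id: str
    predicted_outcome: str
    presentation_index: int

    def __post_init__(self):
        if self.predicted_outcome not in OUTCOMES:
            raise StudyValidationError(
                f"annotation ({self.participant_id}, {self.case_id}): "
                f"unknown outcome {self.predicted_outcome!r}"
            )
        if self.presentation_index < 1:
            raise StudyValidationError(
                f"annotation ({self.participant_id}, {self.case_id}): "
                f"presentation_index must be >= 1"
            )


_CASE_COLS = ["case_id", "ph", "true_outcome"]
_PARTICIPANT_COLS = [
    "participant_id",
    "profession",
    "years_experience",
    "experience_band",
    "setting",
    "country",
    "is_student",
]
_ANNOTATION_COLS = ["participant_id", "case_id", "predicted_outcome", "presentation_index"]


@dataclass
class Study:
    """A validated annotation study: cases, participants and annotations.

    The three tables are pandas DataFrames with canonical column order; the
    constructor normalises and validates them, so any ``Study`` in memory
    satisfies the invariants (referential integrity, unique ids, pH-consistent
    outcomes, gap-free presentation indices).
    """

    cases: pd.DataFrame
    participants: pd.DataFrame
    annotations: pd.DataFrame
    threshold: float = DEFAULT_PH_THRESHOLD

    def __post_init__(self):
        self.cases = _normalise_cases(self.cases, self.threshold)
        self.participants = _normalise_participants(self.participants)
        self.annotations = _normalise_annotations(
            self.annotations, self.cases, self.participants
        )

    # -- convenience ------------------------------------------------------

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)

    def merged(self) -> pd.DataFrame:
        """Annotations joined with case truth and participant strata.

        Adds a boolean ``correct`` column (prediction matches pH-derived truth);
        this is the working table for every accuracy computation.
        """
        df = self.annotations.merge(
            self.cases[["case_id", "ph", "true_outcome"]], on="case_id", validate="m:1"
        ).merge(
            self.participants[["participant_id", "profession", "experience_band"]],
            on="participant_id",
            validate="m:1",
        )
        df["correct"] = df["predicted_outcome"] == df["true_outcome"]
        return df


def _normalise_cases(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    _require_columns(df, ["case_id", "ph"], "cases")
    df = df.copy()
    df["case_id"] = df["case_id"].astype(str)
    df["ph"] = df["ph"].astype(float)

    bad = df[(df["ph"] < PH_MIN) | (df["ph"] > PH_MAX) | df["ph"].isna()]
    if len(bad):
        row = bad.iloc[0]
        raise StudyValidationError(
            f"cases row {bad.index[0]}: pH {row['ph']} outside [{PH_MIN}, {PH_MAX}] "
            f"(case_id={row['case_id']!r})"
        )
    dup = df["case_id"].duplicated()
    if dup.any():
        raise StudyValidationError(
            f"cases row {df.index[dup][0]}: duplicate case_id {df.loc[dup, 'case_id'].iloc[0]!r}"
        )

    derived = np.where(df["ph"] < threshold, HYPOXIA, NORMAL)
    if "true_outcome" in df.columns and df["true_outcome"].notna().any():
        mismatch = df["true_outcome"].astype(str) != derived
        if mismatch.any():
            i = df.index[mismatch][0]
            raise StudyValidationError(
                f"cases row {i}: stored true_outcome {df.loc[i, 'true_outcome']!r} "
                f"contradicts pH {df.loc[i, 'ph']} at threshold {threshold}"
            )
    df["true_outcome"] = derived
    return df[_CASE_COLS].reset_index(drop=True)


def _normalise_participants(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(
        df, ["participant_id", "profession", "years_experience", "setting", "country"],
        "participants",
    )
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["years_experience"] = df["years_experience"].astype(float)
    if "is_student" not in df.columns:
        df["is_student"] = False
    df["is_student"] = df["is_student"].astype(bool)

    dup = df["participant_id"].duplicated()
    if dup.any():
        raise StudyValidationError(
            f"participants: duplicate participant_id "
            f"{df.loc[dup, 'participant_id'].iloc[0]!r}"
        )
    for i, row in df.iterrows():
        if row["profession"] not in PROFESSIONS:
            raise StudyValidationError(
                f"participants row {i}: unknown profession {row['profession']!r}"
            )
        if row["setting"] not in SETTINGS:
            raise StudyValidationError(
                f"participants row {i}: unknown setting {row['setting']!r}"
            )
        if row["years_experience"] < 0 or not np.isfinite(row["years_experience"]):
            raise StudyValidationError(
                f"participants row {i}: invalid years_experience {row['years_experience']!r}"
            )

    derived = df["years_experience"].map(assign_experience_band)
    if "experience_band" in df.columns and df["experience_band"].notna().any():
        mismatch = df["experience_band"].astype(str) != derived
        if mismatch.any():
            i = df.index[mismatch][0]
            raise StudyValidationError(
                f"participants row {i}: stored experience_band "
                f"{df.loc[i, 'experience_band']!r} contradicts "
                f"years_experience {df.loc[i, 'years_experience']}"
            )
    df["experience_band"] = derived
    return df[_PARTICIPANT_COLS].reset_index(drop=True)


def _normalise_annotations(
    df: pd.DataFrame, cases: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    _require_columns(df, _ANNOTATION_COLS, "annotations")
    df = df.copy()
    if len(df) == 0:
        return pd.DataFrame(columns=_ANNOTATION_COLS).astype(
            {"presentation_index": int}
        )
    df["participant_id"] = df["participant_id"].astype(str)
    df["case_id"] = df["case_id"].astype(str)
    df["presentation_index"] = df["presentation_index"].astype(int)

    known_cases = set(cases["case_id"])
    known_participants = set(participants["participant_id"])
    for i, row in df.iterrows():
        if row["case_id"] not in known_cases:
            raise StudyValidationError(
                f"annotations row {i}: unknown case_id {row['case_id']!r}"
            )
        if row["participant_id"] not in known_participants:
            raise StudyValidationError(
                f"annotations row {i}: unknown participant_id {row['participant_id']!r}"
            )
        if row["predicted_outcome"] not in OUTCOMES:
            raise StudyValidationError(
                f"annotations row {i}: unknown predicted_outcome {row['predicted_outcome']!r}"
            )

    dup = df.duplicated(subset=["participant_id", "case_id"])
    if dup.any():
        i = df.index[dup][0]
        raise StudyValidationError(
            f"annotations row {i}: duplicate (participant_id, case_id) pair "
            f"({df.loc[i, 'participant_id']!r}, {df.loc[i, 'case_id']!r})"
        )

    for pid, grp in df.groupby("participant_id"):
        idx = sorted(grp["presentation_index"])
        if idx != list(range(1, len(idx) + 1)):
            raise StudyValidationError(
                f"annotations: participant {pid!r} presentation_index values {idx[:5]}... "
                f"are not 1..{len(idx)} without gaps"
            )
    return df[_ANNOTATION_COLS].reset_index(drop=True)


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StudyValidationError(f"{table}: missing column(s) {missing}")


def read_study(
    cases_path: str | Path,
    participants_path: str | Path,
    annotations_path: str | Path,
    threshold: float = DEFAULT_PH_THRESHOLD,
) -> Study:
    """Read and validate the three study tables from CSV files.

    Stored ``true_outcome`` / ``experience_band`` columns, when present, are
    validated against the values recomputed from pH and years of experience
    rather than trusted.
    """
    cases = pd.read_csv(cases_path, dtype={"case_id": str})
    participants = pd.read_csv(participants_path, dtype={"participant_id": str})
    annotations = pd.read_csv(
        annotations_path, dtype={"participant_id": str, "case_id": str}
    )
    return Study(cases, participants, annotations, threshold=threshold)


def read_study_dir(study_dir: str | Path, threshold: float = DEFAULT_PH_THRESHOLD) -> Study:
    """Read a study from a directory containing the three canonical CSVs."""
    d = Path(study_dir)
    return read_study(
        d / "cases.csv", d / "participants.csv", d / "annotations.csv", threshold=threshold
    )


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write ``cases.csv``, ``participants.csv`` and ``annotations.csv``.

    Output is deterministic (stable row order and float repr), so writing the
    same study twice yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cases": out / "cases.csv",
        "participants": out / "participants.csv",
        "annotations": out / "annotations.csv",
    }
    study.cases.to_csv(paths["cases"], index=False)
    study.participants.to_csv(paths["participants"], index=False)
    study.annotations.to_csv(paths["annotations"], index=False)
    return paths
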