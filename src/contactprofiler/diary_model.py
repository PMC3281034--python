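"""Domain model for setting-stratified contact diaries.

A contact diary records, for one subject on one survey day under one
recording tool, the locations visited (visits) and the face-to-face
conversational or touch interactions that happened there (encounters).
Each visit carries a duration and two headcounts: the number of people
within arm's reach and the number of people in the whole setting, both
excluding the diarist.

Visits are classified into six setting categories — home, other, retail,
social, travel, work — by the *purpose* of the diarist's presence, not the
venue: someone employed in a shop is at "work", someone visiting a friend's
house is in a "social" setting.

Headcount inconsistencies (more people in reach than in the setting) are a
known feature of self-reported diaries; they are flagged in a validation
report but never rejected, so downstream nesting diagnostics can quantify
them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SettingCategory",
    "RecordingTool",
    "Day",
    "SETTINGS",
    "TOOLS",
    "DAYS",
    "DOMINANT_LABELS",
    "DiaryDataset",
    "ValidationReport",
    "DiaryParseError",
    "DiaryValidationError",
    "classify_setting",
    "read_dataset",
    "write_dataset",
    "PURPOSE_TO_SETTING",
]


class SettingCategory(str, enum.Enum):
    """One of the six location classes, in canonical (alphabetical) order."""

    HOME = "home"
    OTHER = "other"
    RETAIL = "retail"
    SOCIAL = "social"
    TRAVEL = "travel"
    WORK = "work"


class RecordingTool(str, enum.Enum):
    """Diary instrument: pre-entry questionnaire, paper diary, or PDA diary."""

    QUESTIONNAIRE = "questionnaire"
    PAPER = "paper"
    PDA = "pda"


class Day(str, enum.Enum):
    """Survey days of the week."""

    WED = "Wed"
    FRI = "Fri"
    SUN = "Sun"


#: Canonical setting order used for every profile vector in the package.
SETTINGS: tuple[str, ...] = tuple(s.value for s in SettingCategory)
TOOLS: tuple[str, ...] = tuple(t.value for t in RecordingTool)
DAYS: tuple[str, ...] = tuple(d.value for d in Day)

#: Two-letter codes for setting-dominated mixing types (cluster labels).
DOMINANT_LABELS: Mapping[str, str] = {
    "home": "HD",
    "other": "OD",
    "retail": "RD",
    "social": "SD",
    "travel": "TD",
    "work": "WD",
}

SEXES: tuple[str, ...] = ("female", "male")

SUBJECT_COLUMNS = ["subject_id", "age", "sex", "household_size", "n_children"]
VISIT_COLUMNS = [
    "subject_id",
    "day",
    "tool",
    "visit_id",
    "setting",
    "duration_h",
    "n_reach",
    "n_setting",
]
ENCOUNTER_COLUMNS = [
    "subject_id",
    "day",
    "tool",
    "visit_id",
    "contact_id",
    "duration_h",
    "touch",
]

#: Controlled vocabulary mapping presence purpose to setting category.
PURPOSE_TO_SETTING: Mapping[str, SettingCategory] = {
    "working": SettingCategory.WORK,
    "shopping": SettingCategory.RETAIL,
    "visiting-friend": SettingCategory.SOCIAL,
    "residing": SettingCategory.HOME,
    "transiting": SettingCategory.TRAVEL,
    "other": SettingCategory.OTHER,
}


class DiaryParseError(ValueError):
    """A delimited-text diary file could not be parsed into the schema."""


class DiaryValidationError(ValueError):
    """A hard invariant of the diary data model is violated."""


@dataclass
class ValidationReport:
    """Soft-invariant findings collected while validating a dataset.

    ``reach_exceeds_setting`` lists (subject_id, day, tool, visit_id) of
    visits reporting more people within arm's reach than in the whole
    setting.  Such rows are retained for analysis and merely flagged.
    """

    reach_exceeds_setting: list[tuple[str, str, str, str]] = field(
        default_factory=list
    )

    @property
    def n_flagged(self) -> int:
        return len(self.reach_exceeds_setting)


@dataclass
class DiaryDataset:
    """Three aligned tables: subjects, visits and encounters.

    The tables use plain pandas DataFrames with the fixed column sets
    ``SUBJECT_COLUMNS``, ``VISIT_COLUMNS`` and ``ENCOUNTER_COLUMNS``.
    ``validate()`` enforces the hard invariants (referential integrity,
    positive durations, encounter nested in its visit) and returns a
    :class:`ValidationReport` of soft-invariant violations.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame
    encounters: pd.DataFrame

    def __post_init__(self) -> None:
        self.subjects = _coerce(self.subjects, SUBJECT_COLUMNS, "subjects")
        self.visits = _coerce(self.visits, VISIT_COLUMNS, "visits")
        self.encounters = _coerce(self.encounters, ENCOUNTER_COLUMNS, "encounters")

    def validate(self) -> ValidationReport:
        """Check all invariants; raise on hard violations, flag soft ones."""
        subs = self.subjects
        vis = self.visits
        enc = self.encounters

        _require_unique(subs["subject_id"], "subjects", "subject_id")
        _check_range(subs, "subjects", "age", lo=18)
        _check_range(subs, "subjects", "household_size", lo=1)
        _check_range(subs, "subjects", "n_children", lo=0)
        bad_sex = ~subs["sex"].isin(SEXES)
        if bad_sex.any():
            row = int(bad_sex.idxmax())
            raise DiaryParseError(
                f"subjects row {row}: sex {subs.loc[row, 'sex']!r} "
                f"not one of {SEXES}"
            )
        too_many = subs["n_children"] >= subs["household_size"]
        if too_many.any():
            row = int(too_many.idxmax())
            raise DiaryValidationError(
                f"subjects row {row}: n_children must be < household_size"
            )

        _check_codes(vis, "visits", "day", DAYS)
        _check_codes(vis, "visits", "tool", TOOLS)
        _check_codes(vis, "visits", "setting", SETTINGS)
        _check_range(vis, "visits", "duration_h", lo=0, hi=24, strict_lo=True)
        _check_range(vis, "visits", "n_reach", lo=0)
        _check_range(vis, "visits", "n_setting", lo=0)
        _require_known_subjects(vis, "visits", set(subs["subject_id"]))

        vkey = vis[["subject_id", "day", "tool", "visit_id"]]
        if vkey.duplicated().any():
            row = int(vkey.duplicated().idxmax())
            raise DiaryValidationError(
                f"visits row {row}: duplicate visit_id within subject-day-tool"
            )

        _check_codes(enc, "encounters", "day", DAYS)
        _check_codes(enc, "encounters", "tool", TOOLS)
        _check_range(enc, "encounters", "duration_h", lo=0, strict_lo=True)
        _require_known_subjects(enc, "encounters", set(subs["subject_id"]))

        # Every encounter must point at an existing visit of the same
        # subject-day-tool, and fit inside its duration.
        merged = enc.merge(
            vis[["subject_id", "day", "tool", "visit_id", "duration_h"]],
            on=["subject_id", "day", "tool", "visit_id"],
            how="left",
            suffixes=("", "_visit"),
        )
        dangling = merged["duration_h_visit"].isna()
        if dangling.any():
            row = int(dangling.idxmax())
            raise DiaryValidationError(
                f"encounters row {row}: visit_id "
                f"{enc.loc[row, 'visit_id']!r} does not reference an existing "
                "visit of the same subject-day-tool"
            )
        too_long = merged["duration_h"] > merged["duration_h_visit"] + 1e-12
        if too_long.any():
            row = int(too_long.idxmax())
            raise DiaryValidationError(
                f"encounters row {row}: encounter duration "
                f"{enc.loc[row, 'duration_h']} h exceeds its visit's duration"
            )

        report = ValidationReport()
        flagged = vis[vis["n_reach"] > vis["n_setting"]]
        for _, r in flagged.sort_values(
            ["subject_id", "day", "tool", "visit_id"]
        ).iterrows():
            report.reach_exceeds_setting.append(
                (r["subject_id"], r["day"], r["tool"], r["visit_id"])
            )
        return report

    def subject_days(self, tool: str | None = None) -> pd.DataFrame:
        """Distinct (subject_id, day[, tool]) combinations present in visits."""
        cols = ["subject_id", "day"] if tool is not None else ["subject_id", "day", "tool"]
        vis = self.visits
        if tool is not None:
            vis = vis[vis["tool"] == tool]
        return vis[cols].drop_duplicates().reset_index(drop=True)

    def for_tool(self, tool: str) -> "DiaryDataset":
        """Restrict visits and encounters to a single recording tool."""
        if tool not in TOOLS:
            raise DiaryValidationError(f"unknown tool {tool!r}; expected one of {TOOLS}")
        return DiaryDataset(
            subjects=self.subjects.copy(),
            visits=self.visits[self.visits["tool"] == tool].reset_index(drop=True),
            encounters=self.encounters[self.encounters["tool"] == tool].reset_index(
                drop=True
            ),
        )

    def equals(self, other: "DiaryDataset") -> bool:
        return (
            self.subjects.equals(other.subjects)
            and self.visits.equals(other.visits)
            and self.encounters.equals(other.encounters)
        )


def classify_setting(raw_location_label: str, purpose: str) -> SettingCategory:
    """Assign a setting category from the purpose of presence.

    The venue name is deliberately ignored: a shop worker is at "work", a
    friend's house is "social", one's own house is "home".

    Parameters
    ----------
    raw_location_label
        Free-text location as written in the diary (kept for error messages
        only; it does not influence the category).
    purpose
        One of the controlled vocabulary ``PURPOSE_TO_SETTING`` keys:
        working, shopping, visiting-friend, residing, transiting, other.
    """
    try:
        return PURPOSE_TO_SETTING[purpose]
    except KeyError:
        raise DiaryParseError(
            f"unknown purpose {purpose!r} for location {raw_location_label!r}; "
            f"expected one of {sorted(PURPOSE_TO_SETTING)}"
        ) from None


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_INT_COLS = {"age", "household_size", "n_children", "n_reach", "n_setting"}
_FLOAT_COLS = {"duration_h"}
_BOOL_COLS = {"touch"}


def read_dataset(
    visits_path: str | Path,
    encounters_path: str | Path,
    subjects_path: str | Path,
) -> tuple[DiaryDataset, ValidationReport]:
    """Read and validate the three diary CSVs.

    Returns the validated dataset together with the soft-violation report.
    Raises :class:`DiaryParseError` on schema problems (missing columns,
    unknown codes, malformed numbers) and :class:`DiaryValidationError` on
    hard invariant violations, in both cases naming the offending row.
    """
    subjects = _read_table(subjects_path, SUBJECT_COLUMNS, "subjects")
    visits = _read_table(visits_path, VISIT_COLUMNS, "visits")
    encounters = _read_table(encounters_path, ENCOUNTER_COLUMNS, "encounters")
    ds = DiaryDataset(subjects=subjects, visits=visits, encounters=encounters)
    report = ds.validate()
    return ds, report


def write_dataset(dataset: DiaryDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write subjects.csv, visits.csv and encounters.csv under ``out_dir``.

    Column order and row order are preserved, so write→read is the identity
    on valid datasets and identical datasets produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out / "subjects.csv",
        "visits": out / "visits.csv",
        "encounters": out / "encounters.csv",
    }
    dataset.subjects.to_csv(paths["subjects"], index=False, lineterminator="\n")
    dataset.visits.to_csv(paths["visits"], index=False, lineterminator="\n")
    enc = dataset.encounters.copy()
    enc["touch"] = enc["touch"].map({True: "true", False: "false"})
    enc.to_csv(paths["encounters"], index=False, lineterminator="\n")
    return paths


def _read_table(path: str | Path, columns: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DiaryParseError(f"{name} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DiaryParseError(f"{name} file {path}: missing columns {missing}")
    df = df[columns]
    for col in columns:
        if col in _INT_COLS:
            df[col] = _parse_numeric(df[col], name, col, int)
        elif col in _FLOAT_COLS:
            df[col] = _parse_numeric(df[col], name, col, float)
        elif col in _BOOL_COLS:
            lowered = df[col].str.lower()
            bad = ~lowered.isin(["true", "false"])
            if bad.any():
                row = int(bad.idxmax())
                raise DiaryParseError(
                    f"{name} row {row}: column {col!r} value "
                    f"{df.loc[row, col]!r} is not true/false"
                )
            df[col] = lowered == "true"
    return df


def _parse_numeric(series: pd.Series, name: str, col: str, kind: type) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise DiaryParseError(
            f"{name} row {row}: column {col!r} value {series.loc[row]!r} "
            f"is not a valid {kind.__name__}"
        )
    if kind is int:
        frac = (converted % 1) != 0
        if frac.any():
            row = int(frac.idxmax())
            raise DiaryParseError(
                f"{name} row {row}: column {col!r} value {series.loc[row]!r} "
                "is not an integer"
            )
        return converted.astype("int64")
    return converted.astype(float)


def _coerce(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    if df is None or (len(df) == 0 and len(df.columns) == 0):
        df = pd.DataFrame({c: [] for c in columns})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DiaryParseError(f"{name} table: missing columns {missing}")
    df = df[columns].reset_index(drop=True).copy()
    for col in columns:
        if col in _INT_COLS:
            df[col] = df[col].astype("int64")
        elif col in _FLOAT_COLS:
            df[col] = df[col].astype(float)
        elif col in _BOOL_COLS:
            df[col] = df[col].astype(bool)
        else:
            df[col] = df[col].astype(str) if len(df) else df[col].astype(object)
    return df


def _require_unique(series: pd.Series, name: str, col: str) -> None:
    dup = series.duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise DiaryValidationError(
            f"{name} row {row}: duplicate {col} {series.loc[row]!r}"
        )


def _check_codes(df: pd.DataFrame, name: str, col: str, allowed: Iterable[str]) -> None:
    allowed = tuple(allowed)
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(bad.idxmax())
        raise DiaryParseError(
            f"{name} row {row}: {col} {df.loc[row, col]!r} not one of {allowed}"
        )


def _check_range(
    df: pd.DataFrame,
    name: str,
    col: str,
    lo: float | None = None,
    hi: float | None = None,
    strict_lo: bool = False,
) -> None:
    vals = df[col]
    if lo is not None:
        bad = vals <= lo if strict_lo else vals < lo
        if bad.any():
            row = int(bad.idxmax())
            op = ">" if strict_lo else ">="
            raise DiaryParseError(
                f"{name} row {row}: {col} = {vals.loc[row]} must be {op} {lo}"
            )
    if hi is not None:
        bad = vals > hi
        if bad.any():
            row = int(bad.idxmax())
            raise DiaryParseError(
                f"{name} row {row}: {col} = {vals.loc[row]} must be <= {hi}"
            )


def _require_known_subjects(df: pd.DataFrame, name: str, known: set[str]) -> None:
    bad = ~df["subject_id"].isin(known)
    if bad.any():
        row = int(bad.idxmax())
        raise DiaryValidationError(
            f"{name} row {row}: unknown subject_id {df.loc[row, 'subject_id']!r}"
        )
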