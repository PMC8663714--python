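"""Interchange schemas and CSV I/O for the recruitment-analysis tables.

Three tables flow through the pipeline:

* a **campaign schedule** — one row per study day, one column per campaign
  channel, values = that day's campaign intensity;
* a **participant table** — one row per recruit (city, reported recruitment
  method, eligibility date, health-questionnaire date, demographics);
* a **cost ledger** — per (city, method): material cost, transmission cost,
  and counted staff activities.

Validation is total: every malformed cell raises :class:`SchemaError` naming
the row and column, never a silent coercion.  All CSV output is deterministic
(fixed column order, fixed decimal formatting) so repeated runs are diffable.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: The nine campaign channels of the daily-recruitment model, in model order.
CHANNELS: tuple[str, ...] = (
    "letters",
    "paid_fb_reach",
    "unpaid_fb_posts",
    "reminders",
    "partner_comms",
    "snowball",
    "wide_media",
    "small_media",
    "other",
)

CITIES: tuple[str, ...] = ("Montreal", "Saskatoon", "Vancouver")

#: The six recruitment-method categories used by the effectiveness metrics.
METHODS: tuple[str, ...] = (
    "mailed_letters",
    "social_media",
    "news_media",
    "partner_communications",
    "snowball",
    "other",
)

PARTICIPATION_OPTIONS: tuple[str, ...] = (
    "full",
    "app_only",
    "device_only",
    "questionnaires_only",
)
AGE_BANDS: tuple[str, ...] = ("18-34", "35-54", "55-64", "65-88")
GENDERS: tuple[str, ...] = ("man", "woman", "other")
INCOME_BANDS: tuple[str, ...] = (
    "0-49999",
    "50000-99999",
    "100000-149999",
    "150000-199999",
    "200000+",
)
EDUCATION_LEVELS: tuple[str, ...] = (
    "less_than_university",
    "university_degree",
    "graduate_degree",
)
ETHNICITIES: tuple[str, ...] = ("white", "indigenous", "visible_minority")
MAIL_GROUPS: tuple[str, ...] = ("A", "B", "C")

#: Staff activity kinds counted by the cost ledger.
ACTIVITY_KINDS: tuple[str, ...] = (
    "fb_post",
    "in_person_event",
    "media_publication",
    "partner_post",
    "letter_campaign",
    "snowball_campaign",
)

PARTICIPANT_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "city",
    "method",
    "eligibility_date",
    "eligible",
    "health_date",
    "participation_option",
    "age_years",
    "gender",
    "income_band",
    "education",
    "ethnicity",
    "mail_group",
)


class SchemaError(ValueError):
    """A table cell violated its schema; carries row/column coordinates."""

    def __init__(self, message: str, row=None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


@dataclasses.dataclass
class AnalysisConfig:
    """Global configuration: staff wage, currency factor, calendar anchor.

    ``hourly_rate`` has no default on purpose — cost-per-completer figures
    depend on the wage and must be stated explicitly by the analyst.
    """

    hourly_rate: float | None = None
    cad_to_usd: float = 0.7692
    recruitment_start_date: _dt.date | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        start = raw.get("recruitment_start_date")
        if isinstance(start, str):
            start = _dt.date.fromisoformat(start)
        return cls(
            hourly_rate=raw.get("hourly_rate"),
            cad_to_usd=float(raw.get("cad_to_usd", 0.7692)),
            recruitment_start_date=start,
        )

    def to_yaml(self, path) -> None:
        raw = {
            "hourly_rate": self.hourly_rate,
            "cad_to_usd": self.cad_to_usd,
            "recruitment_start_date": (
                self.recruitment_start_date.isoformat()
                if self.recruitment_start_date
                else None
            ),
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# campaign schedule
# ---------------------------------------------------------------------------

def validate_schedule(df: pd.DataFrame, expected_days: int | None = None) -> pd.DataFrame:
    """Validate (and, if needed, zero-fill) a campaign-schedule table.

    Requires a ``day_index`` column plus the nine channel columns; enforces a
    contiguous 0..T-1 day index with no duplicates and nonnegative finite
    intensities.  When ``expected_days`` is given, missing days are filled
    with all-zero rows so sparse event logs can be used directly.
    """
    missing = [c for c in ("day_index", *CHANNELS) if c not in df.columns]
    if missing:
        raise SchemaError(f"schedule is missing columns {missing}")
    df = df.loc[:, ["day_index", *CHANNELS]].copy()

    day = pd.to_numeric(df["day_index"], errors="coerce")
    if day.isna().any():
        raise SchemaError(
            "non-integer day_index",
            row=int(day.index[day.isna()][0]),
            column="day_index",
        )
    if (day % 1 != 0).any():
        raise SchemaError(
            "fractional day_index",
            row=int(day.index[day % 1 != 0][0]),
            column="day_index",
        )
    df["day_index"] = day.astype(int)
    if df["day_index"].duplicated().any():
        dup = int(df.loc[df["day_index"].duplicated(), "day_index"].iloc[0])
        raise SchemaError(f"duplicate day_index {dup}", column="day_index")
    if len(df) and df["day_index"].min() < 0:
        raise SchemaError("negative day_index", column="day_index")

    for col in CHANNELS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            raise SchemaError("non-numeric intensity", row=int(df.index[bad][0]), column=col)
        if (vals < 0).any():
            raise SchemaError("negative intensity", row=int(df.index[vals < 0][0]), column=col)
        df[col] = vals.astype(float)

    n_days = expected_days
    if n_days is None:
        n_days = int(df["day_index"].max()) + 1 if len(df) else 0
    if len(df) and int(df["day_index"].max()) >= n_days:
        raise SchemaError(
            f"day_index {int(df['day_index'].max())} outside expected 0..{n_days - 1}",
            column="day_index",
        )
    full = pd.DataFrame({"day_index": np.arange(n_days, dtype=int)})
    out = full.merge(df, on="day_index", how="left").fillna(0.0)
    out = out.sort_values("day_index").reset_index(drop=True)
    if expected_days is None and len(out) != len(df):
        gap = sorted(set(out["day_index"]) - set(df["day_index"]))[0]
        raise SchemaError(f"day_index not contiguous: missing day {gap}", column="day_index")
    return out


def read_campaign_schedule(path, expected_days: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_schedule(df, expected_days=expected_days)


def write_campaign_schedule(schedule: pd.DataFrame, path) -> None:
    _write_csv(validate_schedule(schedule), path)


# ---------------------------------------------------------------------------
# participant table
# ---------------------------------------------------------------------------

def _check_category(df, col, allowed, allow_missing):
    vals = df[col]
    bad = vals.notna() & ~vals.isin(allowed)
    if bad.any():
        raise SchemaError(
            f"unknown {col} label {vals[bad].iloc[0]!r}",
            row=int(df.index[bad][0]),
            column=col,
        )
    if not allow_missing and vals.isna().any():
        raise SchemaError(f"missing {col}", row=int(df.index[vals.isna()][0]), column=col)


def validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a participant table; returns a normalized copy.

    Adds a derived boolean ``completer`` column (health questionnaire
    completed, i.e. ``health_date`` present).  Dates are calendar dates;
    a ``health_date`` earlier than ``eligibility_date``, or present on an
    ineligible record, is an error naming the participant.
    """
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participant table is missing columns {missing}")
    df = df.loc[:, list(PARTICIPANT_COLUMNS)].copy()
    df = df.replace({"": None}).where(pd.notna(df), None)

    if df["participant_id"].isna().any():
        raise SchemaError("missing participant_id", row=int(df.index[df["participant_id"].isna()][0]), column="participant_id")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise SchemaError(f"duplicate participant_id {dup!r}", column="participant_id")

    _check_category(df, "city", CITIES, allow_missing=False)
    _check_category(df, "method", METHODS, allow_missing=False)
    _check_category(df, "participation_option", PARTICIPATION_OPTIONS, allow_missing=False)
    _check_category(df, "gender", GENDERS, allow_missing=True)
    _check_category(df, "income_band", INCOME_BANDS, allow_missing=True)
    _check_category(df, "education", EDUCATION_LEVELS, allow_missing=True)
    _check_category(df, "ethnicity", ETHNICITIES, allow_missing=True)
    _check_category(df, "mail_group", MAIL_GROUPS, allow_missing=True)

    for col, required in (("eligibility_date", True), ("health_date", False)):
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = df[col].notna() & parsed.isna()
        if bad.any():
            raise SchemaError(f"unparseable {col}", row=int(df.index[bad][0]), column=col)
        if required and parsed.isna().any():
            raise SchemaError(f"missing {col}", row=int(df.index[parsed.isna()][0]), column=col)
        df[col] = parsed.dt.date.where(parsed.notna(), None)

    elig = df["eligible"].map(
        {True: True, False: False, "True": True, "False": False, "true": True, "false": False, 1: True, 0: False}
    )
    if elig.isna().any():
        raise SchemaError("eligible must be boolean", row=int(df.index[elig.isna()][0]), column="eligible")
    df["eligible"] = elig.astype(bool)

    age = pd.to_numeric(df["age_years"], errors="coerce")
    bad = df["age_years"].notna() & (age.isna() | (age < 18) | (age > 120) | (age % 1 != 0))
    if bad.any():
        raise SchemaError("age_years outside 18..120", row=int(df.index[bad][0]), column="age_years")
    df["age_years"] = pd.Series(
        [None if pd.isna(v) else float(v) for v in age], index=df.index, dtype=object
    )

    has_health = df["health_date"].notna()
    early = has_health & (
        pd.to_datetime(df["health_date"][has_health]).reindex(df.index)
        < pd.to_datetime(df["eligibility_date"])
    )
    if early.any():
        pid = df.loc[early, "participant_id"].iloc[0]
        raise SchemaError(
            f"health_date earlier than eligibility_date for participant {pid!r}",
            row=int(df.index[early][0]),
            column="health_date",
        )
    if (has_health & ~df["eligible"]).any():
        pid = df.loc[has_health & ~df["eligible"], "participant_id"].iloc[0]
        raise SchemaError(
            f"ineligible participant {pid!r} has a health_date",
            row=int(df.index[has_health & ~df["eligible"]][0]),
            column="health_date",
        )

    df["completer"] = has_health
    return df.reset_index(drop=True)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    return validate_participants(df)


def write_participants(participants: pd.DataFrame, path) -> None:
    out = participants.loc[:, list(PARTICIPANT_COLUMNS)].copy()
    for col in ("eligibility_date", "health_date"):
        out[col] = out[col].map(lambda d: d.isoformat() if d is not None else "")
    out["eligible"] = out["eligible"].map({True: "True", False: "False"})
    out["age_years"] = out["age_years"].map(lambda a: "" if pd.isna(a) else str(int(a)))
    _write_csv(out.fillna(""), path)


# ---------------------------------------------------------------------------
# cost ledger
# ---------------------------------------------------------------------------

LEDGER_COLUMNS: tuple[str, ...] = ("city", "method", "material_cost", "transmission_cost", *ACTIVITY_KINDS)


@dataclasses.dataclass
class CostLedger:
    """Per (city, method) cost components and counted staff activities.

    ``entries`` holds one row per (city, method) with CAD material and
    transmission costs plus integer activity counts; staff hours are derived
    from the counts by :func:`recruitlag.metrics.staff_hours`.
    """

    entries: pd.DataFrame

    def __post_init__(self):
        df = self.entries
        missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cost ledger is missing columns {missing}")
        df = df.loc[:, list(LEDGER_COLUMNS)].copy()
        _check_category(df, "city", CITIES, allow_missing=False)
        _check_category(df, "method", METHODS, allow_missing=False)
        if df.duplicated(["city", "method"]).any():
            key = df.loc[df.duplicated(["city", "method"]), ["city", "method"]].iloc[0]
            raise SchemaError(f"duplicate ledger entry for {tuple(key)}")
        for col in df.columns[2:]:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise SchemaError("non-numeric cost/count", row=int(df.index[vals.isna()][0]), column=col)
            if (vals < 0).any():
                raise SchemaError("negative cost/count", row=int(df.index[vals < 0][0]), column=col)
            df[col] = vals.astype(float)
        self.entries = df.reset_index(drop=True)

    def lookup(self, city: str, method: str) -> pd.Series | None:
        m = (self.entries["city"] == city) & (self.entries["method"] == method)
        return self.entries[m].iloc[0] if m.any() else None


def read_cost_ledger(path) -> CostLedger:
    return CostLedger(pd.read_csv(path))


def write_cost_ledger(ledger: CostLedger, path) -> None:
    _write_csv(ledger.entries, path)


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path) -> None:
    # fixed float formatting + explicit newline => byte-identical reruns
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result table as ``<out_dir>/<name>.csv``, deterministically."""
    out_dir = Path(out_dir)
    written = []
    for name in sorted(tables):
        df = tables[name]
        path = out_dir / f"{name}.csv"
        if isinstance(df, pd.DataFrame) and isinstance(df.index, pd.MultiIndex):
            df = df.reset_index()
        _write_csv(pd.DataFrame(df), path)
        written.append(path)
    return written
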