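"""Recruitment-effectiveness indicators.

Completion rate is the share of eligible recruits who finished the health
questionnaire; completion delay is the whole-day gap between the eligibility
and health questionnaires; cost per completer sums material, transmission
and staff-time cost for a method and divides by its completers.  Percentages
are displayed rounded half-up to one decimal; internal arithmetic is
unrounded.

Denominator convention for the demographic cross-tab: percentages are of the
method's completer count (missing responses included in the denominator and
reported as their own row), mirroring how such tables are conventionally
printed.
"""

from __future__ import annotations

import dataclasses
import decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .campaign_io import (
    ACTIVITY_KINDS,
    AGE_BANDS,
    CITIES,
    EDUCATION_LEVELS,
    ETHNICITIES,
    GENDERS,
    INCOME_BANDS,
    METHODS,
    CostLedger,
)

GROUP_COLUMNS: dict[str, list[str]] = {
    "method": ["method"],
    "city": ["city"],
    "method_city": ["city", "method"],
    "mail_group": ["mail_group"],
    "participation_option": ["participation_option"],
}

_AGE_EDGES = ((18, 34), (35, 54), (55, 64), (65, 88))


@dataclasses.dataclass(frozen=True)
class StaffTimeSchedule:
    """Staff hours booked per counted recruitment activity."""

    fb_post: float = 0.5
    in_person_event: float = 4.0
    media_publication: float = 2.0
    partner_post: float = 2.0
    letter_campaign: float = 50.0
    snowball_campaign: float = 35.0

    def __post_init__(self):
        for kind in ACTIVITY_KINDS:
            if getattr(self, kind) < 0:
                raise ValueError(f"negative staff hours for {kind}")


DEFAULT_STAFF_HOURS = StaffTimeSchedule()


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    if not np.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _group_cols(group_by) -> list[str]:
    if isinstance(group_by, str):
        try:
            return GROUP_COLUMNS[group_by]
        except KeyError:
            raise ValueError(
                f"unknown group_by {group_by!r}; expected one of {sorted(GROUP_COLUMNS)}"
            ) from None
    return list(group_by)


def age_band(age) -> str | None:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return None
    for lo, hi in _AGE_EDGES:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


def completion_rate(participants: pd.DataFrame, group_by="method") -> pd.DataFrame:
    """Eligible count, completer count and completion rate (%) per group.

    Only eligible records enter the denominator.  Empty groups report an
    absent (NaN) rate, never 0.
    """
    cols = _group_cols(group_by)
    elig = participants[participants["eligible"]]
    grouped = elig.groupby(cols, dropna=True, observed=True)
    out = grouped.agg(
        n_recruited=("participant_id", "size"),
        n_completers=("completer", "sum"),
    ).reset_index()
    out["n_completers"] = out["n_completers"].astype(int)
    out["completion_rate"] = np.where(
        out["n_recruited"] > 0,
        100.0 * out["n_completers"] / out["n_recruited"],
        np.nan,
    )
    return out


def completion_delay(participants: pd.DataFrame, group_by="method") -> pd.DataFrame:
    """Mean and sample SD (n-1) of whole-day completion delays per group.

    Completers only; groups with fewer than two completers report an absent
    SD.
    """
    cols = _group_cols(group_by)
    comp = participants[participants["completer"]].copy()
    comp["delay_days"] = [
        (h - e).days for h, e in zip(comp["health_date"], comp["eligibility_date"])
    ]
    grouped = comp.groupby(cols, dropna=True, observed=True)["delay_days"]
    out = grouped.agg(n_completers="size", delay_mean="mean", delay_sd="std").reset_index()
    out.loc[out["n_completers"] < 2, "delay_sd"] = np.nan
    return out


def staff_hours(
    activities: Mapping[str, float], schedule: StaffTimeSchedule = DEFAULT_STAFF_HOURS
) -> float:
    """Total staff hours for counted activities (dot product with the schedule)."""
    total = 0.0
    for kind, count in activities.items():
        if kind not in ACTIVITY_KINDS:
            raise ValueError(f"unknown activity kind {kind!r}")
        if count < 0:
            raise ValueError(f"negative count for activity {kind!r}")
        total += count * getattr(schedule, kind)
    return total


def pooled_cost_per_completer(values: Sequence[float], completers: Sequence[int]) -> float:
    """Completer-weighted mean of per-cell cost-per-completer values.

    Satisfies the pooling identity: pooled value x total completers equals
    the sum of cell value x cell completers.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(completers, dtype=float)
    if len(v) != len(w):
        raise ValueError("values and completers differ in length")
    if w.sum() <= 0:
        return float("nan")
    return float((v * w).sum() / w.sum())


def cost_per_completer(
    ledger: CostLedger,
    completers: Mapping[tuple[str, str], int] | pd.DataFrame,
    hourly_rate: float,
    cad_to_usd: float = 0.7692,
    staff_schedule: StaffTimeSchedule = DEFAULT_STAFF_HOURS,
) -> pd.DataFrame:
    """Cost per completer by (city, method), with pooled method and city rows.

    Cell cost = material + transmission + staff_hours x hourly_rate; cell
    value = cost / completers.  Cells with zero completers but nonzero cost
    are reported infinite with ``flagged=True`` and excluded from pooled
    rows; zero-cost zero-completer cells are omitted from pooling weights
    naturally.  Pooled rows (``method='total'`` per city, ``city='total'``
    per method, and the overall ``('total','total')``) are completer-weighted
    means of their unflagged cells.  ``completers`` maps (city, method) to
    completer counts (or a DataFrame with columns city, method,
    n_completers).
    """
    if hourly_rate < 0:
        raise ValueError("hourly_rate must be >= 0")
    if isinstance(completers, pd.DataFrame):
        completers = {
            (r["city"], r["method"]): int(r["n_completers"]) for _, r in completers.iterrows()
        }

    rows = []
    for city in CITIES:
        for method in METHODS:
            entry = ledger.lookup(city, method)
            n = int(completers.get((city, method), 0))
            if entry is None and n == 0:
                continue
            if entry is None:
                material = transmission = hours = 0.0
            else:
                material = float(entry["material_cost"])
                transmission = float(entry["transmission_cost"])
                hours = staff_hours({k: float(entry[k]) for k in ACTIVITY_KINDS}, staff_schedule)
            total = material + transmission + hours * hourly_rate
            if n > 0:
                value, flagged = total / n, False
            elif total > 0:
                value, flagged = float("inf"), True
            else:
                value, flagged = float("nan"), False
            rows.append(
                {
                    "city": city,
                    "method": method,
                    "n_completers": n,
                    "cost_total": total,
                    "cost_per_completer": value,
                    "flagged": flagged,
                }
            )
    cells = pd.DataFrame(rows)

    def _pool(sub: pd.DataFrame, city: str, method: str) -> dict:
        ok = sub[~sub["flagged"] & (sub["n_completers"] > 0)]
        n = int(sub["n_completers"].sum())
        value = pooled_cost_per_completer(ok["cost_per_completer"], ok["n_completers"]) if len(ok) else float("nan")
        return {
            "city": city,
            "method": method,
            "n_completers": n,
            "cost_total": float(ok["cost_total"].sum()),
            "cost_per_completer": value,
            "flagged": bool(sub["flagged"].any()),
        }

    pooled = []
    for method in METHODS:
        sub = cells[cells["method"] == method]
        if len(sub):
            pooled.append(_pool(sub, "total", method))
    for city in CITIES:
        sub = cells[cells["city"] == city]
        if len(sub):
            pooled.append(_pool(sub, city, "total"))
    if len(cells):
        pooled.append(_pool(cells, "total", "total"))

    out = pd.concat([cells, pd.DataFrame(pooled)], ignore_index=True)
    out["cost_per_completer_usd"] = out["cost_per_completer"] * cad_to_usd
    return out


_CROSSTAB_DIMENSIONS: dict[str, tuple[str, tuple[str, ...]]] = {
    "age": ("age_band", AGE_BANDS),
    "education": ("education", EDUCATION_LEVELS),
    "gender": ("gender", GENDERS),
    "income": ("income_band", INCOME_BANDS),
    "ethnicity": ("ethnicity", ETHNICITIES),
}


def demographic_crosstab(participants: pd.DataFrame) -> pd.DataFrame:
    """Completer counts and column percentages by recruitment method.

    Long-form table with columns (dimension, category, method, n, pct):
    one block per demographic dimension (age bands, education, gender,
    income bands, ethnicity), categories in fixed display order plus a
    ``missing`` row, methods plus a ``total`` column.  ``pct`` is of the
    method's completer count.
    """
    comp = participants[participants["completer"]].copy()
    comp["age_band"] = comp["age_years"].map(age_band)

    method_totals = {m: int((comp["method"] == m).sum()) for m in METHODS}
    method_totals["total"] = len(comp)

    rows = []
    for dim, (col, categories) in _CROSSTAB_DIMENSIONS.items():
        for category in (*categories, "missing"):
            for method in (*METHODS, "total"):
                sub = comp if method == "total" else comp[comp["method"] == method]
                if category == "missing":
                    n = int(sub[col].isna().sum())
                else:
                    n = int((sub[col] == category).sum())
                denom = method_totals[method]
                rows.append(
                    {
                        "dimension": dim,
                        "category": category,
                        "method": method,
                        "n": n,
                        "pct": 100.0 * n / denom if denom else 0.0,
                    }
                )
    return pd.DataFrame(rows)
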