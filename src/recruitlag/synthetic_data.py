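"""Synthetic recruitment data: stochastic simulators and a deterministic fixture.

Two distinct roles:

* **Stochastic generators** (:func:`generate_schedule`,
  :func:`simulate_recruits`, :func:`simulate_participants`) emulate the
  Montreal arm of a three-city Canadian cohort study: a 199-day recruitment
  period with 151 days of paid Facebook reach (truncated-lognormal reach,
  mean 2770, SD 3558, range 144-20,156), 44 unpaid posts over 34 days, one
  mailed-letter and one reminder campaign, 18 partner communications, 2
  wide-reach and 6 smaller-reach media events, one snowball campaign and 16
  other events.  Daily recruit counts are generated from the distributed-lag
  model with the published coefficient estimates as truth; participant
  records draw methods, completion, delays and demographics from the
  published marginal distributions.  Everything is reproducible from a seed.

* **A deterministic fixture** (:func:`build_fixture`) enumerates a
  participant table and cost ledger whose marginal counts equal the study's
  printed tables cell by cell (2318 recruits, 1791 completers; city,
  method, demographic and participation-option margins), so the metric
  suite can be exercised without any external data.  Fixture delays are
  arbitrary valid constants; only counts are meaningful.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math

import numpy as np
import pandas as pd

from .campaign_io import (
    AGE_BANDS,
    CHANNELS,
    CITIES,
    EDUCATION_LEVELS,
    ETHNICITIES,
    GENDERS,
    INCOME_BANDS,
    MAIL_GROUPS,
    METHODS,
    PARTICIPATION_OPTIONS,
    CostLedger,
    LEDGER_COLUMNS,
    validate_participants,
    validate_schedule,
)
from .lag_features import LagSpec, build_design

# ---------------------------------------------------------------------------
# Published summary tables of the study (used as simulation targets and
# fixture margins).  All counts verified to be internally consistent.
# ---------------------------------------------------------------------------

#: Recruits (eligibility questionnaire completed) per method, all cities.
METHOD_RECRUITED: dict[str, int] = {
    "mailed_letters": 319,
    "social_media": 944,
    "news_media": 284,
    "partner_communications": 264,
    "snowball": 167,
    "other": 340,
}

#: Health-questionnaire completers per method, all cities.
METHOD_COMPLETERS: dict[str, int] = {
    "mailed_letters": 282,
    "social_media": 687,
    "news_media": 230,
    "partner_communications": 218,
    "snowball": 121,
    "other": 253,
}

#: Completion-delay mean and SD per method (days).
DELAY_MEAN_SD: dict[str, tuple[float, float]] = {
    "mailed_letters": (9.1, 29.9),
    "social_media": (14.3, 37.7),
    "news_media": (11.8, 34.6),
    "partner_communications": (13.8, 31.4),
    "snowball": (9.6, 28.6),
    "other": (10.6, 25.8),
}

#: Completers per (city, method) — the cost table's cell denominators.
COMPLETERS_BY_CITY_METHOD: dict[str, dict[str, int]] = {
    "Montreal": {
        "mailed_letters": 148, "social_media": 503, "news_media": 226,
        "partner_communications": 91, "snowball": 81, "other": 109,
    },
    "Saskatoon": {
        "mailed_letters": 0, "social_media": 88, "news_media": 4,
        "partner_communications": 126, "snowball": 18, "other": 79,
    },
    "Vancouver": {
        "mailed_letters": 134, "social_media": 96, "news_media": 0,
        "partner_communications": 1, "snowball": 22, "other": 65,
    },
}

#: Recruits per (city, method).  City and method margins are printed
#: (1536/402/380 by city, METHOD_RECRUITED by method); the within-city split
#: of non-completers is not, so cells were allocated once, proportionally to
#: completers, and frozen here.  Montreal mailed letters carries the three
#: printed mail-group sizes (75+88+8 = 171 recruits).
RECRUITED_BY_CITY_METHOD: dict[str, dict[str, int]] = {
    "Montreal": {
        "mailed_letters": 171, "social_media": 698, "news_media": 278,
        "partner_communications": 116, "snowball": 114, "other": 159,
    },
    "Saskatoon": {
        "mailed_letters": 10, "social_media": 117, "news_media": 6,
        "partner_communications": 147, "snowball": 23, "other": 99,
    },
    "Vancouver": {
        "mailed_letters": 138, "social_media": 129, "news_media": 0,
        "partner_communications": 1, "snowball": 30, "other": 82,
    },
}

#: Completer demographic counts per method (columns follow METHODS order).
#: Remaining completers per method are missing responses for that dimension.
DEMOGRAPHICS: dict[str, dict[str, tuple[int, ...]]] = {
    "age": {
        "18-34": (10, 238, 44, 108, 58, 56),
        "35-54": (91, 273, 74, 47, 34, 75),
        "55-64": (89, 95, 62, 17, 11, 29),
        "65-88": (92, 48, 46, 13, 12, 39),
    },
    "education": {
        "less_than_university": (94, 142, 26, 63, 21, 74),
        "university_degree": (85, 259, 90, 79, 51, 82),
        "graduate_degree": (100, 282, 113, 70, 49, 94),
    },
    "gender": {
        "man": (120, 144, 84, 67, 45, 81),
        "woman": (161, 537, 144, 149, 75, 170),
        "other": (0, 3, 2, 2, 0, 2),
    },
    "income": {
        "0-49999": (50, 200, 36, 87, 31, 82),
        "50000-99999": (79, 212, 91, 38, 41, 56),
        "100000-149999": (49, 122, 49, 33, 20, 45),
        "150000-199999": (29, 53, 19, 14, 9, 22),
        "200000+": (33, 40, 15, 15, 10, 13),
    },
    "ethnicity": {
        "white": (246, 591, 217, 155, 93, 195),
        "indigenous": (2, 10, 0, 5, 1, 11),
        "visible_minority": (31, 81, 11, 55, 23, 42),
    },
}

_DIMENSION_COLUMN = {
    "age": "age_years",
    "education": "education",
    "gender": "gender",
    "income": "income_band",
    "ethnicity": "ethnicity",
}
_DIMENSION_CATEGORIES = {
    "age": AGE_BANDS,
    "education": EDUCATION_LEVELS,
    "gender": GENDERS,
    "income": INCOME_BANDS,
    "ethnicity": ETHNICITIES,
}
#: Representative integer age per band (fixture + simulator store ages, not bands).
AGE_BAND_REPRESENTATIVE = {"18-34": 26, "35-54": 44, "55-64": 60, "65-88": 76}

#: Overall missing-response counts per dimension (of 1791 completers).
MISSING_COUNTS: dict[str, int] = {
    "age": 130, "education": 17, "gender": 5, "income": 198, "ethnicity": 22,
}

#: Participation options per city: (recruits, completers) per option.
PARTICIPATION: dict[str, dict[str, tuple[int, int]]] = {
    "Montreal": {
        "full": (937, 744), "app_only": (277, 201),
        "device_only": (0, 0), "questionnaires_only": (322, 213),
    },
    "Saskatoon": {
        "full": (225, 179), "app_only": (67, 56),
        "device_only": (13, 9), "questionnaires_only": (97, 71),
    },
    "Vancouver": {
        "full": (161, 134), "app_only": (68, 51),
        "device_only": (72, 68), "questionnaires_only": (79, 65),
    },
}

#: Montreal mailed-letter arm sizes: personalized letter + reminder (A),
#: personalized letter only (B), nonpersonalized postcard only (C).
MAIL_GROUP_SIZES: dict[str, int] = {"A": 75, "B": 88, "C": 8}

#: Printed cost per completer (CAD) per (city, method); None = no campaign.
COST_PER_COMPLETER_CAD: dict[str, dict[str, float | None]] = {
    "Montreal": {
        "mailed_letters": 130.80, "social_media": 13.35, "news_media": 6.17,
        "partner_communications": 7.32, "snowball": 16.40, "other": 18.05,
    },
    "Saskatoon": {
        "mailed_letters": None, "social_media": 16.13, "news_media": 74.04,
        "partner_communications": 0.88, "snowball": 0.0, "other": 21.60,
    },
    "Vancouver": {
        "mailed_letters": 83.56, "social_media": 22.91, "news_media": None,
        "partner_communications": 347.10, "snowball": 59.80, "other": 72.70,
    },
}

#: Printed average cost per completer per city (CAD).  These are the study's
#: own summary values; they are not the completer-weighted means of the
#: printed method cells (a documented inconsistency of the source tables).
CITY_COST_PER_COMPLETER_CAD: dict[str, float] = {
    "Montreal": 26.52, "Saskatoon": 10.85, "Vancouver": 23.80,
}

#: Distributed-lag model truth used by the simulators: the published
#: coefficient estimates (recruits per campaign event; per log-unit of
#: reach/1000 for paid Facebook reach) and intercept.
TRUE_INTERCEPT: float = 4.3
TRUE_BETA: dict[str, float] = {
    "letters": 106.5,
    "paid_fb_reach": 1.4,
    "unpaid_fb_posts": 3.2,
    "reminders": 16.9,
    "partner_comms": 3.5,
    "snowball": 2.5,
    "wide_media": 163.6,
    "small_media": 10.4,
    "other": -1.3,
}

CITY_START_DATES: dict[str, _dt.date] = {
    "Montreal": _dt.date(2018, 6, 6),
    "Saskatoon": _dt.date(2018, 9, 19),
    "Vancouver": _dt.date(2018, 4, 20),
}
CITY_PERIOD_DAYS: dict[str, int] = {"Montreal": 199, "Saskatoon": 108, "Vancouver": 123}


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD (moment match)."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclasses.dataclass
class SimConfig:
    """Montreal-like simulation conditions (defaults = the study's campaign log)."""

    T: int = 199
    n_paid_days: int = 151
    paid_reach_mean: float = 2770.0
    paid_reach_sd: float = 3558.0
    paid_reach_min: float = 144.0
    paid_reach_max: float = 20156.0
    contiguity: float = 0.9  # share of paid days kept in one contiguous block
    n_unpaid_posts: int = 44
    n_unpaid_days: int = 34
    n_letters: int = 1
    n_reminders: int = 1
    reminder_offset_days: int = 14  # reminder postcard mailed two weeks after letters
    n_partner: int = 18
    n_wide_media: int = 2
    n_small_media: int = 6
    n_snowball: int = 1
    n_other: int = 16
    alpha: float = TRUE_INTERCEPT
    beta: dict[str, float] = dataclasses.field(default_factory=lambda: dict(TRUE_BETA))
    lag_spec: LagSpec = dataclasses.field(default_factory=LagSpec.published)
    noise: str = "gaussian"  # or "poisson"
    sigma: float = 2.0
    recruitment_start_date: _dt.date = _dt.date(2018, 6, 6)

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        for name in ("n_paid_days", "n_unpaid_days", "n_partner", "n_wide_media",
                     "n_small_media", "n_snowball", "n_other", "n_letters", "n_reminders"):
            if getattr(self, name) > self.T:
                raise ValueError(f"{name}={getattr(self, name)} exceeds T={self.T} days")
        if self.n_unpaid_posts < self.n_unpaid_days:
            raise ValueError("n_unpaid_posts must be >= n_unpaid_days")
        if self.noise not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise family {self.noise!r}")
        if not 0.0 <= self.contiguity <= 1.0:
            raise ValueError("contiguity must be in [0, 1]")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def truncated_lognormal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Lognormal samples moment-matched to (mean, sd), rejected outside [lo, hi].

    Calibration matches moments *before* truncation; the truncated sample
    mean sits slightly below the target (documented behaviour).
    """
    mu, sig = lognormal_params(mean, sd)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sig, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_schedule(config: SimConfig | None = None, seed=0) -> pd.DataFrame:
    """Draw a synthetic Montreal-like campaign schedule.

    Event days are uniform without replacement per channel, with two
    realism constraints: paid-reach days form a contiguous block with a
    ``1 - contiguity`` fraction swapped to random days, and the reminder
    campaign follows the letter campaign by ``reminder_offset_days`` (the
    letter day is drawn early enough to leave room for the reminder and a
    15-day lag window where possible).
    """
    config = config or SimConfig()
    rng = _as_rng(seed)
    T = config.T
    sched = pd.DataFrame({"day_index": np.arange(T, dtype=int)})
    for ch in CHANNELS:
        sched[ch] = 0.0

    # paid reach: contiguous-biased day set, truncated-lognormal intensities
    n_paid = config.n_paid_days
    if n_paid > 0:
        start = int(rng.integers(0, T - n_paid + 1))
        block = set(range(start, start + n_paid))
        n_swap = int(round((1.0 - config.contiguity) * n_paid))
        outside = np.array(sorted(set(range(T)) - block), dtype=int)
        n_swap = min(n_swap, len(outside))
        if n_swap > 0:
            drop = rng.choice(sorted(block), size=n_swap, replace=False)
            add = rng.choice(outside, size=n_swap, replace=False)
            block = (block - set(drop.tolist())) | set(add.tolist())
        days = np.array(sorted(block), dtype=int)
        sched.loc[days, "paid_fb_reach"] = truncated_lognormal(
            rng, n_paid, config.paid_reach_mean, config.paid_reach_sd,
            config.paid_reach_min, config.paid_reach_max,
        )

    # unpaid posts: n_unpaid_days distinct days sharing n_unpaid_posts posts
    if config.n_unpaid_days > 0:
        days = rng.choice(T, size=config.n_unpaid_days, replace=False)
        counts = np.ones(config.n_unpaid_days)
        extra = config.n_unpaid_posts - config.n_unpaid_days
        if extra > 0:
            counts += rng.multinomial(extra, np.full(config.n_unpaid_days, 1.0 / config.n_unpaid_days))
        sched.loc[np.sort(days), "unpaid_fb_posts"] = counts[np.argsort(days)]

    # letters + reminder: letter day early enough for the reminder to land in-period
    if config.n_letters == 1:
        latest = max(T - config.reminder_offset_days - 16, 1)
        letter_day = int(rng.integers(0, min(latest, T)))
        sched.loc[letter_day, "letters"] = 1.0
        if config.n_reminders == 1:
            sched.loc[min(letter_day + config.reminder_offset_days, T - 1), "reminders"] = 1.0
    else:
        for ch, k in (("letters", config.n_letters), ("reminders", config.n_reminders)):
            if k > 0:
                days = rng.choice(T, size=k, replace=False)
                sched.loc[np.sort(days), ch] = 1.0

    for ch, k in (
        ("partner_comms", config.n_partner),
        ("wide_media", config.n_wide_media),
        ("small_media", config.n_small_media),
        ("snowball", config.n_snowball),
        ("other", config.n_other),
    ):
        if k > 0:
            days = rng.choice(T, size=k, replace=False)
            sched.loc[np.sort(days), ch] = 1.0

    return validate_schedule(sched)


def simulate_recruits(schedule: pd.DataFrame, config: SimConfig | None = None, seed=0) -> pd.DataFrame:
    """Daily recruit counts from the distributed-lag model used generatively.

    The linear predictor is built with the *true* lag configuration
    (``config.lag_spec``); counts are Poisson(max(eta, 0.01)) or
    round(max(Normal(eta, sigma), 0)) depending on ``config.noise``.
    """
    config = config or SimConfig()
    rng = _as_rng(seed)
    schedule = validate_schedule(schedule)
    design = build_design(schedule, config.lag_spec)
    coef = np.array(
        [config.alpha] + [config.beta[ch] for ch in CHANNELS], dtype=float
    )
    eta = np.asarray(design, dtype=float) @ coef
    if config.noise == "poisson":
        y = rng.poisson(np.maximum(eta, 0.01))
    else:
        y = np.round(np.maximum(rng.normal(eta, config.sigma), 0.0)).astype(int)
    return pd.DataFrame({"day_index": schedule["day_index"], "recruits": y.astype(int)})


def _method_probs() -> np.ndarray:
    total = sum(METHOD_RECRUITED.values())
    return np.array([METHOD_RECRUITED[m] / total for m in METHODS])


def _demographic_sampler(dim: str) -> tuple[list, np.ndarray, float]:
    """Per-method category probabilities for one dimension + global missing rate."""
    categories = list(_DIMENSION_CATEGORIES[dim])
    counts = np.array([DEMOGRAPHICS[dim][c] for c in categories], dtype=float)  # cat x method
    probs = counts / counts.sum(axis=0, keepdims=True)
    miss = MISSING_COUNTS[dim] / sum(METHOD_COMPLETERS.values())
    return categories, probs, miss


def simulate_participants(daily: pd.DataFrame, config: SimConfig | None = None, seed=0) -> pd.DataFrame:
    """Participant-level records for a simulated daily recruit series.

    Each recruit gets a method (multinomial over the published recruited
    shares), a completer flag (Bernoulli at the method's completion rate),
    a whole-day lognormal delay calibrated to the method's delay mean/SD,
    and demographics drawn per method from the published completer
    distributions, with missingness at the published overall rates applied
    uniformly across methods.
    """
    config = config or SimConfig()
    rng = _as_rng(seed)
    days = np.repeat(daily["day_index"].to_numpy(), daily["recruits"].to_numpy().astype(int))
    n = len(days)
    if n == 0:
        return validate_participants(
            pd.DataFrame(columns=[
                "participant_id", "city", "method", "eligibility_date", "eligible",
                "health_date", "participation_option", "age_years", "gender",
                "income_band", "education", "ethnicity", "mail_group",
            ])
        )

    method_idx = rng.choice(len(METHODS), size=n, p=_method_probs())
    methods = np.array(METHODS, dtype=object)[method_idx]
    rates = np.array([METHOD_COMPLETERS[m] / METHOD_RECRUITED[m] for m in METHODS])
    completer = rng.random(n) < rates[method_idx]

    mu_sig = np.array([lognormal_params(*DELAY_MEAN_SD[m]) for m in METHODS])
    delays = np.round(
        rng.lognormal(mu_sig[method_idx, 0], mu_sig[method_idx, 1])
    ).astype(int)

    start = config.recruitment_start_date
    elig = np.array([start + _dt.timedelta(days=int(d)) for d in range(int(days.max()) + 1)], dtype=object)[days]
    health = np.where(
        completer,
        [e + _dt.timedelta(days=int(d)) for e, d in zip(elig, delays)],
        None,
    )

    opt_rec = np.array([PARTICIPATION["Montreal"][o][0] for o in PARTICIPATION_OPTIONS], dtype=float)
    options = rng.choice(np.array(PARTICIPATION_OPTIONS, dtype=object), size=n, p=opt_rec / opt_rec.sum())

    groups = np.full(n, None, dtype=object)
    letters = methods == "mailed_letters"
    gp = np.array([MAIL_GROUP_SIZES[g] for g in MAIL_GROUPS], dtype=float)
    groups[letters] = rng.choice(np.array(MAIL_GROUPS, dtype=object), size=int(letters.sum()), p=gp / gp.sum())

    df = pd.DataFrame(
        {
            "participant_id": [f"SIM-{i:06d}" for i in range(n)],
            "city": "Montreal",
            "method": methods,
            "eligibility_date": elig,
            "eligible": True,
            "health_date": health,
            "participation_option": options,
        }
    )
    for dim in DEMOGRAPHICS:
        cats, probs, miss = _demographic_sampler(dim)
        values = np.full(n, None, dtype=object)
        for j, m in enumerate(METHODS):
            sel = np.flatnonzero(method_idx == j)
            if len(sel) == 0:
                continue
            drawn = rng.choice(len(cats), size=len(sel), p=probs[:, j])
            filled = np.array(
                [AGE_BAND_REPRESENTATIVE[cats[k]] if dim == "age" else cats[k] for k in drawn],
                dtype=object,
            )
            filled[rng.random(len(sel)) < miss] = None
            values[sel] = filled
        df[_DIMENSION_COLUMN[dim]] = values
    df["mail_group"] = groups
    return validate_participants(df)


# ---------------------------------------------------------------------------
# deterministic fixture
# ---------------------------------------------------------------------------

class FixtureConsistencyError(ValueError):
    """The fixture specification violates a marginal identity."""


@dataclasses.dataclass
class FixtureSpec:
    """Marginal counts the deterministic fixture must reproduce exactly."""

    recruited: dict[str, dict[str, int]] = dataclasses.field(
        default_factory=lambda: {c: dict(RECRUITED_BY_CITY_METHOD[c]) for c in CITIES}
    )
    completers: dict[str, dict[str, int]] = dataclasses.field(
        default_factory=lambda: {c: dict(COMPLETERS_BY_CITY_METHOD[c]) for c in CITIES}
    )
    demographics: dict[str, dict[str, tuple[int, ...]]] = dataclasses.field(
        default_factory=lambda: {d: dict(v) for d, v in DEMOGRAPHICS.items()}
    )
    participation: dict[str, dict[str, tuple[int, int]]] = dataclasses.field(
        default_factory=lambda: {c: dict(PARTICIPATION[c]) for c in CITIES}
    )
    mail_groups: dict[str, int] = dataclasses.field(default_factory=lambda: dict(MAIL_GROUP_SIZES))
    cost_cells: dict[str, dict[str, float | None]] = dataclasses.field(
        default_factory=lambda: {c: dict(COST_PER_COMPLETER_CAD[c]) for c in CITIES}
    )
    delay_days: dict[str, int] = dataclasses.field(
        default_factory=lambda: {m: int(round(DELAY_MEAN_SD[m][0])) for m in METHODS}
    )

    def validate(self) -> None:
        def fail(identity: str):
            raise FixtureConsistencyError(f"fixture spec inconsistent: {identity}")

        for city in CITIES:
            for m in METHODS:
                if self.completers[city][m] > self.recruited[city][m]:
                    fail(f"completers > recruited in ({city}, {m})")
        total_rec = sum(self.recruited[c][m] for c in CITIES for m in METHODS)
        total_comp = sum(self.completers[c][m] for c in CITIES for m in METHODS)
        if total_rec != 2318:
            fail(f"total recruited {total_rec} != 2318")
        if total_comp != 1791:
            fail(f"total completers {total_comp} != 1791")
        for city, expect in (("Montreal", 1158), ("Saskatoon", 315), ("Vancouver", 318)):
            got = sum(self.completers[city].values())
            if got != expect:
                fail(f"{city} completers {got} != {expect}")
        for city in CITIES:
            for which, table in (("recruited", self.recruited), ("completers", self.completers)):
                got = sum(table[city].values())
                want = sum(v[0 if which == "recruited" else 1] for v in self.participation[city].values())
                if got != want:
                    fail(f"{city} {which} {got} != participation-option sum {want}")
        for dim, cats in self.demographics.items():
            col_sums = np.array(list(cats.values())).sum(axis=0)
            for j, m in enumerate(METHODS):
                total_m = sum(self.completers[c][m] for c in CITIES)
                if col_sums[j] > total_m:
                    fail(f"{dim} counts for {m} exceed its {total_m} completers")
        if sum(self.mail_groups.values()) != self.recruited["Montreal"]["mailed_letters"]:
            fail(
                f"mail groups sum {sum(self.mail_groups.values())} != Montreal mailed-letter "
                f"recruits {self.recruited['Montreal']['mailed_letters']}"
            )


def build_fixture(spec: FixtureSpec | None = None) -> tuple[pd.DataFrame, CostLedger]:
    """Enumerate the deterministic participant table and back-solved cost ledger.

    Participants are listed city by city, method by method, completers first,
    with dates spread evenly over each city's recruitment period and delays
    set to the per-method constant.  Demographic categories are assigned
    blockwise per method so every printed cell count is matched exactly;
    participation options are assigned blockwise per city separately among
    completers and non-completers so the per-option completion table is
    matched too.  The ledger's material costs are back-solved as
    ``printed cost-per-completer x completers`` with zero staff activities,
    so the printed cost cells are reproduced without inventing a wage.
    """
    spec = spec or FixtureSpec()
    spec.validate()

    rows: list[dict] = []
    for city in CITIES:
        period = CITY_PERIOD_DAYS[city]
        start = CITY_START_DATES[city]
        for method in METHODS:
            n_rec = spec.recruited[city][method]
            n_comp = spec.completers[city][method]
            delay = spec.delay_days[method]
            for i in range(n_rec):
                day = (i * (period - 1)) // max(n_rec - 1, 1)
                elig = start + _dt.timedelta(days=day)
                is_comp = i < n_comp
                rows.append(
                    {
                        "participant_id": f"{city[:3].upper()}-{method}-{i + 1:04d}",
                        "city": city,
                        "method": method,
                        "eligibility_date": elig,
                        "eligible": True,
                        "health_date": elig + _dt.timedelta(days=delay) if is_comp else None,
                        "participation_option": None,
                        "age_years": None,
                        "gender": None,
                        "income_band": None,
                        "education": None,
                        "ethnicity": None,
                        "mail_group": None,
                        "_completer": is_comp,
                    }
                )
    df = pd.DataFrame(rows)

    # demographics: blockwise over each method's completers (construction order)
    for dim, cats in spec.demographics.items():
        col = _DIMENSION_COLUMN[dim]
        for j, method in enumerate(METHODS):
            idx = df.index[(df["method"] == method) & df["_completer"]]
            values: list = []
            for cat in _DIMENSION_CATEGORIES[dim]:
                n = cats[cat][j]
                fill = AGE_BAND_REPRESENTATIVE[cat] if dim == "age" else cat
                values.extend([fill] * n)
            values.extend([None] * (len(idx) - len(values)))
            df.loc[idx, col] = pd.Series(values, index=idx, dtype=object)

    # participation options: blockwise per city, completers and non-completers apart
    for city in CITIES:
        for flag in (True, False):
            idx = df.index[(df["city"] == city) & (df["_completer"] == flag)]
            values = []
            for opt in PARTICIPATION_OPTIONS:
                rec, comp = spec.participation[city][opt]
                values.extend([opt] * (comp if flag else rec - comp))
            df.loc[idx, "participation_option"] = pd.Series(values, index=idx, dtype=object)

    # mail groups: blockwise over Montreal mailed-letter recruits
    idx = df.index[(df["city"] == "Montreal") & (df["method"] == "mailed_letters")]
    values = []
    for g in MAIL_GROUPS:
        values.extend([g] * spec.mail_groups[g])
    df.loc[idx, "mail_group"] = pd.Series(values, index=idx, dtype=object)

    participants = validate_participants(df.drop(columns=["_completer"]))

    ledger_rows = []
    for city in CITIES:
        for method in METHODS:
            value = spec.cost_cells[city][method]
            if value is None:
                continue
            n_comp = spec.completers[city][method]
            row = {c: 0.0 for c in LEDGER_COLUMNS[2:]}
            row.update(
                city=city, method=method, material_cost=value * n_comp, transmission_cost=0.0
            )
            ledger_rows.append(row)
    ledger = CostLedger(pd.DataFrame(ledger_rows, columns=list(LEDGER_COLUMNS)))
    return participants, ledger
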