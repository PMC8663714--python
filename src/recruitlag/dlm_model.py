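"""Fitting and lag selection for the daily-recruitment distributed-lag model.

The model for the number of recruits on study day ``d`` is the linear
regression

    y_d = alpha + sum_k beta_k * z_k(d) + e_d

where each ``z_k`` is the lag-distributed (and, for paid reach, semilog-
transformed) intensity of campaign channel ``k`` built by
:mod:`recruitlag.lag_features`.  Estimation is ordinary least squares with a
Gaussian likelihood; 95% confidence intervals use the t distribution with
``n - p`` degrees of freedom.  AIC and BIC are computed from the full
Gaussian log-likelihood with ``k = p + 1`` parameters (the error variance is
counted); only criterion *differences* matter for lag selection, so the
convention is a documentation choice, not a modelling one.

Because every lag kernel sums to one, the coefficient on an identity channel
is the total number of recruits attributable to one unit campaign event, and
its per-day profile is ``beta * w_j`` over the lag window
(:func:`campaign_effect`).  The semilog channel instead admits a
proportional-change reading: a fractional reach increase ``delta`` changes
predicted recruitment by approximately ``beta * ln(1 + delta)``
(:func:`proportional_effect`).

Lag-length selection scans candidate lags per channel and retains the
configuration minimizing AIC, with deterministic tie-breaking (lower BIC,
then the smaller lag).  The default ``profile_then_descend`` strategy is
coordinate-wise: starting from lag 2 everywhere, each channel in turn is
profiled over the candidate range holding the others fixed, repeating passes
until no lag changes.  A full factorial search over nine channels and 15
lags is astronomically large; the coordinate search reproduces the same
per-channel criterion curves at tractable cost.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .campaign_io import CHANNELS, validate_schedule
from .lag_features import (
    ChannelSpec,
    LagSpec,
    column_name,
    distribute_lags,
    kernel_weights,
    semilog_transform,
)

# SSR per observation below this is treated as a perfect (degenerate) fit.
_PERFECT_FIT_TOL = 1e-12
# absolute tolerance when comparing information criteria for ties
_CRIT_TIE_TOL = 1e-6


@dataclasses.dataclass
class DlmFit:
    """OLS fit of the distributed-lag recruitment model."""

    terms: list[str]
    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    resid: np.ndarray
    r2: float
    adj_r2: float
    llf: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    sigma2: float

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table with columns (term, estimate, se, ci_low, ci_high, p)."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": self.ci_low.to_numpy(),
                "ci_high": self.ci_high.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


def _gaussian_criteria(ssr: float, n: int, p: int) -> tuple[float, float, float]:
    """(llf, aic, bic) for an OLS fit; k = p + 1 counts the error variance."""
    k = p + 1
    if ssr / n < _PERFECT_FIT_TOL:
        # degenerate perfect fit: likelihood unbounded above
        return math.inf, -math.inf, -math.inf
    llf = -0.5 * n * (math.log(2.0 * math.pi * ssr / n) + 1.0)
    return llf, -2.0 * llf + 2.0 * k, -2.0 * llf + k * math.log(n)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns dropped by rank-revealing QR (the collinear set)."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_dlm(design: pd.DataFrame, y) -> DlmFit:
    """Fit the daily-recruitment model by ordinary least squares.

    ``design`` is the matrix from :func:`recruitlag.lag_features.build_design`
    (or any intercept-plus-regressors frame); ``y`` is the daily recruit
    series, aligned by row.  Raises on rank deficiency (naming the collinear
    columns) and when there are no residual degrees of freedom.
    """
    X = np.asarray(design, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(yv) != n:
        raise ValueError(f"y has length {len(yv)}, design has {n} rows")
    if n <= p:
        raise ValueError(f"n_obs={n} must exceed n_params={p}")
    if not np.isfinite(X).all():
        raise ValueError("design contains non-finite cells")
    if np.linalg.matrix_rank(X) < p:
        cols = _collinear_columns(X, list(design.columns))
        raise ValueError(f"design is rank deficient; collinear columns: {cols}")

    res = sm.OLS(yv, X).fit()
    names = list(design.columns)
    ci = res.conf_int(alpha=0.05)  # t distribution, n - p dof
    llf, aic, bic = _gaussian_criteria(float(res.ssr), n, p)
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss > 0:
        r2 = 1.0 - float(res.ssr) / tss
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    else:  # constant outcome: no variance to explain
        r2, adj_r2 = 0.0, 0.0
    return DlmFit(
        terms=names,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        ci_low=pd.Series(ci[:, 0], index=names),
        ci_high=pd.Series(ci[:, 1], index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        fitted=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
        r2=r2,
        adj_r2=adj_r2,
        llf=llf,
        aic=aic,
        bic=bic,
        n_obs=n,
        n_params=p,
        sigma2=float(res.ssr) / (n - p),
    )


def predict_daily(fit: DlmFit, design: pd.DataFrame) -> np.ndarray:
    """Predicted daily recruits for a (possibly new) design matrix.

    Values from the linear model may be negative; they are reported
    unclipped.
    """
    if list(design.columns) != fit.terms:
        raise ValueError(
            f"design columns {list(design.columns)} do not match fit terms {fit.terms}"
        )
    return np.asarray(design, dtype=float) @ fit.params.to_numpy()


# ---------------------------------------------------------------------------
# campaign effects
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CampaignEffect:
    """Total recruits per unit event and its per-day profile."""

    channel: str
    total: float
    profile: np.ndarray  # beta * w_j, length = lag


def _term_for(fit: DlmFit, spec: LagSpec, channel: str) -> str:
    name = column_name(channel, spec[channel])
    if name not in fit.terms:
        raise ValueError(f"fit has no term {name!r} for channel {channel!r}")
    return name


def campaign_effect(fit: DlmFit, spec: LagSpec, channel: str) -> CampaignEffect:
    """Recruits attributable to one unit event on an identity channel.

    Kernel weights sum to one, so the total incremental recruits per unit
    event equals the coefficient itself; the per-day profile is
    ``beta * w_j``.  The semilog channel has no additive per-event reading —
    use :func:`proportional_effect` instead.
    """
    cs = spec[channel]
    if cs.transform != "identity":
        raise ValueError(
            f"channel {channel!r} is semilog-transformed; its coefficient scales with "
            "proportional reach changes - use proportional_effect()"
        )
    beta = float(fit.params[_term_for(fit, spec, channel)])
    w = kernel_weights(cs.lag, cs.kernel)
    return CampaignEffect(channel=channel, total=beta, profile=beta * w)


def proportional_effect(fit: DlmFit, spec: LagSpec, channel: str, delta: float) -> float:
    """Approximate recruit change for a fractional increase of a semilog channel.

    For a ``delta`` proportional increase in lagged reach the linear
    predictor changes by ``beta * ln(1 + delta)`` (exact under the log, an
    approximation of the average daily effect once lag truncation and
    zero-exposure days are considered).
    """
    cs = spec[channel]
    if cs.transform != "log_per_1000":
        raise ValueError(f"channel {channel!r} is not semilog-transformed")
    if delta <= -1:
        raise ValueError("delta must be > -1")
    beta = float(fit.params[_term_for(fit, spec, channel)])
    return beta * math.log1p(delta)


# ---------------------------------------------------------------------------
# lag-length selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LagSearchResult:
    spec: LagSpec
    table: pd.DataFrame  # columns: channel, lag, aic, bic, r2, adj_r2
    fit: DlmFit
    converged: bool
    n_passes: int
    active_channels: list[str]


def _criteria_fast(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(aic, bic, r2, adj_r2) by direct least squares; used by the lag search.

    Same quantities as :func:`fit_dlm` without standard errors; a unit test
    pins the two paths together.
    """
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    _, aic, bic = _gaussian_criteria(ssr, n, p)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss > 0:
        r2 = 1.0 - ssr / tss
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    else:
        r2, adj_r2 = 0.0, 0.0
    return aic, bic, r2, adj_r2


def _better(cand: tuple[float, float], best: tuple[float, float]) -> bool:
    """Strictly better by (AIC, then BIC) with a tie tolerance.

    Candidates are visited in increasing lag order, so "not better" keeps the
    smaller lag on ties.
    """
    ca, cb = cand
    ba, bb = best
    if ca == ba:  # handles matched infinities exactly
        aic_tie = True
    elif math.isinf(ca) or math.isinf(ba):
        aic_tie = False
    else:
        aic_tie = abs(ca - ba) <= _CRIT_TIE_TOL
    if not aic_tie:
        return ca < ba
    if cb == bb:
        return False
    if math.isinf(cb) or math.isinf(bb):
        return cb < bb
    return cb < bb - _CRIT_TIE_TOL


class _LaggedColumns:
    """Precomputed lag-distributed columns for every (channel, lag) pair."""

    def __init__(self, schedule: pd.DataFrame, lags: Sequence[int], kernel: str, zero_mode: str):
        self.lags = list(lags)
        self.cols: dict[str, dict[int, np.ndarray]] = {}
        for ch in CHANNELS:
            x = schedule[ch].to_numpy()
            per = {}
            for s in self.lags:
                col = distribute_lags(x, s, kernel)
                if ch == "paid_fb_reach":
                    col = semilog_transform(col, zero_mode=zero_mode)
                per[s] = col
            self.cols[ch] = per

    def design(self, channels: Sequence[str], lags: Mapping[str, int], n: int) -> np.ndarray:
        out = np.empty((n, len(channels) + 1))
        out[:, 0] = 1.0
        for j, ch in enumerate(channels, start=1):
            out[:, j] = self.cols[ch][lags[ch]]
        return out


def select_lags(
    schedule: pd.DataFrame,
    y,
    lag_range: Iterable[int] = range(1, 16),
    strategy: str = "profile_then_descend",
    candidate_sets: Mapping[str, Iterable[int]] | None = None,
    kernel: str = "uniform",
    zero_mode: str = "zero",
    max_passes: int = 5,
    init_lag: int = 2,
) -> LagSearchResult:
    """Choose a lag length per channel by AIC, with BIC / smaller-lag tie-breaks.

    ``profile_then_descend`` (default): start every channel at ``init_lag``;
    cycle through channels, profiling each over ``lag_range`` with the others
    held fixed and keeping the AIC-minimizing lag; repeat until a full pass
    changes nothing or ``max_passes`` is reached (then return best-so-far
    with ``converged=False`` and a warning).

    ``exhaustive_capped``: full factorial over ``candidate_sets`` (a mapping
    channel -> candidate lags; channels omitted keep ``init_lag``).

    Channels with all-zero intensity carry no information about their own
    lag: they are excluded from the fitted design, keep the smallest
    candidate lag, and are listed outside ``active_channels``.  The emitted
    ``table`` holds every (channel, lag) candidate evaluated with its AIC,
    BIC and (adjusted) R².
    """
    schedule = validate_schedule(schedule)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(schedule)
    if len(yv) != n:
        raise ValueError(f"y has length {len(yv)}, schedule has {n} days")
    lag_range = sorted(set(int(s) for s in lag_range))

    pre = _LaggedColumns(schedule, lag_range, kernel, zero_mode)
    active = [ch for ch in CHANNELS if (schedule[ch].to_numpy() != 0).any()]
    lags: dict[str, int] = {ch: (init_lag if ch in active else lag_range[0]) for ch in CHANNELS}
    rows: list[tuple] = []
    converged = True
    n_passes = 0

    if strategy == "profile_then_descend":
        for n_passes in range(1, max_passes + 1):
            changed = False
            for ch in active:
                best_lag, best_key = None, None
                for s in lag_range:
                    trial = dict(lags, **{ch: s})
                    aic, bic, r2, adj = _criteria_fast(pre.design(active, trial, n), yv)
                    rows.append((n_passes, ch, s, aic, bic, r2, adj))
                    if best_key is None or _better((aic, bic), best_key):
                        best_lag, best_key = s, (aic, bic)
                if best_lag != lags[ch]:
                    lags[ch] = best_lag
                    changed = True
            if not changed:
                break
        else:
            converged = False
            warnings.warn(
                f"lag search did not settle within {max_passes} passes; "
                "returning best configuration found",
                stacklevel=2,
            )
    elif strategy == "exhaustive_capped":
        if candidate_sets is None:
            raise ValueError("exhaustive_capped requires candidate_sets")
        grid_channels = [ch for ch in CHANNELS if ch in candidate_sets and ch in active]
        grids = [sorted(set(int(s) for s in candidate_sets[ch])) for ch in grid_channels]
        total = int(np.prod([len(g) for g in grids])) if grids else 1
        if total > 200_000:
            raise ValueError(f"exhaustive grid of {total} combinations exceeds the cap")
        best_key, best_lags = None, None
        for combo in itertools.product(*grids):
            trial = dict(lags)
            trial.update(zip(grid_channels, combo))
            aic, bic, r2, adj = _criteria_fast(pre.design(active, trial, n), yv)
            for ch, s in zip(grid_channels, combo):
                rows.append((1, ch, s, aic, bic, r2, adj))
            if best_key is None or _better((aic, bic), best_key):
                best_key, best_lags = (aic, bic), dict(trial)
        lags = best_lags
        n_passes = 1
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    spec = LagSpec(
        {
            ch: ChannelSpec(
                lag=lags[ch],
                kernel=kernel,
                transform="log_per_1000" if ch == "paid_fb_reach" else "identity",
            )
            for ch in CHANNELS
        }
    )
    final_design = pd.DataFrame(
        pre.design(active, lags, n),
        columns=["intercept"] + [column_name(ch, spec[ch]) for ch in active],
        index=schedule["day_index"].to_numpy(),
    )
    fit = fit_dlm(final_design, yv)
    table = pd.DataFrame(
        rows, columns=["pass", "channel", "lag", "aic", "bic", "r2", "adj_r2"]
    )
    return LagSearchResult(
        spec=spec,
        table=table,
        fit=fit,
        converged=converged,
        n_passes=n_passes,
        active_channels=active,
    )
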