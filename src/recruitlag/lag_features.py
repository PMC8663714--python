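"""Finite distributed-lag features for daily campaign-event regressors.

A campaign event on day ``d`` is assumed to influence recruitment over a
finite window of ``s`` days starting on the event day, with nonnegative
weights ``w_0..w_{s-1}`` summing to one.  Each channel's daily intensity
series is therefore replaced by its lag-weighted convolution, and — for the
paid-reach channel, whose natural scale is thousands of persons — by the
natural log of the lag-weighted reach per 1000, so the coefficient measures
recruits per log-unit (i.e. per proportional change) of reach.

Because the weights sum to one, the regression coefficient on an
identity-transformed channel is directly interpretable as the *total*
number of recruits attributable to one unit campaign event, spread over the
lag window.

Conventions (documented so results are reproducible):

* the lag window *includes* the event day (``j = 0``): same-day recruitment
  from a campaign exposure is allowed;
* the log transform is applied *after* lag-weighting (log of the lagged
  variable);
* days with zero lagged exposure contribute 0 to the semilog regressor
  ("no campaign" adds nothing to the linear predictor); ``log1p`` handling
  is available as an alternative via ``zero_mode``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .campaign_io import CHANNELS, validate_schedule

KERNELS = ("uniform", "linear_decay")
TRANSFORMS = ("identity", "log_per_1000")

MIN_LAG, MAX_LAG = 1, 15

#: Lag lengths retained by the Montreal analysis, per channel (days).
PUBLISHED_LAGS: dict[str, int] = {
    "letters": 15,
    "paid_fb_reach": 2,
    "unpaid_fb_posts": 2,
    "reminders": 5,
    "partner_comms": 2,
    "snowball": 4,
    "wide_media": 2,
    "small_media": 2,
    "other": 4,
}


@dataclasses.dataclass(frozen=True)
class ChannelSpec:
    """Lag length, weight kernel and transform for one campaign channel."""

    lag: int
    kernel: str = "uniform"
    transform: str = "identity"

    def __post_init__(self):
        if not (MIN_LAG <= self.lag <= MAX_LAG):
            raise ValueError(f"lag length {self.lag} outside {MIN_LAG}..{MAX_LAG}")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclasses.dataclass
class LagSpec:
    """Per-channel :class:`ChannelSpec` covering all nine channels."""

    channels: dict[str, ChannelSpec]

    def __post_init__(self):
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"LagSpec missing channels {missing}")

    def __getitem__(self, channel: str) -> ChannelSpec:
        return self.channels[channel]

    @classmethod
    def published(cls, kernel: str = "uniform") -> "LagSpec":
        """The retained Montreal configuration: published lags, semilog paid reach."""
        return cls(
            {
                ch: ChannelSpec(
                    lag=PUBLISHED_LAGS[ch],
                    kernel=kernel,
                    transform="log_per_1000" if ch == "paid_fb_reach" else "identity",
                )
                for ch in CHANNELS
            }
        )

    @classmethod
    def uniform(cls, lag: int, kernel: str = "uniform", semilog_paid: bool = True) -> "LagSpec":
        """Same lag for every channel (the search's starting point)."""
        return cls(
            {
                ch: ChannelSpec(
                    lag=lag,
                    kernel=kernel,
                    transform="log_per_1000" if (semilog_paid and ch == "paid_fb_reach") else "identity",
                )
                for ch in CHANNELS
            }
        )

    def replace(self, channel: str, lag: int) -> "LagSpec":
        new = dict(self.channels)
        new[channel] = dataclasses.replace(new[channel], lag=lag)
        return LagSpec(new)

    @classmethod
    def from_yaml(cls, path) -> "LagSpec":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            {
                ch: ChannelSpec(
                    lag=int(v["lag"]),
                    kernel=v.get("kernel", "uniform"),
                    transform=v.get("transform", "identity"),
                )
                for ch, v in raw.items()
            }
        )

    def to_yaml(self, path) -> None:
        raw = {
            ch: {"lag": cs.lag, "kernel": cs.kernel, "transform": cs.transform}
            for ch, cs in ((c, self.channels[c]) for c in CHANNELS)
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def kernel_weights(s: int, kernel: str = "uniform") -> np.ndarray:
    """Nonnegative lag weights of length ``s`` summing to one.

    ``uniform`` gives ``1/s`` each day; ``linear_decay`` gives weights
    proportional to ``(s, s-1, ..., 1)``.
    """
    if s < 1:
        raise ValueError(f"lag length must be >= 1, got {s}")
    if kernel == "uniform":
        return np.full(s, 1.0 / s)
    if kernel == "linear_decay":
        raw = np.arange(s, 0, -1, dtype=float)
        return raw / raw.sum()
    raise ValueError(f"unknown kernel {kernel!r}")


def distribute_lags(intensity, s: int, kernel: str = "uniform") -> np.ndarray:
    """Spread each day's intensity over the following ``s``-day lag window.

    ``out[d] = sum_j w_j * intensity[d - j]`` for ``j = 0..s-1`` (terms with
    ``d - j < 0`` dropped).  Total mass is conserved except for truncation at
    the end of the series: an event within ``s-1`` days of the last day has
    part of its window cut off.
    """
    x = np.asarray(intensity, dtype=float)
    if x.ndim != 1:
        raise ValueError("intensity must be a 1-d series")
    if (x < 0).any():
        raise ValueError("intensity must be nonnegative")
    w = kernel_weights(s, kernel)
    return np.convolve(x, w)[: len(x)]


def semilog_transform(lagged_reach, scale: float = 1000.0, zero_mode: str = "zero") -> np.ndarray:
    """``ln(lagged_reach / scale)`` with an explicit zero-exposure convention.

    ``zero_mode="zero"`` (default) maps zero-exposure days to 0 so they
    contribute nothing to the linear predictor; ``zero_mode="log1p"`` uses
    ``log1p(lagged_reach / scale)`` everywhere instead.
    """
    z = np.asarray(lagged_reach, dtype=float)
    if (z < 0).any():
        raise ValueError("lagged reach must be nonnegative")
    if zero_mode == "log1p":
        return np.log1p(z / scale)
    if zero_mode != "zero":
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    out = np.zeros_like(z)
    pos = z > 0
    out[pos] = np.log(z[pos] / scale)
    return out


def column_name(channel: str, spec: ChannelSpec) -> str:
    tag = "_log" if spec.transform == "log_per_1000" else ""
    return f"{channel}{tag}_lag{spec.lag}"


def build_design(schedule: pd.DataFrame, spec: LagSpec, zero_mode: str = "zero") -> pd.DataFrame:
    """Assemble the regression design: intercept + one lagged column per channel.

    For the semilog channel the column is
    ``semilog_transform(distribute_lags(x, s))``; for identity channels it is
    ``distribute_lags(x, s)``.  Column names carry channel, transform and lag
    metadata, e.g. ``paid_fb_reach_log_lag2``.
    """
    schedule = validate_schedule(schedule)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(schedule))}
    for ch in CHANNELS:
        cs = spec[ch]
        lagged = distribute_lags(schedule[ch].to_numpy(), cs.lag, cs.kernel)
        if cs.transform == "log_per_1000":
            lagged = semilog_transform(lagged, zero_mode=zero_mode)
        cols[column_name(ch, cs)] = lagged
    design = pd.DataFrame(cols, index=schedule["day_index"].to_numpy())
    design.index.name = "day_index"
    return design
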