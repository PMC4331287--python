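"""Daily food intake from body mass, via seasonal mass/intake ratios.

Field data on Nile crocodiles across ontogeny yield season-specific constants
for the ratio of body mass to mean daily food intake on the log10 scale:

    log10(BM / daily intake) = 2.151   (growing season)
    log10(BM / daily intake) = 2.592   (non-growing season)

so daily intake is ``BM / 10**c`` and, equivalently, ``10**c`` is the number
of days the animal takes to consume its own body mass at that season's rate.
Intake is therefore linear in body mass, and days-to-consume-body-mass is a
constant of the season, independent of size — a strong assumption when
extrapolated to multi-tonne animals, and used here as a first appraisal only.

Reporting convention: seasonal intakes are quoted in kg/day at 1-decimal
precision (half-up), the mean rate is the mean of the two quoted rates, and
the day counts divide body mass by the quoted rates — the arithmetic chain
that such figures are conventionally derived from. Full-precision values are
kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["IntakeConstants", "IntakeEstimate", "daily_intake", "intake_summary"]

#: log10(body mass / daily intake) during the growing season.
LOG_RATIO_GROWING = 2.151
#: log10(body mass / daily intake) during the non-growing season.
LOG_RATIO_NONGROWING = 2.592


@dataclass(frozen=True)
class IntakeConstants:
    """Seasonal log10 mass-to-intake ratios (dimensionally, log10 of days)."""

    log_ratio_growing: float = LOG_RATIO_GROWING
    log_ratio_nongrowing: float = LOG_RATIO_NONGROWING

    def __post_init__(self) -> None:
        if self.log_ratio_growing <= 0 or self.log_ratio_nongrowing <= 0:
            raise ValueError("seasonal log-ratios must be positive")
        if self.log_ratio_nongrowing < self.log_ratio_growing:
            raise ValueError(
                "non-growing season must have the larger log-ratio "
                "(slower intake off-season)"
            )

    @property
    def days_ratio(self) -> float:
        """Exact ratio of slow-season to fast-season days, 10**(c2 - c1)."""
        return 10.0 ** (self.log_ratio_nongrowing - self.log_ratio_growing)


@dataclass(frozen=True)
class IntakeEstimate:
    """Seasonal daily intakes and days-to-consume-own-body-mass.

    ``intake_*`` are full-precision kg/day; ``reported_*`` are the 1-decimal
    quoted values (half-up), with ``reported_mean`` the mean of the two
    quoted rates. ``days_fast``/``days_slow`` are whole days at the quoted
    growing/non-growing rates.
    """

    bm: float
    intake_growing: float
    intake_nongrowing: float
    intake_mean: float
    reported_growing: float
    reported_nongrowing: float
    reported_mean: float
    days_fast: int
    days_slow: int

    def __post_init__(self) -> None:
        if not (
            self.intake_nongrowing <= self.intake_mean <= self.intake_growing
        ):
            raise ValueError("intake_mean must lie between the seasonal rates")
        if self.days_fast > self.days_slow:
            raise ValueError("days_fast must not exceed days_slow")


def _half_up_tenths(x: float) -> int:
    """Round to the nearest tenth, half away from zero, as integer tenths."""
    return math.floor(x * 10.0 + 0.5)


def daily_intake(bm: float, log_ratio: float) -> float:
    """Mean daily food intake (kg/day) for body mass ``bm`` (kg).

    ``log_ratio`` is the seasonal constant log10(BM / intake); the result is
    ``bm / 10**log_ratio``.
    """
    bm = float(bm)
    if not math.isfinite(bm) or bm <= 0:
        raise ValueError("body mass must be strictly positive and finite")
    return bm / 10.0**log_ratio


def intake_summary(
    bm: float, constants: IntakeConstants | None = None
) -> IntakeEstimate:
    """Full seasonal intake summary for one body mass (kg).

    Quoted (1-decimal) rates and their mean are computed in integer tenths so
    half-up rounding is exact; day counts divide body mass by the quoted
    rates and round half-up to whole days.
    """
    constants = constants or IntakeConstants()
    fast = daily_intake(bm, constants.log_ratio_growing)
    slow = daily_intake(bm, constants.log_ratio_nongrowing)
    fast_tenths = _half_up_tenths(fast)
    slow_tenths = _half_up_tenths(slow)
    # mean of the two quoted rates, half-up, still in exact tenths
    mean_tenths = (fast_tenths + slow_tenths + 1) // 2
    # a rate quoting to 0.0 kg/day cannot anchor a day count; fall back to
    # the full-precision rate (only reachable for sub-15 kg body masses)
    days_fast = (
        float(bm) * 10.0 / fast_tenths if fast_tenths else bm / fast
    )
    days_slow = (
        float(bm) * 10.0 / slow_tenths if slow_tenths else bm / slow
    )
    return IntakeEstimate(
        bm=float(bm),
        intake_growing=fast,
        intake_nongrowing=slow,
        intake_mean=(fast + slow) / 2.0,
        reported_growing=fast_tenths / 10.0,
        reported_nongrowing=slow_tenths / 10.0,
        reported_mean=mean_tenths / 10.0,
        days_fast=int(math.floor(days_fast + 0.5)),
        days_slow=int(math.floor(days_slow + 0.5)),
    )
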