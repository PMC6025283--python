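"""Research-area lifetime: three-year Time Periods built backwards from Y_last.

A research area's lifetime is measured from its annual publication counts.
Starting at the newest complete calendar year ``Y_last``, consecutive
``window_years``-year windows are formed backwards in time; a window is an
eligible Time Period when its annual average publication count strictly
exceeds ``min_avg`` (default 10 — the level at which research in a field
can be said to have begun).  Scanning stops at the first ineligible window,
so the lifetime is a single contiguous span of N periods, relabelled so the
oldest eligible window is T1 and the newest (ending at Y_last) is TN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping

from .corpus_io import Corpus

__all__ = ["LifetimeConfig", "TimePeriod", "annual_counts", "build_time_periods", "default_y_last"]


@dataclass(frozen=True)
class LifetimeConfig:
    """Parameters of the lifetime measurement.

    ``mode`` is reserved for a rolling-year variant whose anchor convention
    is not yet settled; only calendar mode is implemented.
    """

    y_last: int
    window_years: int = 3
    min_avg: float = 10.0
    mode: str = "calendar"

    def __post_init__(self) -> None:
        if self.window_years < 1:
            raise ValueError("window_years must be >= 1")
        if self.min_avg < 0:
            raise ValueError("min_avg must be >= 0")
        if self.mode != "calendar":
            raise NotImplementedError(
                f"mode {self.mode!r} is reserved but not implemented; use 'calendar'"
            )


@dataclass(frozen=True)
class TimePeriod:
    """One eligible window.  ``index`` is 1 for the oldest period, N for the
    newest; ``annual_counts`` runs oldest year first."""

    index: int
    start_year: int
    end_year: int
    annual_counts: tuple[int, ...]

    @property
    def avg_count(self) -> float:
        """Unrounded annual average; display rounding is one decimal."""
        return sum(self.annual_counts) / len(self.annual_counts)

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


def annual_counts(corpus: Corpus | Iterable) -> dict[int, int]:
    """Publication count per calendar year; absent years are simply absent
    (query with ``.get(year, 0)``)."""
    return dict(Counter(r.year for r in corpus))


def default_y_last(counts: Mapping[int, int]) -> int:
    """Newest year present in the counts.

    Callers working from a live retrieval should pass the most recent
    COMPLETE calendar year explicitly: a partial current year understates
    the final period's average.
    """
    if not counts:
        raise ValueError("empty counts: no year to anchor Y_last")
    return max(counts)


def build_time_periods(
    counts: Mapping[int, int], config: LifetimeConfig
) -> list[TimePeriod]:
    """Eligible Time Periods, oldest first.

    Walks backwards from ``y_last`` in steps of ``window_years`` and stops
    at the FIRST window whose average is <= ``min_avg`` (strict-inequality
    eligibility).  An eligible window older than an ineligible one is
    discarded: the lifetime is contiguous by definition.  Returns an empty
    list when even the newest window is ineligible.
    """
    w = config.window_years
    periods_newest_first: list[tuple[int, int, tuple[int, ...]]] = []
    end = config.y_last
    min_year = min(counts, default=config.y_last)
    while end >= min_year:
        start = end - w + 1
        window = tuple(counts.get(y, 0) for y in range(start, end + 1))
        if sum(window) / w <= config.min_avg:
            break
        periods_newest_first.append((start, end, window))
        end = start - 1

    n = len(periods_newest_first)
    return [
        TimePeriod(index=n - i, start_year=start, end_year=end, annual_counts=window)
        for i, (start, end, window) in enumerate(periods_newest_first)
    ][::-1]


def lifetime_years(periods: list[TimePeriod]) -> int:
    """Total span of the eligible periods in calendar years."""
    return sum(p.end_year - p.start_year + 1 for p in periods)
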