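"""Partial calendar dates as they occur in FAERS date fields.

FAERS dates are plain digit strings: ``YYYYMMDD``, ``YYYYMM`` or ``YYYY``.
A partial date keeps whatever precision was reported; only full-precision
dates take part in day arithmetic (time-to-onset), everything else is
tagged so downstream code can exclude it explicitly rather than silently
coercing e.g. ``202001`` to January 1st.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date of day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @property
    def is_full(self) -> bool:
        return self.day is not None

    def to_date(self) -> datetime.date:
        if not self.is_full:
            raise ValueError(f"partial date {self} has no day component")
        return datetime.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple:
        # Missing components sort before any real value: a partial date
        # loses ties against a full one in the dedup ordering.
        return (self.year, self.month or 0, self.day or 0)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_date(raw: str) -> Optional[PartialDate]:
    """Parse a FAERS date string; return None when unparseable/empty.

    Accepts 8-digit (day), 6-digit (month) and 4-digit (year) forms and
    validates that the components form a real calendar date.
    """
    s = (raw or "").strip()
    if not s or not s.isdigit():
        return None
    try:
        if len(s) == 8:
            d = datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
            return PartialDate(d.year, d.month, d.day)
        if len(s) == 6:
            y, m = int(s[:4]), int(s[4:6])
            if not 1 <= m <= 12:
                return None
            return PartialDate(y, m)
        if len(s) == 4:
            return PartialDate(int(s))
    except ValueError:
        return None
    return None


def days_between(start: Optional[PartialDate], end: Optional[PartialDate]) -> Optional[int]:
    """Whole days from start to end; None unless both are full-precision."""
    if start is None or end is None or not start.is_full or not end.is_full:
        return None
    return (end.to_date() - start.to_date()).days


MIN_SORT_KEY = (0, 0, 0)


def date_sort_key(d: Optional[PartialDate]) -> tuple:
    """Sort key treating a missing/unparseable date as minimal."""
    return d.sort_key() if d is not None else MIN_SORT_KEY
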