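"""Calendar helpers shared across the package.

All durations are integer days; "month" as a reporting unit is the fixed
mean Gregorian month so that binning is deterministic and independent of
which calendar months a difference happens to span.
"""
from __future__ import annotations

import calendar
import datetime

#: Mean Gregorian month in days, used whenever day counts are expressed in months.
MONTH_DAYS = 30.4375


def add_months(d: datetime.date, months: int) -> datetime.date:
    """Calendar-month addition with day-of-month clamped to the month end.

    ``2008-08-31 + 6 months`` is ``2009-02-28`` (``-02-29`` in a leap year):
    the day is clamped rather than rolled over into the next month.
    """
    month_index = d.year * 12 + (d.month - 1) + months
    year, month = divmod(month_index, 12)
    month += 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return datetime.date(year, month, day)


def parse_date(text: str) -> datetime.date:
    """Parse an ISO-8601 calendar date (YYYY-MM-DD)."""
    return datetime.date.fromisoformat(text)


def midpoint(start: datetime.date, end: datetime.date) -> datetime.date:
    """Midpoint of a closed date window: ``start + floor((end - start)/2)`` days."""
    return start + datetime.timedelta(days=(end - start).days // 2)
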