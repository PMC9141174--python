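"""Season definitions for the seasonal AOD-PM2.5 models.

The season table follows the study design this pipeline implements: spring =
March-May, summer = June-August, autumn = September and November, winter =
February and December. January and October are unmapped — in the source
monitoring campaign those months had no usable cloud-free coverage — and
records falling in them are excluded by season-aware stages.
"""

from __future__ import annotations

import datetime as _dt

SEASONS = ("spring", "summer", "autumn", "winter")

SEASON_OF_MONTH: dict[int, str] = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 11: "autumn",
    2: "winter", 12: "winter",
}

#: months belonging to each season, in calendar order within the season
MONTHS_OF_SEASON: dict[str, tuple[int, ...]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 11),
    "winter": (2, 12),
}


def season_of_month(month: int) -> str | None:
    """Season label for a calendar month, or None if the month is unmapped."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return SEASON_OF_MONTH.get(month)


def season_of_date(date: _dt.date | str) -> str | None:
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return season_of_month(date.month)
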