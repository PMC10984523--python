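"""Calendar conventions shared across the package.

Month index 0 is January 2018. All series are monthly and 0-based, and
windows are half-open ``[start, end)``.
"""

from __future__ import annotations

ORIGIN_YEAR = 2018


def month_index(label: str) -> int:
    """Convert an ISO ``YYYY-MM`` label to a 0-based month index."""
    year_s, _, month_s = label.partition("-")
    year, month = int(year_s), int(month_s)
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month in label {label!r}")
    return (year - ORIGIN_YEAR) * 12 + (month - 1)


def month_label(index: int) -> str:
    """Convert a 0-based month index to an ISO ``YYYY-MM`` label."""
    year, month = divmod(index, 12)
    return f"{ORIGIN_YEAR + year:04d}-{month + 1:02d}"


def year_start(year: int) -> int:
    """Month index of January of a calendar year."""
    return (year - ORIGIN_YEAR) * 12


def year_window(first_year: int, last_year: int) -> tuple[int, int]:
    """Half-open month-index window covering ``first_year``..``last_year`` inclusive."""
    return year_start(first_year), year_start(last_year + 1)


def year_of_month(index: int) -> int:
    return ORIGIN_YEAR + index // 12
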