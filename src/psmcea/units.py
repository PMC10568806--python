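"""Time-unit conventions.

All internal times are days. Calendar months and years convert at the
average Gregorian lengths so that mixed week/month/year inputs cannot
drift against each other.
"""

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25
DAYS_PER_WEEK = 7.0


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


def years_to_days(years: float) -> float:
    return years * DAYS_PER_YEAR


def days_to_years(days: float) -> float:
    return days / DAYS_PER_YEAR
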