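"""Expected rescue values by age band and gender.

The per-person "expected rescue value" is a dimensionless score of the
capacity to rescue a trapped neighbour (e.g. pull a survivor from rubble),

    expected value = strength x executing rate x activity rate,

tabulated by decade age band and gender.  Strength is normalised so that a
man in his teens-to-twenties scores 1; the executing rate reflects the
fraction of people who actually performed rescue work after the 1995
Hanshin-Awaji earthquake; the activity rate is the gender share of residents
available for rescue activity in each band.  Elementary and junior-high
school children (and anyone who themselves needs evacuation assistance)
contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "RescueRateRow",
    "RescueRateTable",
    "DEFAULT_RATE_TABLE",
    "DEFAULT_ELIGIBILITY_AGE",
    "expected_value",
    "round_half_up",
]

#: Youngest age at which a resident counts as a potential rescuer.  The model
#: excludes elementary and junior-high students; Japanese junior high school
#: ends at age 15, so 16 is the default cut-off.
DEFAULT_ELIGIBILITY_AGE = 16


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, as the reference tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RescueRateRow:
    """One decade band of the rescue-capacity rate table."""

    age_band: int
    strength_male: float
    strength_female: float
    executing_rate: float
    activity_rate_male: float
    activity_rate_female: float

    def expected(self, gender: str) -> float:
        """strength x executing rate x activity rate, rounded to 4 decimals."""
        if gender == "male":
            raw = self.strength_male * self.executing_rate * self.activity_rate_male
        elif gender == "female":
            raw = self.strength_female * self.executing_rate * self.activity_rate_female
        else:
            raise ValueError(f"unknown gender: {gender!r}")
        return round_half_up(raw, 4)


class RescueRateTable:
    """Decade-band lookup of rescue rates.

    Bands are labelled by their lower decade (10, 20, ..., 70); ages at or
    above the top label fall into the top band, ages below the youngest band
    score zero.
    """

    def __init__(self, rows: list[RescueRateRow]):
        if not rows:
            raise ValueError("rate table needs at least one row")
        self.rows = sorted(rows, key=lambda r: r.age_band)
        self._bands = [r.age_band for r in self.rows]

    def row_for_age(self, age: float) -> RescueRateRow | None:
        """Return the band row covering ``age``, or None below the youngest."""
        if age < 0:
            raise ValueError(f"age must be non-negative, got {age}")
        if age < self._bands[0]:
            return None
        band = None
        for r in self.rows:
            if age >= r.age_band:
                band = r
        return band

    def __iter__(self):
        return iter(self.rows)


# Rates compiled by the Tokyo Fire Department from rescue activity observed
# after the 1995 Hanshin-Awaji earthquake.  Columns: band, strength (M, F),
# executing rate, activity rate (M, F).
DEFAULT_RATE_TABLE = RescueRateTable(
    [
        RescueRateRow(10, 1.00, 0.85, 0.228, 0.76, 0.24),
        RescueRateRow(20, 1.00, 0.76, 0.228, 0.76, 0.24),
        RescueRateRow(30, 0.96, 0.76, 0.229, 0.72, 0.28),
        RescueRateRow(40, 0.93, 0.73, 0.298, 0.72, 0.28),
        RescueRateRow(50, 0.90, 0.72, 0.228, 0.63, 0.37),
        RescueRateRow(60, 0.84, 0.70, 0.191, 0.74, 0.26),
        RescueRateRow(70, 0.78, 0.65, 0.129, 0.75, 0.25),
    ]
)


def expected_value(
    age: float,
    gender: str,
    table: RescueRateTable = DEFAULT_RATE_TABLE,
    rescuer_eligible: bool = True,
) -> float:
    """Expected rescue value of one resident.

    Returns 0 for residents who are not rescuer-eligible (school children,
    people who themselves need assistance) and for ages below the youngest
    band of the table.

    >>> expected_value(40, "male")
    0.1995
    >>> expected_value(13, "male", rescuer_eligible=False)
    0.0
    """
    if gender not in ("male", "female"):
        raise ValueError(f"unknown gender: {gender!r}")
    if not rescuer_eligible:
        return 0.0
    row = table.row_for_age(age)
    if row is None:
        return 0.0
    return row.expected(gender)
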