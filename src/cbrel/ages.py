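"""Developmental age handling.

Donor ages in developmental brain atlases are printed in mixed units
("12 pcw", "4 mos", "8 yrs").  Every analysis here needs the ages on one
monotone numeric axis, so all labels are converted to days post conception
with birth fixed at 280 days (40 gestational weeks), one month at 30.44
days and one year at 365.25 days.  The conversion constants are module
attributes so an alternative convention can be injected if required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Gestation length used to anchor postnatal ages, in days.
BIRTH_DAYS = 280.0
#: Mean calendar month, in days.
DAYS_PER_MONTH = 30.44
#: Julian year, in days.
DAYS_PER_YEAR = 365.25

_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(pcw|mos|yrs)\s*$")


class AgeParseError(ValueError):
    """Raised for an age label outside the '<n> pcw|mos|yrs' dialect."""


@dataclass(frozen=True)
class AgePoint:
    """A donor age on the common days-post-conception scale."""

    raw_label: str
    days_post_conception: float
    is_prenatal: bool

    def __post_init__(self) -> None:
        if self.days_post_conception <= 0:
            raise ValueError(f"non-positive age in days: {self.days_post_conception}")
        if self.is_prenatal != (self.days_post_conception < BIRTH_DAYS):
            raise ValueError("prenatal flag inconsistent with age in days")


def parse_age(label: str) -> AgePoint:
    """Parse an age label such as ``"12 pcw"``, ``"4 mos"`` or ``"8 yrs"``.

    Post-conception weeks count from conception; months and years count
    from birth and are offset by :data:`BIRTH_DAYS`.

    Raises
    ------
    AgeParseError
        If the unit is unrecognised or the quantity is not positive.
    """
    m = _AGE_RE.match(label)
    if m is None:
        raise AgeParseError(f"unrecognised age label: {label!r}")
    qty = float(m.group(1))
    unit = m.group(2)
    if qty <= 0:
        raise AgeParseError(f"non-positive age quantity in label: {label!r}")
    if unit == "pcw":
        days = qty * 7.0
    elif unit == "mos":
        days = BIRTH_DAYS + qty * DAYS_PER_MONTH
    else:  # yrs
        days = BIRTH_DAYS + qty * DAYS_PER_YEAR
    return AgePoint(
        raw_label=format_age(qty, unit),
        days_post_conception=days,
        is_prenatal=days < BIRTH_DAYS,
    )


def format_age(qty: float, unit: str) -> str:
    """Canonical rendering of an age quantity/unit pair."""
    if unit not in ("pcw", "mos", "yrs"):
        raise AgeParseError(f"unrecognised age unit: {unit!r}")
    q = int(qty) if float(qty).is_integer() else qty
    return f"{q} {unit}"
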