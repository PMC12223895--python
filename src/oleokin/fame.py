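"""Fatty-acid methyl ester (FAME) profile bookkeeping and proximate arithmetic.

A gas-chromatography FAME profile lists each fatty acid as a shorthand
"C<carbons>:<double bonds>" plus its chromatogram area percentage.
Saturation classes follow the double-bond count: 0 -> saturated (SFA),
1 -> monounsaturated (MUFA), >= 2 -> polyunsaturated (PUFA). Class totals
are plain sums of the member area percentages with no renormalisation to
100 % (published columns rarely sum exactly to 100).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

SATURATED = "saturated"
MONOUNSATURATED = "monounsaturated"
POLYUNSATURATED = "polyunsaturated"

_SHORTHAND_RE = re.compile(r"^C(\d+):(\d+)$")

__all__ = [
    "FattyAcidRecord",
    "SaturationSummary",
    "parse_shorthand",
    "classify_fame",
    "aggregate_saturation",
    "carbohydrate_by_difference",
]


def parse_shorthand(shorthand: str) -> tuple[int, int]:
    """Parse 'C<carbons>:<double_bonds>' into an integer pair.

    Carbon counts below 4 are rejected (shorter chains are not fatty acids).
    """
    m = _SHORTHAND_RE.match(shorthand.strip())
    if m is None:
        raise ValueError(f"unparseable fatty-acid shorthand: {shorthand!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    if carbons < 4:
        raise ValueError(f"carbon count must be >= 4 in {shorthand!r}")
    return carbons, double_bonds


def classify_fame(shorthand: str) -> str:
    """Saturation class of a fatty acid from its shorthand alone."""
    _, double_bonds = parse_shorthand(shorthand)
    if double_bonds == 0:
        return SATURATED
    if double_bonds == 1:
        return MONOUNSATURATED
    return POLYUNSATURATED


@dataclass(frozen=True)
class FattyAcidRecord:
    """One FAME row: common name, Cx:y shorthand, and chromatogram area %."""

    common_name: str
    shorthand: str
    area_pct: float

    def __post_init__(self) -> None:
        parse_shorthand(self.shorthand)  # validates notation and carbon count
        if self.area_pct < 0:
            raise ValueError(f"area_pct must be >= 0, got {self.area_pct}")

    @property
    def saturation_class(self) -> str:
        return classify_fame(self.shorthand)


@dataclass(frozen=True)
class SaturationSummary:
    """SFA/MUFA/PUFA totals (area %), plain sums of the member records."""

    sfa_total: float
    mufa_total: float
    pufa_total: float

    @property
    def grand_total(self) -> float:
        return self.sfa_total + self.mufa_total + self.pufa_total


def aggregate_saturation(profile: Sequence[FattyAcidRecord] | Iterable[FattyAcidRecord]) -> SaturationSummary:
    """Sum area percentages by saturation class over a nonempty profile."""
    totals = {SATURATED: 0.0, MONOUNSATURATED: 0.0, POLYUNSATURATED: 0.0}
    n = 0
    for rec in profile:
        totals[rec.saturation_class] += rec.area_pct
        n += 1
    if n == 0:
        raise ValueError("profile is empty")
    return SaturationSummary(
        sfa_total=totals[SATURATED],
        mufa_total=totals[MONOUNSATURATED],
        pufa_total=totals[POLYUNSATURATED],
    )


def carbohydrate_by_difference(
    moisture: float, ash: float, protein: float, lipid: float
) -> float:
    """Carbohydrate % as 100 minus moisture, ash, protein and lipid.

    Each input must lie in [0, 100]. When the measured fractions sum past
    100 % the result is floored at 0 with a warning rather than reported
    negative.
    """
    for name, value in (
        ("moisture", moisture),
        ("ash", ash),
        ("protein", protein),
        ("lipid", lipid),
    ):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"{name} must be within [0, 100] %, got {value}")
    carb = 100.0 - (moisture + ash + protein + lipid)
    if carb < 0:
        warnings.warn(
            f"measured components sum to {100 - carb:.2f} %; "
            "carbohydrate-by-difference floored at 0",
            stacklevel=2,
        )
        return 0.0
    return carb
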