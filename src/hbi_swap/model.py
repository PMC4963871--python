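"""Core domain types for the beverage-substitution analysis.

The data model follows the structure of a single 24-h dietary recall:
each respondent-day (:class:`PersonDay`) carries demographics,
anthropometrics, survey-design fields and a list of consumed beverage
items (:class:`BeverageRecord`), each classified into one of eight
beverage groups. Per-person derived metrics live in
:class:`IntakeSummary`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

#: mL per US fluid ounce, used for all volume conversions except the
#: 8-oz substitution serving, which is pinned to the 237 mL constant of
#: the substitution policy.
ML_PER_FL_OZ = 29.5735

#: fluid ounces per beverage serving.
OZ_PER_SERVING = 8.0


class BeverageGroup(str, enum.Enum):
    """The eight beverage groups of the Healthy Beverage Index.

    Every classified record maps to exactly one group; the set is closed.
    """

    WATER = "WATER"
    COFFEE_TEA_UNSWEETENED = "COFFEE_TEA_UNSWEETENED"
    LOW_FAT_MILK = "LOW_FAT_MILK"
    DIET = "DIET"
    JUICE_100 = "JUICE_100"
    ALCOHOL = "ALCOHOL"
    WHOLE_MILK = "WHOLE_MILK"
    SSB = "SSB"


class ConsumerBin(str, enum.Enum):
    """SSB consumption bins partitioning servings/day: {0}, (0,1], (1,2], (2,inf)."""

    NON_CONSUMER = "NON_CONSUMER"
    ONE = "ONE"
    ONE_TO_TWO = "ONE_TO_TWO"
    GT_TWO = "GT_TWO"


#: Adult age groups used throughout the reporting tables.
AGE_GROUPS = ("19-29", "30-49", "50-65", "66+")


def age_group_of(age_years: int) -> str:
    if age_years < 19:
        raise ValueError(f"adult analysis requires age >= 19, got {age_years}")
    if age_years <= 29:
        return "19-29"
    if age_years <= 49:
        return "30-49"
    if age_years <= 65:
        return "50-65"
    return "66+"


class ValidationError(ValueError):
    """Raised when an input row or domain object violates an invariant."""


@dataclass(frozen=True)
class BeverageRecord:
    """One consumed beverage item from a 24-h recall."""

    person_id: str
    food_code: str
    group: BeverageGroup
    volume_oz: float
    energy_kcal: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.volume_oz) or self.volume_oz < 0:
            raise ValidationError(
                f"volume_oz must be finite and >= 0, got {self.volume_oz!r} "
                f"(person {self.person_id}, code {self.food_code})"
            )
        if not math.isfinite(self.energy_kcal) or self.energy_kcal < 0:
            raise ValidationError(
                f"energy_kcal must be finite and >= 0, got {self.energy_kcal!r} "
                f"(person {self.person_id}, code {self.food_code})"
            )


@dataclass
class PersonDay:
    """One respondent-day: demographics, anthropometrics, design fields, intake."""

    person_id: str
    age_years: int
    sex: str  # "M" or "F"
    weight_kg: float
    height_m: float
    total_kcal: float
    svy_weight: float
    stratum: str
    psu: str
    beverages: list[BeverageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_years < 19:
            raise ValidationError(
                f"person {self.person_id}: age_years must be >= 19, got {self.age_years}"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(f"person {self.person_id}: sex must be 'M' or 'F', got {self.sex!r}")
        if not self.weight_kg > 0:
            raise ValidationError(f"person {self.person_id}: weight_kg must be > 0, got {self.weight_kg}")
        if not self.height_m > 0:
            raise ValidationError(f"person {self.person_id}: height_m must be > 0, got {self.height_m}")
        if self.total_kcal < 0:
            raise ValidationError(f"person {self.person_id}: total_kcal must be >= 0, got {self.total_kcal}")
        if not self.svy_weight > 0:
            raise ValidationError(f"person {self.person_id}: svy_weight must be > 0, got {self.svy_weight}")
        bev = self.beverage_kcal
        # energy conservation: the recall's total energy includes beverages
        if self.total_kcal + 1e-9 < bev:
            raise ValidationError(
                f"person {self.person_id}: total_kcal ({self.total_kcal}) < "
                f"beverage energy ({bev})"
            )

    @property
    def beverage_kcal(self) -> float:
        return sum(r.energy_kcal for r in self.beverages)


def bin_of_servings(servings: float) -> ConsumerBin:
    """Assign the consumer bin; bins partition [0, inf)."""
    if servings < 0:
        raise ValidationError(f"servings must be >= 0, got {servings}")
    if servings == 0:
        return ConsumerBin.NON_CONSUMER
    if servings <= 1:
        return ConsumerBin.ONE
    if servings <= 2:
        return ConsumerBin.ONE_TO_TWO
    return ConsumerBin.GT_TWO


@dataclass
class IntakeSummary:
    """Per-person derived beverage metrics for one recall day."""

    person_id: str
    oz_by_group: dict[BeverageGroup, float]
    kcal_by_group: dict[BeverageGroup, float]
    bev_kcal: float
    total_kcal: float
    pct_energy_bev: float
    ssb_oz: float
    ssb_servings: float
    bin: ConsumerBin
    age_group: str
    sex: str

    @property
    def total_oz(self) -> float:
        return sum(self.oz_by_group.values())

    def copy(self) -> "IntakeSummary":
        return replace(
            self,
            oz_by_group=dict(self.oz_by_group),
            kcal_by_group=dict(self.kcal_by_group),
        )


def summarize_person(p: PersonDay) -> IntakeSummary:
    """Reduce a person-day to its beverage intake summary.

    Percent of energy from beverages uses the recalled total energy
    (beverages included) as denominator, and is 0 when total energy is 0.
    Order-independent and idempotent over the beverage list.
    """
    oz = {g: 0.0 for g in BeverageGroup}
    kcal = {g: 0.0 for g in BeverageGroup}
    for r in p.beverages:
        oz[r.group] += r.volume_oz
        kcal[r.group] += r.energy_kcal
    bev_kcal = sum(kcal.values())
    pct = 100.0 * bev_kcal / p.total_kcal if p.total_kcal > 0 else 0.0
    ssb_oz = oz[BeverageGroup.SSB]
    servings = ssb_oz / OZ_PER_SERVING
    return IntakeSummary(
        person_id=p.person_id,
        oz_by_group=oz,
        kcal_by_group=kcal,
        bev_kcal=bev_kcal,
        total_kcal=p.total_kcal,
        pct_energy_bev=pct,
        ssb_oz=ssb_oz,
        ssb_servings=servings,
        bin=bin_of_servings(servings),
        age_group=age_group_of(p.age_years),
        sex=p.sex,
    )
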