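"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from hbi_swap import (
    BeverageGroup,
    BeverageRecord,
    PersonDay,
    summarize_person,
)

# energy densities used when building ad-hoc records (kcal / fl oz)
DENSITY = {
    BeverageGroup.WATER: 0.0,
    BeverageGroup.COFFEE_TEA_UNSWEETENED: 0.3,
    BeverageGroup.LOW_FAT_MILK: 12.75,
    BeverageGroup.DIET: 0.0,
    BeverageGroup.JUICE_100: 14.0,
    BeverageGroup.ALCOHOL: 12.5,
    BeverageGroup.WHOLE_MILK: 18.6,
    BeverageGroup.SSB: 12.5,
}


def make_person(
    person_id: str = "p1",
    age: int = 35,
    sex: str = "F",
    weight_kg: float = 70.0,
    height_m: float = 1.65,
    total_kcal: float = 2000.0,
    svy_weight: float = 1.0,
    stratum: str = "S1",
    psu: str = "U1",
    oz_by_group: dict[BeverageGroup, float] | None = None,
    kcal_by_group: dict[BeverageGroup, float] | None = None,
) -> PersonDay:
    """Build a PersonDay with one record per nonzero beverage group."""
    oz_by_group = oz_by_group or {}
    kcal_by_group = kcal_by_group or {}
    records = []
    for group, oz in oz_by_group.items():
        if oz <= 0:
            continue
        kcal = kcal_by_group.get(group, DENSITY[group] * oz)
        records.append(
            BeverageRecord(
                person_id=person_id,
                food_code="00000000",
                group=group,
                volume_oz=oz,
                energy_kcal=kcal,
            )
        )
    return PersonDay(
        person_id=person_id,
        age_years=age,
        sex=sex,
        weight_kg=weight_kg,
        height_m=height_m,
        total_kcal=total_kcal,
        svy_weight=svy_weight,
        stratum=stratum,
        psu=psu,
        beverages=records,
    )


def make_summary(**kwargs):
    return summarize_person(make_person(**kwargs))


@pytest.fixture
def ssb_person():
    """A 1.5-serving SSB consumer with a mixed beverage pattern."""
    return make_person(
        oz_by_group={
            BeverageGroup.WATER: 30.0,
            BeverageGroup.SSB: 12.0,
            BeverageGroup.JUICE_100: 4.0,
        }
    )
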