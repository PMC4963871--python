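"""Synthetic NHANES-like population generator.

Generates single-day beverage recalls with the statistical structure the
downstream analysis assumes: zero-inflated gamma SSB intake by adult age
group, independent gamma draws for the other seven beverage groups,
normal total energy (floored, and never below beverage energy),
lognormal BMI with normal height, and a stratified two-PSU survey design
with lognormal weights normalized to mean 1.

Default parameters are calibrated to published adult beverage-intake
tables: per-age-group non-consumer fractions and consumer-mean SSB
ounces, gamma shapes fitted so the implied serving-bin proportions
(non-consumer / <=1 / 1-2 / >2 servings of 8 oz) track the published
distribution, and per-group mean ounces and total energy matching the
reported means. Beverage energy uses fixed per-group energy densities,
with the SSB density at 12.5 kcal/fl oz so one 8-oz serving carries
100 kcal — the same constant the substitution policy uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .io import write_tables
from .model import AGE_GROUPS, BeverageGroup, BeverageRecord, PersonDay

__all__ = [
    "AgeGroupParams",
    "SyntheticConfig",
    "SyntheticPopulation",
    "generate_population",
    "write_population",
    "default_config",
    "ENERGY_DENSITY_KCAL_PER_OZ",
]

#: fixed per-group energy densities, kcal per fluid oz
ENERGY_DENSITY_KCAL_PER_OZ = {
    BeverageGroup.WATER: 0.0,
    BeverageGroup.COFFEE_TEA_UNSWEETENED: 0.3,   # black coffee/tea
    BeverageGroup.LOW_FAT_MILK: 12.75,           # 1% milk, ~102 kcal/cup
    BeverageGroup.DIET: 0.0,
    BeverageGroup.JUICE_100: 14.0,               # ~112 kcal/cup
    BeverageGroup.ALCOHOL: 12.5,                 # beer-dominated mix
    BeverageGroup.WHOLE_MILK: 18.6,              # ~149 kcal/cup
    BeverageGroup.SSB: 12.5,                     # 8 oz = 100 kcal
}

#: representative food code per group (matches the shipped mapping fixture)
_FOOD_CODE = {
    BeverageGroup.WATER: "94000100",
    BeverageGroup.COFFEE_TEA_UNSWEETENED: "92302000",
    BeverageGroup.LOW_FAT_MILK: "11112110",
    BeverageGroup.DIET: "92410510",
    BeverageGroup.JUICE_100: "61210000",
    BeverageGroup.ALCOHOL: "93101000",
    BeverageGroup.WHOLE_MILK: "11111000",
    BeverageGroup.SSB: "92410310",
}

#: draw order for the six "other" beverage groups
_OTHER_GROUPS = (
    BeverageGroup.COFFEE_TEA_UNSWEETENED,
    BeverageGroup.LOW_FAT_MILK,
    BeverageGroup.DIET,
    BeverageGroup.JUICE_100,
    BeverageGroup.ALCOHOL,
    BeverageGroup.WHOLE_MILK,
)

_AGE_RANGES = {"19-29": (19, 29), "30-49": (30, 49), "50-65": (50, 65), "66+": (66, 85)}


class AgeGroupParams(BaseModel):
    """Per-age-group intake parameters."""

    ssb_zero_prob: float = Field(ge=0.0, le=1.0)
    ssb_oz_mean_consumers: float = Field(gt=0.0)
    ssb_oz_shape: float = Field(gt=0.0)
    water_oz_mean: float = Field(ge=0.0)
    #: coffee/tea, low-fat milk, diet, juice, alcohol, whole milk
    other_group_oz_means: list[float] = Field(min_length=6, max_length=6)
    total_kcal_mean: float = Field(gt=0.0)
    total_kcal_sd: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _nonneg(self) -> "AgeGroupParams":
        for v in self.other_group_oz_means:
            if v < 0:
                raise ValueError("other_group_oz_means must be nonnegative")
        return self


class SyntheticConfig(BaseModel):
    """Full generator configuration; defaults via :func:`default_config`."""

    n_persons: int = Field(gt=0)
    age_group_probs: list[float] = Field(min_length=4, max_length=4)
    groups: dict[str, AgeGroupParams]
    male_prob: float = Field(default=0.49, ge=0.0, le=1.0)
    other_oz_shape: float = Field(default=1.0, gt=0.0)
    water_oz_shape: float = Field(default=1.5, gt=0.0)
    bmi_lognormal_mu: float = 3.321
    bmi_lognormal_sigma: float = Field(default=0.211, ge=0.0)
    height_mean_m: float = Field(default=1.68, gt=0.0)
    height_sd_m: float = Field(default=0.095, ge=0.0)
    total_kcal_floor: float = Field(default=500.0, gt=0.0)
    n_strata: int = Field(default=15, gt=0)
    psus_per_stratum: int = Field(default=2, ge=2)
    weight_cv: float = Field(default=0.5, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if abs(sum(self.age_group_probs) - 1.0) > 1e-9:
            raise ValueError("age_group_probs must sum to 1")
        if any(p < 0 for p in self.age_group_probs):
            raise ValueError("age_group_probs must be nonnegative")
        missing = [g for g in AGE_GROUPS if g not in self.groups]
        if missing:
            raise ValueError(f"groups missing age group(s): {missing}")
        return self

    @classmethod
    def from_yaml(cls, source) -> "SyntheticConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        return cls.model_validate(raw)


@dataclass
class SyntheticPopulation:
    persons: list[PersonDay]
    generating_config: SyntheticConfig


def default_config(n_persons: int = 2000, seed: int = 0) -> SyntheticConfig:
    """Defaults calibrated to published adult beverage-intake tables.

    Age-group shares follow the analytic sample's age composition;
    non-consumer fractions, consumer means and fitted gamma shapes track
    the published SSB serving-bin distribution; per-group ounces and
    total energy follow the reported age-group means.
    """
    groups = {
        # water, [coffee/tea, low-fat milk, diet, juice, alcohol, whole milk]
        "19-29": AgeGroupParams(
            ssb_zero_prob=0.374, ssb_oz_mean_consumers=29.6, ssb_oz_shape=1.96,
            water_oz_mean=41.0, other_group_oz_means=[5.0, 2.0, 3.0, 3.0, 8.3, 3.0],
            total_kcal_mean=1831.0, total_kcal_sd=750.0,
        ),
        "30-49": AgeGroupParams(
            ssb_zero_prob=0.483, ssb_oz_mean_consumers=27.2, ssb_oz_shape=1.95,
            water_oz_mean=40.8, other_group_oz_means=[12.3, 2.1, 6.1, 2.4, 7.6, 2.8],
            total_kcal_mean=1820.0, total_kcal_sd=730.0,
        ),
        "50-65": AgeGroupParams(
            ssb_zero_prob=0.634, ssb_oz_mean_consumers=20.8, ssb_oz_shape=2.33,
            water_oz_mean=35.0, other_group_oz_means=[20.0, 3.0, 7.0, 2.0, 6.4, 2.0],
            total_kcal_mean=1706.0, total_kcal_sd=680.0,
        ),
        "66+": AgeGroupParams(
            ssb_zero_prob=0.711, ssb_oz_mean_consumers=14.7, ssb_oz_shape=2.32,
            water_oz_mean=26.0, other_group_oz_means=[18.0, 3.0, 4.0, 2.0, 3.2, 3.0],
            total_kcal_mean=1479.0, total_kcal_sd=600.0,
        ),
    }
    return SyntheticConfig(
        n_persons=n_persons,
        age_group_probs=[0.190, 0.329, 0.264, 0.217],
        groups=groups,
        seed=seed,
    )


def generate_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Draw a population; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    age_idx = rng.choice(4, size=n, p=np.asarray(config.age_group_probs) / sum(config.age_group_probs))
    sexes = np.where(rng.random(n) < config.male_prob, "M", "F")
    heights = np.clip(rng.normal(config.height_mean_m, config.height_sd_m, n), 1.30, 2.20)
    bmis = rng.lognormal(config.bmi_lognormal_mu, config.bmi_lognormal_sigma, n)
    weights_kg = bmis * heights**2

    # survey design: round-robin over stratum x PSU cells, lognormal weights
    cells = config.n_strata * config.psus_per_stratum
    cell_idx = np.arange(n) % cells
    strata = cell_idx // config.psus_per_stratum + 1
    psus = cell_idx % config.psus_per_stratum + 1
    if config.weight_cv > 0:
        sigma2 = np.log1p(config.weight_cv**2)
        svy_w = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)
    else:
        svy_w = np.ones(n)
    svy_w = svy_w / svy_w.mean()

    persons: list[PersonDay] = []
    for i in range(n):
        g = config.groups[AGE_GROUPS[age_idx[i]]]
        lo, hi = _AGE_RANGES[AGE_GROUPS[age_idx[i]]]
        age = int(rng.integers(lo, hi + 1))

        oz: dict[BeverageGroup, float] = {}
        if rng.random() < g.ssb_zero_prob:
            oz[BeverageGroup.SSB] = 0.0
        else:
            k = g.ssb_oz_shape
            oz[BeverageGroup.SSB] = float(rng.gamma(k, g.ssb_oz_mean_consumers / k))
        if g.water_oz_mean > 0:
            kw = config.water_oz_shape
            oz[BeverageGroup.WATER] = float(rng.gamma(kw, g.water_oz_mean / kw))
        else:
            oz[BeverageGroup.WATER] = 0.0
        for grp, mean in zip(_OTHER_GROUPS, g.other_group_oz_means):
            if mean > 0:
                ko = config.other_oz_shape
                oz[grp] = float(rng.gamma(ko, mean / ko))
            else:
                oz[grp] = 0.0

        records = []
        bev_kcal = 0.0
        for grp in BeverageGroup:
            vol = oz[grp]
            if vol <= 0:
                continue
            kcal = ENERGY_DENSITY_KCAL_PER_OZ[grp] * vol
            bev_kcal += kcal
            records.append(
                BeverageRecord(
                    person_id=f"P{i:06d}",
                    food_code=_FOOD_CODE[grp],
                    group=grp,
                    volume_oz=vol,
                    energy_kcal=kcal,
                )
            )

        total_kcal = rng.normal(g.total_kcal_mean, g.total_kcal_sd)
        total_kcal = max(total_kcal, config.total_kcal_floor, bev_kcal)

        persons.append(
            PersonDay(
                person_id=f"P{i:06d}",
                age_years=age,
                sex=str(sexes[i]),
                weight_kg=float(weights_kg[i]),
                height_m=float(heights[i]),
                total_kcal=float(total_kcal),
                svy_weight=float(svy_w[i]),
                stratum=f"S{strata[i]:02d}",
                psu=f"U{psus[i]}",
                beverages=records,
            )
        )
    return SyntheticPopulation(persons=persons, generating_config=config)


def expected_bin_probs(g: AgeGroupParams) -> dict[str, float]:
    """Bin probabilities implied by the generating parameters (closed form)."""
    from scipy import stats as _st

    dist = _st.gamma(g.ssb_oz_shape, scale=g.ssb_oz_mean_consumers / g.ssb_oz_shape)
    p0 = g.ssb_zero_prob
    pc = 1.0 - p0
    c8, c16 = dist.cdf(8.0), dist.cdf(16.0)
    return {
        "NON_CONSUMER": p0,
        "ONE": pc * c8,
        "ONE_TO_TWO": pc * (c16 - c8),
        "GT_TWO": pc * (1.0 - c16),
    }


def write_population(pop: SyntheticPopulation, out_dir) -> tuple[Path, Path]:
    """Write the person and beverage TSVs consumed by the readers."""
    if not pop.persons:
        raise ValueError("population is empty")
    return write_tables(pop.persons, out_dir)
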