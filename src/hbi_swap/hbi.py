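"""Healthy Beverage Index (HBI) scoring engine.

The HBI is a ten-component, 0-100 index of adherence to beverage-intake
recommendations; higher scores indicate a healthier beverage pattern.
Eight components correspond to the eight beverage groups (with standards
expressed as fluid ounces per day, or for water as a percentage of the
daily fluid requirement), one to the percent of total energy obtained
from beverages, and one to meeting the total daily fluid requirement.

The engine is deliberately config-driven: each component carries a
full-credit band ``[standard_lo, standard_hi]``, a ``zero_point`` at or
beyond which no points are awarded, a ``max_points`` allocation, and a
scoring ``mode``. In ``proportional`` mode points decay linearly from
the edge of the full-credit band to the zero point; in ``binary`` mode
the component is all-or-nothing. The ten max-point allocations must sum
to 100, which makes any transcription of component standards a valid
0-100 scorer. The default allocation shipped in
``data/hbi_components.yaml`` follows the published index's component
list; its cut-points are documented in the package methods note.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from typing import Iterable, Mapping

import yaml
from pydantic import BaseModel, Field, model_validator

from .model import ML_PER_FL_OZ, BeverageGroup, IntakeSummary

__all__ = [
    "HBIComponent",
    "HBIComponentConfig",
    "FluidRequirement",
    "HBIScore",
    "ScoringError",
    "score_component",
    "score_hbi",
    "load_component_configs",
    "default_component_configs",
]


class ScoringError(ValueError):
    pass


class HBIComponent(str, enum.Enum):
    WATER = "WATER"
    COFFEE_TEA_UNSWEETENED = "COFFEE_TEA_UNSWEETENED"
    LOW_FAT_MILK = "LOW_FAT_MILK"
    DIET = "DIET"
    JUICE_100 = "JUICE_100"
    ALCOHOL = "ALCOHOL"
    WHOLE_MILK = "WHOLE_MILK"
    SSB = "SSB"
    PCT_ENERGY_BEV = "PCT_ENERGY_BEV"
    MEETS_FLUID_REQS = "MEETS_FLUID_REQS"


class FluidRequirement(BaseModel):
    """Adequate-intake fluid requirement by sex, litres/day.

    Defaults are the adult Daily Recommended Intake values: 3.7 L/day
    for men and 2.7 L/day for non-pregnant, non-lactating women.
    """

    male_l: float = 3.7
    female_l: float = 2.7

    def liters_for(self, sex: str) -> float:
        if sex == "M":
            return self.male_l
        if sex == "F":
            return self.female_l
        raise ScoringError(f"unknown sex {sex!r}")


class HBIComponentConfig(BaseModel):
    """Scoring standard for one HBI component."""

    component_id: HBIComponent
    standard_lo: float
    standard_hi: float
    zero_point: float
    max_points: float = Field(ge=0)
    mode: str = "proportional"  # or "binary"

    @model_validator(mode="after")
    def _check(self) -> "HBIComponentConfig":
        if self.standard_lo > self.standard_hi:
            raise ValueError(
                f"{self.component_id}: empty full-credit band "
                f"[{self.standard_lo}, {self.standard_hi}]"
            )
        if self.mode not in ("proportional", "binary"):
            raise ValueError(f"{self.component_id}: mode must be proportional or binary")
        if self.mode == "proportional" and self.standard_lo <= self.zero_point <= self.standard_hi:
            raise ValueError(
                f"{self.component_id}: zero_point {self.zero_point} lies inside "
                f"the full-credit band"
            )
        return self


class HBIScore(BaseModel):
    """Per-component points and the 0-100 total."""

    points_by_component: dict[HBIComponent, float]
    total: float

    @property
    def points(self) -> dict[HBIComponent, float]:
        return self.points_by_component


def _metric_value(summary: IntakeSummary, component: HBIComponent, fluid: FluidRequirement) -> float:
    """Per-person quantity scored by a component, in that component's units."""
    if component == HBIComponent.WATER:
        req_ml = fluid.liters_for(summary.sex) * 1000.0
        return 100.0 * summary.oz_by_group[BeverageGroup.WATER] * ML_PER_FL_OZ / req_ml
    if component == HBIComponent.PCT_ENERGY_BEV:
        return summary.pct_energy_bev
    if component == HBIComponent.MEETS_FLUID_REQS:
        # total fluid from all beverage groups, as % of the requirement
        req_ml = fluid.liters_for(summary.sex) * 1000.0
        return 100.0 * summary.total_oz * ML_PER_FL_OZ / req_ml
    try:
        group = BeverageGroup(component.value)
    except ValueError as exc:  # pragma: no cover - closed enum
        raise ScoringError(f"no metric for component {component}") from exc
    return summary.oz_by_group[group]


def score_component(
    summary: IntakeSummary,
    cfg: HBIComponentConfig,
    fluid: FluidRequirement | None = None,
) -> float:
    """Score one component; result lies in [0, cfg.max_points].

    Full credit inside ``[standard_lo, standard_hi]``. Binary mode gives
    0 outside the band. Proportional mode decays linearly to 0 at the
    zero point on the side of the band where the zero point lies, and
    gives 0 outside the band on any side without a zero point.
    """
    fluid = fluid or FluidRequirement()
    m = _metric_value(summary, cfg.component_id, fluid)
    lo, hi, zero = cfg.standard_lo, cfg.standard_hi, cfg.zero_point
    if lo <= m <= hi:
        return cfg.max_points
    if cfg.mode == "binary":
        return 0.0
    if m > hi and zero > hi:
        frac = (zero - m) / (zero - hi)
    elif m < lo and zero < lo:
        frac = (m - zero) / (lo - zero)
    else:
        return 0.0
    return cfg.max_points * min(1.0, max(0.0, frac))


def score_hbi(
    summary: IntakeSummary,
    configs: Iterable[HBIComponentConfig] | None = None,
    fluid: FluidRequirement | None = None,
) -> HBIScore:
    """Score all ten components; the total is guaranteed to lie in [0, 100]."""
    configs = list(configs) if configs is not None else default_component_configs()
    fluid = fluid or FluidRequirement()
    ids = [c.component_id for c in configs]
    if sorted(set(ids)) != sorted(HBIComponent) or len(ids) != len(HBIComponent):
        raise ScoringError(
            f"expected exactly one config per component ({len(HBIComponent)} total), got {ids}"
        )
    total_max = sum(c.max_points for c in configs)
    if not math.isclose(total_max, 100.0, abs_tol=1e-9):
        raise ScoringError(f"component max_points must sum to 100, got {total_max}")
    points = {c.component_id: score_component(summary, c, fluid) for c in configs}
    return HBIScore(points_by_component=points, total=sum(points.values()))


def load_component_configs(source) -> list[HBIComponentConfig]:
    """Load component configs from YAML (path, file object, or parsed list)."""
    if isinstance(source, (list, tuple)):
        raw = list(source)
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ScoringError("HBI component config must be a YAML list of component blocks")
    return [HBIComponentConfig.model_validate(block) for block in raw]


_DEFAULTS: list[HBIComponentConfig] | None = None


def default_component_configs() -> list[HBIComponentConfig]:
    """The component standards shipped with the package."""
    global _DEFAULTS
    if _DEFAULTS is None:
        ref = resources.files("hbi_swap.data").joinpath("hbi_components.yaml")
        with ref.open("r", encoding="utf-8") as fh:
            _DEFAULTS = load_component_configs(fh)
    return [c.model_copy() for c in _DEFAULTS]
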