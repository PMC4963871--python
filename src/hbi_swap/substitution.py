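"""The SSB-to-water substitution counterfactual.

One 8-oz serving of sugar-sweetened beverage (assumed to equal 237 mL
and to carry on average 100 kcal) is replaced with one 8-oz serving of
water, per eligible person. SSB volume falls by one serving (floored at
zero), water volume rises by one serving, and both beverage energy and
total energy fall by the per-serving energy reduction — the
substitution models a change in dietary energy, not a relabelling, so
the percent of energy from beverages is recomputed with both a reduced
numerator and a reduced denominator. The HBI is then rescored on the
counterfactual intake.

Non-consumers are never modified. Consumers of less than one full
serving are still substituted (their SSB goes to zero); by default the
energy reduction is clamped to the energy actually present in the
person's SSB records so intake can never go negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from pydantic import BaseModel, Field

from .hbi import FluidRequirement, HBIComponentConfig, HBIScore, score_hbi
from .model import (
    BeverageGroup,
    ConsumerBin,
    IntakeSummary,
    OZ_PER_SERVING,
    bin_of_servings,
)

__all__ = ["SubstitutionPolicy", "CounterfactualPair", "apply_substitution", "substitute_all"]


class SubstitutionPolicy(BaseModel):
    """Constants of the one-serving SSB-to-water replacement."""

    kcal_per_serving: float = Field(default=100.0, gt=0)
    serving_oz: float = Field(default=8.0, gt=0)
    serving_ml: float = Field(default=237.0, gt=0)
    n_servings_replaced: int = Field(default=1, ge=1)
    apply_to: set[ConsumerBin] = Field(
        default_factory=lambda: {ConsumerBin.ONE, ConsumerBin.ONE_TO_TWO, ConsumerBin.GT_TWO}
    )
    #: clamp the energy reduction to the energy present in SSB records
    clamp_to_available_kcal: bool = True


@dataclass
class CounterfactualPair:
    """Observed and predicted (post-substitution) state for one person."""

    person_id: str
    observed: IntakeSummary
    predicted: IntakeSummary
    observed_hbi: HBIScore
    predicted_hbi: HBIScore
    substituted: bool
    delta_bev_kcal: float
    delta_pct_energy: float
    pct_change_hbi: Optional[float]  # None when observed HBI total is 0


def apply_substitution(
    summary: IntakeSummary,
    policy: SubstitutionPolicy | None = None,
    hbi_configs: Iterable[HBIComponentConfig] | None = None,
    fluid: FluidRequirement | None = None,
) -> CounterfactualPair:
    """Apply the water-replacement counterfactual to one person-day."""
    policy = policy or SubstitutionPolicy()
    configs = list(hbi_configs) if hbi_configs is not None else None
    observed_hbi = score_hbi(summary, configs, fluid)

    if summary.bin not in policy.apply_to:
        return CounterfactualPair(
            person_id=summary.person_id,
            observed=summary,
            predicted=summary.copy(),
            observed_hbi=observed_hbi,
            predicted_hbi=score_hbi(summary, configs, fluid),
            substituted=False,
            delta_bev_kcal=0.0,
            delta_pct_energy=0.0,
            pct_change_hbi=0.0 if observed_hbi.total > 0 else None,
        )

    n = policy.n_servings_replaced
    oz_swap = policy.serving_oz * n
    kcal_cut = policy.kcal_per_serving * n
    if policy.clamp_to_available_kcal:
        kcal_cut = min(kcal_cut, summary.kcal_by_group[BeverageGroup.SSB])

    pred = summary.copy()
    pred.oz_by_group[BeverageGroup.SSB] = max(0.0, summary.ssb_oz - oz_swap)
    pred.oz_by_group[BeverageGroup.WATER] = summary.oz_by_group[BeverageGroup.WATER] + oz_swap
    pred.kcal_by_group[BeverageGroup.SSB] = max(
        0.0, summary.kcal_by_group[BeverageGroup.SSB] - kcal_cut
    )
    pred.bev_kcal = max(0.0, summary.bev_kcal - kcal_cut)
    pred.total_kcal = max(pred.bev_kcal, summary.total_kcal - kcal_cut)
    pred.pct_energy_bev = (
        100.0 * pred.bev_kcal / pred.total_kcal if pred.total_kcal > 0 else 0.0
    )
    pred.ssb_oz = pred.oz_by_group[BeverageGroup.SSB]
    pred.ssb_servings = pred.ssb_oz / OZ_PER_SERVING
    pred.bin = bin_of_servings(pred.ssb_servings)

    predicted_hbi = score_hbi(pred, configs, fluid)
    pct_change = (
        100.0 * (predicted_hbi.total - observed_hbi.total) / observed_hbi.total
        if observed_hbi.total > 0
        else None
    )
    return CounterfactualPair(
        person_id=summary.person_id,
        observed=summary,
        predicted=pred,
        observed_hbi=observed_hbi,
        predicted_hbi=predicted_hbi,
        substituted=True,
        delta_bev_kcal=pred.bev_kcal - summary.bev_kcal,
        delta_pct_energy=pred.pct_energy_bev - summary.pct_energy_bev,
        pct_change_hbi=pct_change,
    )


def substitute_all(
    summaries: Iterable[IntakeSummary],
    policy: SubstitutionPolicy | None = None,
    hbi_configs: Iterable[HBIComponentConfig] | None = None,
    fluid: FluidRequirement | None = None,
) -> list[CounterfactualPair]:
    policy = policy or SubstitutionPolicy()
    configs = list(hbi_configs) if hbi_configs is not None else None
    return [apply_substitution(s, policy, configs, fluid) for s in summaries]
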