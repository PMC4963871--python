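"""End-to-end orchestration: simulate/ingest → summarize → score →
substitute → reclassify → estimate.

Every reporting table is derived from persisted per-person intermediate
files (summaries, counterfactual pairs, reclassified anthropometrics),
so each printed cell can be recomputed from them. Output tables mirror
the shape of a beverage-intake analysis: per-group intake by age group,
the SSB serving-bin distribution, the energy impact of the water
substitution by bin, HBI by age group and bin, the percent change in
HBI, and BMI-category prevalences under each weight scenario.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import survey
from .hbi import FluidRequirement, default_component_configs, load_component_configs
from .io import IngestReport, read_tables
from .model import AGE_GROUPS, BeverageGroup, ConsumerBin, summarize_person
from .substitution import SubstitutionPolicy, substitute_all
from .synthetic import SyntheticConfig, generate_population
from .weight import (
    BMICategory,
    HIGH_SCENARIO,
    LOW_SCENARIO,
    WeightScenario,
    apply_scenario,
)

logger = logging.getLogger(__name__)

_BINS = [ConsumerBin.NON_CONSUMER, ConsumerBin.ONE, ConsumerBin.ONE_TO_TWO, ConsumerBin.GT_TWO]
_CONSUMER_BINS = [ConsumerBin.ONE, ConsumerBin.ONE_TO_TWO, ConsumerBin.GT_TWO]


class RunConfig(BaseModel):
    """Single-run configuration for the full pipeline."""

    person_path: Optional[str] = None
    beverage_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    hbi_config_path: Optional[str] = None
    policy: SubstitutionPolicy = Field(default_factory=SubstitutionPolicy)
    fluid: FluidRequirement = Field(default_factory=FluidRequirement)
    scenarios: list[WeightScenario] = Field(
        default_factory=lambda: [LOW_SCENARIO.model_copy(), HIGH_SCENARIO.model_copy()]
    )
    out_dir: str = "hbi_swap_out"
    seed: Optional[int] = None  # overrides synthetic.seed when given

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        file_input = self.person_path is not None or self.beverage_path is not None
        if file_input and self.synthetic is not None:
            raise ValueError("provide input paths or a synthetic config, not both")
        if file_input and (self.person_path is None or self.beverage_path is None):
            raise ValueError("both person_path and beverage_path are required for file input")
        if not file_input and self.synthetic is None:
            raise ValueError("either input paths or a synthetic config is required")
        if not self.scenarios:
            raise ValueError("scenarios must be nonempty")
        return self


def _fmt(est: survey.SurveyEstimate) -> str:
    return f"{est.estimate:.1f} ({est.se:.1f})"


class PipelineResult(BaseModel, arbitrary_types_allowed=True):
    out_dir: Path
    n_persons: int
    ingest: Optional[IngestReport] = None
    m_comparisons: int = 0


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run all stages and write the report bundle under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, out, written)
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _run(cfg: RunConfig, out: Path, written: list[Path]) -> PipelineResult:
    ingest = None
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        if cfg.seed is not None:
            syn = syn.model_copy(update={"seed": cfg.seed})
        persons = generate_population(syn).persons
        logger.info("simulated %d persons (seed %d)", len(persons), syn.seed)
    else:
        persons, ingest = read_tables(cfg.person_path, cfg.beverage_path)
        logger.info(
            "ingested %d persons (%d roster rows, %d excluded missing dietary data)",
            ingest.n_retained, ingest.n_rows, ingest.n_excluded_missing,
        )

    hbi_configs = (
        load_component_configs(cfg.hbi_config_path)
        if cfg.hbi_config_path
        else default_component_configs()
    )

    summaries = [summarize_person(p) for p in persons]
    pairs = substitute_all(summaries, cfg.policy, hbi_configs, cfg.fluid)
    pair_by_id = {pr.person_id: pr for pr in pairs}

    # ---- per-person intermediates (full provenance for every table) ----
    sum_df = pd.DataFrame(
        {
            "person_id": [s.person_id for s in summaries],
            "age_group": [s.age_group for s in summaries],
            "sex": [s.sex for s in summaries],
            "bin": [s.bin.value for s in summaries],
            **{
                f"oz_{g.value.lower()}": [s.oz_by_group[g] for s in summaries]
                for g in BeverageGroup
            },
            "bev_kcal": [s.bev_kcal for s in summaries],
            "total_kcal": [s.total_kcal for s in summaries],
            "pct_energy_bev": [s.pct_energy_bev for s in summaries],
            "ssb_servings": [s.ssb_servings for s in summaries],
            "svy_weight": [p.svy_weight for p in persons],
            "stratum": [p.stratum for p in persons],
            "psu": [p.psu for p in persons],
        }
    )
    _write(sum_df, out / "summaries.tsv", written)

    pair_df = pd.DataFrame(
        {
            "person_id": [pr.person_id for pr in pairs],
            "substituted": [pr.substituted for pr in pairs],
            "bev_kcal_obs": [pr.observed.bev_kcal for pr in pairs],
            "bev_kcal_pred": [pr.predicted.bev_kcal for pr in pairs],
            "pct_energy_obs": [pr.observed.pct_energy_bev for pr in pairs],
            "pct_energy_pred": [pr.predicted.pct_energy_bev for pr in pairs],
            "hbi_obs": [pr.observed_hbi.total for pr in pairs],
            "hbi_pred": [pr.predicted_hbi.total for pr in pairs],
            "pct_change_hbi": [pr.pct_change_hbi for pr in pairs],
        }
    )
    _write(pair_df, out / "pairs.tsv", written)

    w = sum_df["svy_weight"].to_numpy()
    strata = sum_df["stratum"].to_numpy()
    psus = sum_df["psu"].to_numpy()
    ages = sum_df["age_group"].to_numpy()
    bins = sum_df["bin"].to_numpy()

    # ---- intake by age group (group ounces, energy) ----
    rows = []
    for g in BeverageGroup:
        col = sum_df[f"oz_{g.value.lower()}"].to_numpy()
        rows.append(
            {"quantity": f"{g.value} (oz)"}
            | {
                a: _fmt(survey.survey_mean(col, w, strata, psus, domain_mask=(ages == a)))
                for a in AGE_GROUPS
            }
        )
    for label, col in [
        ("Beverage energy (kcal)", sum_df["bev_kcal"].to_numpy()),
        ("% energy from beverages", sum_df["pct_energy_bev"].to_numpy()),
        ("Total energy (kcal)", sum_df["total_kcal"].to_numpy()),
    ]:
        rows.append(
            {"quantity": label}
            | {
                a: _fmt(survey.survey_mean(col, w, strata, psus, domain_mask=(ages == a)))
                for a in AGE_GROUPS
            }
        )
    _write(pd.DataFrame(rows), out / "table_intake_by_age.tsv", written)

    # ---- SSB distribution: means and bin prevalences by age group ----
    ssb = sum_df["oz_ssb"].to_numpy()
    rows = []
    for a in list(AGE_GROUPS) + ["19+"]:
        mask = np.ones(len(sum_df), dtype=bool) if a == "19+" else (ages == a)
        cons = mask & (ssb > 0)
        prev = survey.weighted_prevalence(
            bins, w, strata, psus, levels=[b.value for b in _BINS], domain_mask=mask
        )
        row = {
            "age_group": a,
            "n": int(mask.sum()),
            "ssb_oz_full_sample": _fmt(survey.survey_mean(ssb, w, strata, psus, domain_mask=mask)),
            "ssb_oz_consumers": _fmt(
                survey.survey_mean(ssb, w, strata, psus, domain_mask=cons)
            )
            if cons.any()
            else "NA",
        }
        row |= {f"pct_{b.value}": _fmt(prev[b.value]) for b in _BINS}
        rows.append(row)
    _write(pd.DataFrame(rows), out / "table_ssb_distribution.tsv", written)

    # ---- substitution impact on beverage energy, by consumer bin ----
    obs_kcal = pair_df["bev_kcal_obs"].to_numpy()
    pred_kcal = pair_df["bev_kcal_pred"].to_numpy()
    obs_pct = pair_df["pct_energy_obs"].to_numpy()
    pred_pct = pair_df["pct_energy_pred"].to_numpy()
    rows = []
    for b in _CONSUMER_BINS:
        mask = bins == b.value
        if not mask.any():
            rows.append({"bin": b.value, "n": 0})
            continue
        kobs = survey.survey_mean(obs_kcal, w, strata, psus, domain_mask=mask)
        kpred = survey.survey_mean(pred_kcal, w, strata, psus, domain_mask=mask)
        rows.append(
            {
                "bin": b.value,
                "n": int(mask.sum()),
                "bev_kcal_obs": _fmt(kobs),
                "bev_kcal_pred": _fmt(kpred),
                "pct_change_kcal": round(100.0 * (kpred.estimate - kobs.estimate) / kobs.estimate, 1)
                if kobs.estimate
                else float("nan"),
                "pct_energy_obs": _fmt(survey.survey_mean(obs_pct, w, strata, psus, domain_mask=mask)),
                "pct_energy_pred": _fmt(survey.survey_mean(pred_pct, w, strata, psus, domain_mask=mask)),
            }
        )
    _write(pd.DataFrame(rows), out / "table_substitution_impact.tsv", written)

    # ---- HBI by age group and bin, with paired observed-vs-predicted tests ----
    hbi_obs = pair_df["hbi_obs"].to_numpy()
    hbi_pred = pair_df["hbi_pred"].to_numpy()
    cells = [(a, b) for a in AGE_GROUPS for b in _CONSUMER_BINS]
    m = sum(
        1 for a, b in cells if ((ages == a) & (bins == b.value)).any()
    )  # comparisons actually performed
    rows = []
    for a in AGE_GROUPS:
        amask = ages == a
        row = {"age_group": a}
        row["full_sample"] = _fmt(survey.survey_mean(hbi_obs, w, strata, psus, domain_mask=amask))
        for b in _BINS:
            mask = amask & (bins == b.value)
            row[f"hbi_{b.value}"] = (
                _fmt(survey.survey_mean(hbi_obs, w, strata, psus, domain_mask=mask))
                if mask.any()
                else "NA"
            )
        rows.append(row)
    _write(pd.DataFrame(rows), out / "table_hbi_by_bin.tsv", written)

    rows = []
    pcs = pair_df["pct_change_hbi"].to_numpy(dtype=float)
    for a in AGE_GROUPS:
        row = {"age_group": a}
        for b in _CONSUMER_BINS:
            mask = (ages == a) & (bins == b.value) & ~np.isnan(pcs)
            if mask.any():
                est = survey.survey_mean(pcs, w, strata, psus, domain_mask=mask)
                test = survey.paired_t(
                    hbi_pred, hbi_obs, w, strata, psus, m_comparisons=m, domain_mask=mask
                )
                row[f"pct_change_{b.value}"] = _fmt(est)
                row[f"p_bonf_{b.value}"] = (
                    f"{test.p_bonferroni:.4g}" if test.p_bonferroni is not None else "NA"
                )
            else:
                row[f"pct_change_{b.value}"] = "NA"
                row[f"p_bonf_{b.value}"] = "NA"
        rows.append(row)
    _write(pd.DataFrame(rows), out / "table_hbi_pct_change.tsv", written)

    # ---- BMI-category prevalence under each weight scenario ----
    cat_levels = [c.value for c in BMICategory]
    scen_rows = []
    m_prev = len(cfg.scenarios) * len(cat_levels)
    for scenario in cfg.scenarios:
        recl = apply_scenario(persons, pair_by_id, scenario)
        rdf = pd.DataFrame(
            {
                "person_id": [r.person_id for r in recl],
                "substituted": [r.substituted for r in recl],
                "observed_bmi": [r.observed_bmi for r in recl],
                "predicted_bmi": [r.predicted_bmi for r in recl],
                "observed_category": [r.observed_category.value for r in recl],
                "predicted_category": [r.predicted_category.value for r in recl],
                "svy_weight": [r.svy_weight for r in recl],
                "stratum": [r.stratum for r in recl],
                "psu": [r.psu for r in recl],
            }
        )
        _write(rdf, out / f"reclassified_{scenario.label}.tsv", written)
        obs_prev = survey.weighted_prevalence(
            rdf["observed_category"], w, strata, psus, levels=cat_levels
        )
        pred_prev = survey.weighted_prevalence(
            rdf["predicted_category"], w, strata, psus, levels=cat_levels
        )
        for level in cat_levels:
            obs_ind = (rdf["observed_category"] == level).to_numpy(float) * 100.0
            pred_ind = (rdf["predicted_category"] == level).to_numpy(float) * 100.0
            test = survey.paired_t(pred_ind, obs_ind, w, strata, psus, m_comparisons=m_prev)
            scen_rows.append(
                {
                    "scenario": scenario.label,
                    "delta_kg": scenario.delta_kg,
                    "category": level,
                    "observed_pct": _fmt(obs_prev[level]),
                    "predicted_pct": _fmt(pred_prev[level]),
                    "observed_pct_value": obs_prev[level].estimate,
                    "predicted_pct_value": pred_prev[level].estimate,
                    "p_bonferroni": f"{test.p_bonferroni:.4g}"
                    if test.p_bonferroni is not None
                    else "NA",
                    "significant": test.significant,
                }
            )
    _write(pd.DataFrame(scen_rows), out / "table_bmi_prevalence.tsv", written)

    log = {
        "n_persons": len(persons),
        "n_roster_rows": ingest.n_rows if ingest else len(persons),
        "n_excluded_missing": ingest.n_excluded_missing if ingest else 0,
        "m_comparisons_hbi": m,
        "m_comparisons_prevalence": m_prev,
        "seed": cfg.seed if cfg.seed is not None else (cfg.synthetic.seed if cfg.synthetic else None),
        "policy": cfg.policy.model_dump(mode="json"),
        "scenarios": [s.model_dump() for s in cfg.scenarios],
    }
    log["policy"]["apply_to"] = sorted(log["policy"]["apply_to"])
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written.append(path)

    return PipelineResult(
        out_dir=out, n_persons=len(persons), ingest=ingest, m_comparisons=m
    )


def _write(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
    written.append(path)
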