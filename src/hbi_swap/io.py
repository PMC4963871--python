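"""Delimited-text readers and writers for person and beverage tables.

Schemas
-------
Person table (TSV):
    person_id, age_years, sex (M/F), weight_kg, height_cm, total_kcal,
    svy_weight, stratum, psu
Beverage table (TSV):
    person_id, food_code, group_label (optional), volume_oz, energy_kcal

Heights are accepted in cm on file and stored in metres. Persons flagged
as missing dietary data — no beverage rows AND a missing total_kcal —
are excluded on ingest and counted, mirroring the analytic-sample
construction of a dietary survey.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import GroupMapping, default_mapping
from .model import BeverageRecord, PersonDay, ValidationError

logger = logging.getLogger(__name__)

PERSON_COLUMNS = [
    "person_id", "age_years", "sex", "weight_kg", "height_cm",
    "total_kcal", "svy_weight", "stratum", "psu",
]
BEVERAGE_COLUMNS = ["person_id", "food_code", "group_label", "volume_oz", "energy_kcal"]


@dataclass
class IngestReport:
    """Bookkeeping from :func:`read_tables`."""

    n_rows: int
    n_excluded_missing: int

    @property
    def n_retained(self) -> int:
        return self.n_rows - self.n_excluded_missing


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_tables(
    person_path,
    beverage_path,
    mapping: GroupMapping | None = None,
) -> tuple[list[PersonDay], IngestReport]:
    """Read person and beverage tables into validated :class:`PersonDay` rows.

    Returns the retained persons plus an :class:`IngestReport` with the
    number of roster rows and the count excluded for missing dietary data.
    """
    mapping = mapping or default_mapping()
    persons_df = pd.read_csv(person_path, sep="\t", dtype={"person_id": str, "stratum": str, "psu": str})
    bev_df = pd.read_csv(
        beverage_path, sep="\t", dtype={"person_id": str, "food_code": str, "group_label": str}
    )
    _require_columns(persons_df, PERSON_COLUMNS, "person")
    required_bev = [c for c in BEVERAGE_COLUMNS if c != "group_label"]
    _require_columns(bev_df, required_bev, "beverage")
    has_label = "group_label" in bev_df.columns

    records_by_person: dict[str, list[BeverageRecord]] = {}
    for i, row in enumerate(bev_df.itertuples(index=False), start=2):  # 1-based + header
        vol = float(row.volume_oz)
        kcal = float(row.energy_kcal)
        if vol < 0:
            raise ValidationError(f"beverage table row {i}: negative volume_oz ({vol})")
        if kcal < 0:
            raise ValidationError(f"beverage table row {i}: negative energy_kcal ({kcal})")
        label = getattr(row, "group_label", None) if has_label else None
        if isinstance(label, float) and math.isnan(label):
            label = None
        group = mapping.classify(row.food_code, label)
        rec = BeverageRecord(
            person_id=row.person_id,
            food_code=str(row.food_code),
            group=group,
            volume_oz=vol,
            energy_kcal=kcal,
        )
        records_by_person.setdefault(row.person_id, []).append(rec)

    persons: list[PersonDay] = []
    n_excluded = 0
    for i, row in enumerate(persons_df.itertuples(index=False), start=2):
        pid = row.person_id
        beverages = records_by_person.get(pid, [])
        total_kcal_missing = pd.isna(row.total_kcal)
        if total_kcal_missing and not beverages:
            n_excluded += 1
            continue
        if total_kcal_missing:
            raise ValidationError(
                f"person table row {i} (id {pid}): total_kcal missing but beverage rows present"
            )
        height_cm = float(row.height_cm)
        if not height_cm > 0:
            raise ValidationError(f"person table row {i} (id {pid}): height_cm must be > 0, got {height_cm}")
        persons.append(
            PersonDay(
                person_id=pid,
                age_years=int(row.age_years),
                sex=str(row.sex),
                weight_kg=float(row.weight_kg),
                height_m=height_cm / 100.0,
                total_kcal=float(row.total_kcal),
                svy_weight=float(row.svy_weight),
                stratum=str(row.stratum),
                psu=str(row.psu),
                beverages=beverages,
            )
        )
    report = IngestReport(n_rows=len(persons_df), n_excluded_missing=n_excluded)
    logger.info(
        "ingest: %d roster rows, %d excluded for missing dietary data, %d retained",
        report.n_rows, report.n_excluded_missing, report.n_retained,
    )
    return persons, report


def persons_to_frames(persons: list[PersonDay]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten persons into (person table, beverage table) DataFrames."""
    prow = [
        {
            "person_id": p.person_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "weight_kg": p.weight_kg,
            "height_cm": p.height_m * 100.0,
            "total_kcal": p.total_kcal,
            "svy_weight": p.svy_weight,
            "stratum": p.stratum,
            "psu": p.psu,
        }
        for p in persons
    ]
    brow = [
        {
            "person_id": r.person_id,
            "food_code": r.food_code,
            "group_label": r.group.value,
            "volume_oz": r.volume_oz,
            "energy_kcal": r.energy_kcal,
        }
        for p in persons
        for r in p.beverages
    ]
    persons_df = pd.DataFrame(prow, columns=PERSON_COLUMNS)
    bev_df = pd.DataFrame(brow, columns=BEVERAGE_COLUMNS)
    return persons_df, bev_df


def write_tables(persons: list[PersonDay], out_dir) -> tuple[Path, Path]:
    """Write the two TSV files; floats use repr so the round-trip is lossless."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    persons_df, bev_df = persons_to_frames(persons)
    ppath = out / "persons.tsv"
    bpath = out / "beverages.tsv"
    persons_df.to_csv(ppath, sep="\t", index=False)
    bev_df.to_csv(bpath, sep="\t", index=False)
    return ppath, bpath
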