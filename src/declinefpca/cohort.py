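"""Cohort construction: inclusion filters and primary-center assignment.

Encounter-level registry records (patient_id, year, center_id, encounter_age,
fev1pp) are restricted to ages 6-21, patients with fewer than 7 retained
measurements are dropped (too few points for stable trajectory estimation),
and each patient is assigned the primary care center at which they spent the
most years of follow-up. Centers are categorized by primary-patient count as
small (<30), medium (30-150) or large (>150).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "CohortTable",
    "read_encounters",
    "restrict_age_window",
    "deduplicate",
    "filter_min_encounters",
    "assign_primary_center",
    "categorize_center_size",
    "build_cohort",
]

REQUIRED_COLUMNS = ["patient_id", "year", "center_id", "encounter_age", "fev1pp"]

SMALL_MAX = 30    # small: count < 30
MEDIUM_MAX = 150  # medium: 30 <= count <= 150; large: count > 150


def read_encounters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"encounter table missing columns: {missing}")
    return df


def restrict_age_window(records: pd.DataFrame, age_min: float = 6.0,
                        age_max: float = 21.0) -> pd.DataFrame:
    """Keep encounters with age_min <= encounter_age <= age_max (inclusive)."""
    out = records[(records["encounter_age"] >= age_min)
                  & (records["encounter_age"] <= age_max)].copy()
    if out.empty:
        warnings.warn("age restriction removed every encounter", stacklevel=2)
    return out


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Drop repeated (patient_id, encounter_age) rows, keeping the first."""
    return records.drop_duplicates(subset=["patient_id", "encounter_age"], keep="first")


def filter_min_encounters(records: pd.DataFrame, min_encounters: int = 7) -> pd.DataFrame:
    """Remove patients with fewer than min_encounters retained measurements."""
    counts = records.groupby("patient_id")["encounter_age"].size()
    keep = counts[counts >= min_encounters].index
    return records[records["patient_id"].isin(keep)].copy()


def assign_primary_center(records: pd.DataFrame) -> pd.Series:
    """Per patient, the center with the most distinct years of follow-up.

    Ties are broken deterministically: the center attended earliest wins,
    then the lexicographically smaller center id.
    """
    per = (records.drop_duplicates(["patient_id", "center_id", "year"])
           .groupby(["patient_id", "center_id"])["year"]
           .agg(n_years="nunique", first_year="min")
           .reset_index())
    per = per.sort_values(
        ["patient_id", "n_years", "first_year", "center_id"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    primary = per.groupby("patient_id", sort=True).first()["center_id"]
    primary.name = "primary_center"
    return primary


def categorize_center_size(center_counts: pd.Series) -> pd.Series:
    """Map primary-patient counts to small (<30) / medium (30-150) / large (>150)."""
    def cat(n: int) -> str:
        if n < SMALL_MAX:
            return "small"
        if n <= MEDIUM_MAX:
            return "medium"
        return "large"

    out = center_counts.map(cat)
    out.name = "size_category"
    return out


@dataclass
class CohortTable:
    """Filtered encounters plus the per-patient and per-center assignments."""

    records: pd.DataFrame
    primary_center: pd.Series   # index patient_id
    center_counts: pd.Series    # index center_id -> n primary patients
    size_category: pd.Series    # index center_id -> small/medium/large

    @property
    def n_patients(self) -> int:
        return int(self.primary_center.size)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"n_patients": self.center_counts,
                            "size_category": self.size_category})
        out.index.name = "center_id"
        return out.reset_index()

    def write_summary_csv(self, path: str | Path) -> None:
        self.summary().to_csv(path, index=False)


def build_cohort(records: pd.DataFrame, *, age_min: float = 6.0, age_max: float = 21.0,
                 min_encounters: int = 7) -> CohortTable:
    """Apply age window -> de-duplication -> minimum-encounter filter, then
    assign primary centers and size categories.

    The encounter-count threshold is applied after the age restriction, so
    only measurements inside the analysis window count toward eligibility.
    """
    recs = restrict_age_window(records, age_min, age_max)
    recs = deduplicate(recs)
    recs = filter_min_encounters(recs, min_encounters)
    primary = assign_primary_center(recs)
    counts = primary.value_counts().sort_index()
    counts.index.name = "center_id"
    return CohortTable(
        records=recs.reset_index(drop=True),
        primary_center=primary,
        center_counts=counts,
        size_category=categorize_center_size(counts),
    )
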