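"""Center-level aggregation and size-category benchmarking.

Fitted patient trajectories are aggregated to the primary care center:
per-phenotype functional means and mean rate-of-change curves, phenotype
prevalences, and peak-decline summaries. Centers are then compared across
size categories (small/medium/large) variable by variable with two-sample
Welch t-tests, Bonferroni-adjusted for the three pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phenotyping import LABELS, peak_decline_table

__all__ = [
    "CenterProfile",
    "CategoryComparison",
    "center_functional_mean",
    "center_rate_mean",
    "prevalence_by_center",
    "build_center_profiles",
    "summarize_table1",
    "compare_categories",
    "patient_table",
    "curve_table",
]

CATEGORY_ORDER = ("small", "medium", "large")
PAIRS = (("small", "medium"), ("medium", "large"), ("small", "large"))


@dataclass
class CenterProfile:
    """Aggregates for one care center; absent phenotype cells hold no curve."""

    center_id: str
    size_category: str
    n_patients: int
    prevalence: dict[str, float]                 # % per phenotype, sums to 100
    mean_trajectory: dict[str, np.ndarray]       # phenotype -> curve on grid
    mean_rate: dict[str, np.ndarray]
    peak_extent_mean: float                      # mean over the center's patients
    peak_age_mean: float
    fpc1_mean: float
    baseline_age_mean: float
    baseline_fev_mean: float


def _cell_means(curves: pd.DataFrame, labels: pd.Series,
                centers: pd.Series) -> dict[tuple[str, str], np.ndarray]:
    """Pointwise mean curve per (center, phenotype) cell; empty cells absent."""
    out: dict[tuple[str, str], np.ndarray] = {}
    df = curves.copy()
    meta = pd.DataFrame({"label": labels, "center": centers}).loc[df.index]
    for (center, label), sub in df.groupby([meta["center"], meta["label"]], sort=True):
        out[(str(center), str(label))] = sub.to_numpy(dtype=float).mean(axis=0)
    return out


def center_functional_mean(curves: pd.DataFrame, labels: pd.Series,
                           centers: pd.Series) -> dict[tuple[str, str], np.ndarray]:
    """Per-center, per-phenotype mean fitted trajectory on the common grid."""
    return _cell_means(curves, labels, centers)


def center_rate_mean(derivatives: pd.DataFrame, labels: pd.Series,
                     centers: pd.Series) -> dict[tuple[str, str], np.ndarray]:
    """Per-center, per-phenotype mean rate-of-change curve."""
    return _cell_means(derivatives, labels, centers)


def prevalence_by_center(labels: pd.Series, centers: pd.Series) -> pd.DataFrame:
    """Phenotype percentages per center (rows sum to 100)."""
    df = pd.DataFrame({"label": labels, "center": centers})
    counts = df.groupby(["center", "label"]).size().unstack(fill_value=0)
    for lab in LABELS:
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[list(LABELS)]
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    pct.index.name = "center_id"
    return pct


def _baselines(records: pd.DataFrame) -> pd.DataFrame:
    """Each patient's first in-window encounter: baseline age and FEV1."""
    first = (records.sort_values(["patient_id", "encounter_age"], kind="stable")
             .groupby("patient_id").first())
    return first[["encounter_age", "fev1pp"]].rename(
        columns={"encounter_age": "baseline_age", "fev1pp": "baseline_fev1pp"})


def build_center_profiles(curves: pd.DataFrame, derivatives: pd.DataFrame,
                          labels: pd.Series, cohort, scores: pd.Series) -> list[CenterProfile]:
    """Assemble one CenterProfile per center from patient-level pieces.

    ``cohort`` is a CohortTable (primary centers, size categories, records);
    ``scores`` is the per-patient FPC1 score series.
    """
    centers = cohort.primary_center.loc[curves.index]
    traj = center_functional_mean(curves, labels, centers)
    rate = center_rate_mean(derivatives, labels, centers)
    prev = prevalence_by_center(labels, centers)
    peaks = peak_decline_table(derivatives)
    base = _baselines(cohort.records).loc[curves.index]

    profiles = []
    for center_id in cohort.center_counts.index:
        pids = centers.index[centers == center_id]
        if len(pids) == 0:
            continue
        profiles.append(CenterProfile(
            center_id=str(center_id),
            size_category=str(cohort.size_category.loc[center_id]),
            n_patients=int(len(pids)),
            prevalence={lab: float(prev.loc[center_id, lab]) for lab in LABELS},
            mean_trajectory={lab: traj[(center_id, lab)] for lab in LABELS
                             if (center_id, lab) in traj},
            mean_rate={lab: rate[(center_id, lab)] for lab in LABELS
                       if (center_id, lab) in rate},
            peak_extent_mean=float(peaks.loc[pids, "peak_extent"].mean()),
            peak_age_mean=float(peaks.loc[pids, "peak_age"].mean()),
            fpc1_mean=float(scores.loc[pids].mean()),
            baseline_age_mean=float(base.loc[pids, "baseline_age"].mean()),
            baseline_fev_mean=float(base.loc[pids, "baseline_fev1pp"].mean()),
        ))
    return profiles


_TABLE1_VARS = {
    "baseline_age": "baseline_age_mean",
    "baseline_fev1pp": "baseline_fev_mean",
    "fpc1_score": "fpc1_mean",
    "prevalence_early": ("prevalence", "early"),
    "prevalence_middle": ("prevalence", "middle"),
    "prevalence_late": ("prevalence", "late"),
    "peak_extent": "peak_extent_mean",
    "peak_age": "peak_age_mean",
}


def center_values(profiles: list[CenterProfile], variable: str) -> dict[str, np.ndarray]:
    """Center-level values of a summary variable, grouped by size category."""
    spec = _TABLE1_VARS[variable]
    out: dict[str, list[float]] = {c: [] for c in CATEGORY_ORDER}
    for p in profiles:
        v = p.prevalence[spec[1]] if isinstance(spec, tuple) else getattr(p, spec)
        out[p.size_category].append(float(v))
    return {c: np.asarray(v, dtype=float) for c, v in out.items()}


def summarize_table1(profiles: list[CenterProfile]) -> pd.DataFrame:
    """Size-category summary of center characteristics and decline features.

    Per category: number of centers (n, %), patients per center mean (SD),
    patients across centers (n, %), then mean (SD) across centers of the
    center-level means of baseline age/FEV1, FPC1 score, phenotype
    prevalences, and peak-decline extent/age. Centers are weighted equally
    within category; SD is absent for categories with fewer than 2 centers.
    """
    n_centers_total = len(profiles)
    n_patients_total = sum(p.n_patients for p in profiles)
    rows = []
    for cat in CATEGORY_ORDER:
        ps = [p for p in profiles if p.size_category == cat]
        if not ps:
            continue
        sizes = np.array([p.n_patients for p in ps], dtype=float)
        row = {
            "size_category": cat,
            "n_centers": len(ps),
            "pct_centers": 100.0 * len(ps) / n_centers_total,
            "patients_per_center_mean": sizes.mean(),
            "patients_per_center_sd": sizes.std(ddof=1) if len(ps) > 1 else np.nan,
            "n_patients": int(sizes.sum()),
            "pct_patients": 100.0 * sizes.sum() / n_patients_total,
        }
        for var in _TABLE1_VARS:
            vals = center_values(ps, var)[cat]
            row[f"{var}_mean"] = vals.mean()
            row[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("size_category")


@dataclass(frozen=True)
class CategoryComparison:
    """Pairwise Welch t-tests for one variable across size categories."""

    variable: str
    means: dict[str, float]
    sds: dict[str, float]
    t_stats: dict[tuple[str, str], float]
    raw_p: dict[tuple[str, str], float]
    adjusted_p: dict[tuple[str, str], float]  # Bonferroni, factor 3, capped at 1


def compare_categories(values_by_category: dict[str, np.ndarray],
                       variable: str = "") -> CategoryComparison:
    """Welch unequal-variance t-test for each category pair, Bonferroni x3."""
    t_stats, raw_p, adj_p = {}, {}, {}
    for a, b in PAIRS:
        x, y = values_by_category.get(a), values_by_category.get(b)
        if x is None or y is None or len(x) < 2 or len(y) < 2:
            continue
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            if np.mean(x) == np.mean(y):
                t_stats[(a, b)], raw_p[(a, b)], adj_p[(a, b)] = 0.0, 1.0, 1.0
                continue
            raise ValueError(f"zero variance in both groups for {a} vs {b}")
        res = stats.ttest_ind(x, y, equal_var=False)
        t_stats[(a, b)] = float(res.statistic)
        raw_p[(a, b)] = float(res.pvalue)
        adj_p[(a, b)] = min(1.0, 3.0 * float(res.pvalue))
    means = {c: float(np.mean(v)) for c, v in values_by_category.items() if len(v)}
    sds = {c: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
           for c, v in values_by_category.items() if len(v)}
    return CategoryComparison(variable, means, sds, t_stats, raw_p, adj_p)


def patient_table(scores: pd.Series, labels: pd.Series, cohort,
                  derivatives: pd.DataFrame) -> pd.DataFrame:
    """Patient-level analysis table: center, score, label, peak extent/age."""
    peaks = peak_decline_table(derivatives)
    out = pd.DataFrame({
        "center_id": cohort.primary_center.loc[scores.index],
        "fpc1_score": scores,
        "label": labels,
        "peak_extent": peaks["peak_extent"],
        "peak_age": peaks["peak_age"],
    })
    out.index.name = "patient_id"
    return out.reset_index()


def curve_table(traj_means: dict[tuple[str, str], np.ndarray],
                rate_means: dict[tuple[str, str], np.ndarray],
                grid: np.ndarray) -> pd.DataFrame:
    """Long-format curve table: center, phenotype, age, mean_fev1pp, mean_rate."""
    rows = []
    for (center, label), curve in sorted(traj_means.items()):
        rate = rate_means.get((center, label))
        for g, age in enumerate(grid):
            rows.append({"center_id": center, "label": label, "age": float(age),
                         "mean_fev1pp": float(curve[g]),
                         "mean_rate": float(rate[g]) if rate is not None else np.nan})
    return pd.DataFrame(rows)


def write_analysis_csvs(curve_tab: pd.DataFrame, patient_tab: pd.DataFrame,
                        directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    curve_tab.to_csv(d / "center_curves.csv", index=False)
    patient_tab.to_csv(d / "patient_summary.csv", index=False)
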