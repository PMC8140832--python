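"""Decline phenotypes from first-component scores; peak-decline statistics.

Patients are classified by cohort-wide quartiles of the first functional
principal component score (oriented so higher = more rapid decline):

* score < Q1  -> "late"  decliner (mildest decline),
* Q1 <= score <= Q3 -> "middle" decliner,
* score > Q3  -> "early" decliner (most rapid).

Quartiles use the linear-interpolation convention of the empirical
distribution; the thresholds are recorded with each assignment because label
boundaries depend on it. Peak decline is the lowest point of a fitted
trajectory's derivative and the (first) grid age attaining it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fpca import FittedPatientCurve

__all__ = ["LABELS", "PhenotypeAssignment", "PeakDecline", "classify_decliners",
           "assignments_frame", "peak_decline", "peak_decline_table"]

LABELS = ("early", "middle", "late")


@dataclass(frozen=True)
class PhenotypeAssignment:
    patient_id: str
    fpc1_score: float
    label: str
    q1: float
    q3: float


@dataclass(frozen=True)
class PeakDecline:
    extent: float        # % predicted / year, minimum of the derivative
    age_at_peak: float   # grid age attaining it (first on ties)


def classify_decliners(scores: pd.Series) -> list[PhenotypeAssignment]:
    """Quartile-based early/middle/late classification of FPC1 scores.

    Thresholds are computed cohort-wide (a single Q1/Q3 for the run);
    boundary scores exactly at a threshold are classified middle.
    """
    vals = scores.to_numpy(dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 patients with finite scores")
    if not np.all(np.isfinite(vals)):
        raise ValueError("scores must be finite")
    q1, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.75]))
    if q1 == q3:
        warnings.warn("degenerate quartiles (identical scores); everyone classified middle",
                      stacklevel=2)
    out = []
    for pid, s in scores.items():
        s = float(s)
        label = "late" if s < q1 else ("early" if s > q3 else "middle")
        out.append(PhenotypeAssignment(str(pid), s, label, q1, q3))
    return out


def assignments_frame(assignments: list[PhenotypeAssignment]) -> pd.DataFrame:
    """Labels table: patient_id, fpc1_score, label, q1, q3."""
    return pd.DataFrame(
        {"patient_id": [a.patient_id for a in assignments],
         "fpc1_score": [a.fpc1_score for a in assignments],
         "label": [a.label for a in assignments],
         "q1": [a.q1 for a in assignments],
         "q3": [a.q3 for a in assignments]}
    )


def write_labels_csv(assignments: list[PhenotypeAssignment], path: str | Path) -> None:
    assignments_frame(assignments).to_csv(path, index=False)


def peak_decline(curve: FittedPatientCurve) -> PeakDecline:
    """Lowest point of the rate-of-change curve and the age where it occurs."""
    d = np.asarray(curve.derivative, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("derivative contains non-finite values")
    i = int(np.argmin(d))  # argmin returns the first index on ties
    return PeakDecline(extent=float(d[i]), age_at_peak=float(curve.grid[i]))


def peak_decline_table(derivatives: pd.DataFrame) -> pd.DataFrame:
    """Per-patient peak decline from a (patients x grid) derivative frame."""
    d = derivatives.to_numpy(dtype=float)
    grid = derivatives.columns.to_numpy(dtype=float)
    idx = np.argmin(d, axis=1)
    return pd.DataFrame({"peak_extent": d[np.arange(len(d)), idx],
                         "peak_age": grid[idx]},
                        index=derivatives.index)
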