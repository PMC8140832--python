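"""Synthetic CF-registry cohort generator with known latent structure.

Real encounter-level registry data on cystic fibrosis lung function cannot be
shared, so every downstream stage of this package is exercised on cohorts
drawn from the latent model the analysis itself assumes:

    Y_ij = mu(t_ij) + sum_k xi_ik * phi_k(t_ij) + eps_ij,

where ``mu`` is a declining population mean of FEV1 % predicted over ages
6-21, ``phi_k`` are orthonormal principal-component functions whose scores
``xi_ik ~ N(0, sd_k^2)`` govern the timing and severity of each patient's
decline, and ``eps_ij ~ N(0, noise_sd^2)`` is spirometry measurement error.
Patients are nested in care centers of small/medium/large size and may
transfer between centers over calendar years. The generator returns both the
encounter table and the ground truth (scores, labels, curves) so recovery can
be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "default_mean",
    "default_eigenfunctions",
    "generate_cohort",
    "true_trajectory",
    "write_cohort_csv",
    "write_truth",
]

AGE_MIN, AGE_MAX = 6.0, 21.0
REFERENCE_GRID = np.linspace(AGE_MIN, AGE_MAX, 61)


_MEAN_A, _MEAN_B, _MEAN_C, _MEAN_S = 95.56, 26.9, 14.5, 2.2


def default_mean(t: np.ndarray) -> np.ndarray:
    """Smooth logistic population decline: ~95 %pred at age 6 to ~70 at 21.

    The steepest mean decline (~-3 %pred/year) occurs at age 14.5, in
    adolescence; the curve is differentiable everywhere.
    """
    t = np.asarray(t, dtype=float)
    return _MEAN_A - _MEAN_B / (1.0 + np.exp(-(t - _MEAN_C) / _MEAN_S))


def default_mean_derivative(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    s = 1.0 / (1.0 + np.exp(-(t - _MEAN_C) / _MEAN_S))
    return -(_MEAN_B / _MEAN_S) * s * (1.0 - s)


def _raw_phi1(t: np.ndarray) -> np.ndarray:
    # negated logistic ramp: a high score subtracts an amount that grows
    # through adolescence -> earlier and steeper decline
    return -1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - 12.0) / 1.5))


def _raw_phi2(t: np.ndarray) -> np.ndarray:
    # constant level shift; after orthogonalization against phi1 it becomes
    # a stable between-patient level contrast (a random intercept, the
    # classic second mode of variation in growth curves)
    return np.ones_like(np.asarray(t, dtype=float))


def _orthonormalize(raw_funcs: Sequence[Callable], n_quad: int = 2001) -> list[Callable]:
    """Gram-Schmidt in L2[AGE_MIN, AGE_MAX] via dense trapezoid quadrature.

    Returns callables (linear combinations of the raw functions) usable at
    arbitrary ages.
    """
    tq = np.linspace(AGE_MIN, AGE_MAX, n_quad)

    def inner(f, g):
        return float(np.trapezoid(f(tq) * g(tq), tq))

    funcs: list[Callable] = []
    for raw in raw_funcs:
        proj_coefs = [inner(raw, f) for f in funcs]

        def resid(t, raw=raw, proj_coefs=proj_coefs, basis=list(funcs)):
            out = raw(t).astype(float)
            for c, f in zip(proj_coefs, basis):
                out = out - c * f(t)
            return out

        nrm = math.sqrt(inner(resid, resid))
        if nrm < 1e-12:
            raise ValueError("raw eigenfunctions are linearly dependent")

        def unit(t, resid=resid, nrm=nrm):
            return resid(t) / nrm

        funcs.append(unit)
    return funcs


def default_eigenfunctions() -> list[Callable]:
    """Two orthonormal component shapes on [6, 21] (unit L2 norm)."""
    return _orthonormalize([_raw_phi1, _raw_phi2])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic registry cohort.

    ``center_size_mix`` gives the proportions of small/medium/large centers
    in the center pool; target patient capacities are drawn to straddle the
    30- and 150-patient category boundaries so all three categories occur.
    ``visits_per_year`` is the mean of the per-year visit-count distribution
    (at least one encounter per designated year is always recorded).
    """

    n_patients: int = 500
    center_size_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    visits_per_year: float = 0.9
    age_entry_range: tuple[float, float] = (6.0, 10.0)
    followup_years_range: tuple[int, int] = (8, 12)
    mean_curve: Callable = field(default=default_mean)
    eigenfunctions: tuple[Callable, ...] = field(
        default_factory=lambda: tuple(default_eigenfunctions())
    )
    score_sds: tuple[float, ...] = (25.0, 12.0)
    noise_sd: float = 5.0
    transfer_prob: float = 0.02
    seed: int = 0
    # optional center-size effects (off by default): shift entry ages of
    # patients homed at small centers upward, and their first-component
    # scores downward (milder decline), to emulate older, milder small-center
    # case mixes
    small_center_age_shift: float = 0.0
    small_center_score_shift: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("invalid config: n_patients must be >= 1")
        mix = np.asarray(self.center_size_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("invalid config: center_size_mix must be 3 nonnegative proportions summing to 1")
        if self.visits_per_year <= 0:
            raise ValueError("invalid config: visits_per_year must be positive")
        lo, hi = self.age_entry_range
        if not (AGE_MIN <= lo <= hi <= AGE_MAX):
            raise ValueError("invalid config: age_entry_range must lie within [6, 21]")
        fl, fh = self.followup_years_range
        if not (1 <= fl <= fh):
            raise ValueError("invalid config: followup_years_range must be increasing and >= 1 year")
        # follow-up may nominally run past age 21; encounters beyond 21 are
        # simply not recorded, so the cohort collectively covers ages up to 21
        if len(self.score_sds) != len(self.eigenfunctions):
            raise ValueError("invalid config: score_sds and eigenfunctions must have equal length")
        sds = np.asarray(self.score_sds, dtype=float)
        if sds.size and (np.any(sds <= 0) or np.any(np.diff(sds) >= 0)):
            raise ValueError("invalid config: score_sds must be positive and strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("invalid config: noise_sd must be nonnegative")
        if not (0.0 <= self.transfer_prob <= 1.0):
            raise ValueError("invalid config: transfer_prob must be a probability")


@dataclass
class SyntheticTruth:
    """Generator ground truth used as the oracle in recovery tests."""

    scores: pd.DataFrame          # index patient_id, columns xi1..xiK
    labels: pd.Series             # early/middle/late from quartiles of true xi1
    centers_by_year: pd.DataFrame # patient_id, year, center_id
    grid: np.ndarray
    mean_on_grid: np.ndarray
    eigenfunctions_on_grid: np.ndarray  # (K, G)
    score_sds: np.ndarray
    noise_sd: float
    config: GeneratorConfig

    def patient_ids(self) -> list[str]:
        return list(self.scores.index)


def _quartile_labels(xi1: np.ndarray) -> np.ndarray:
    """Exact 25/50/25 split (up to rounding) by rank of the first score."""
    n = len(xi1)
    order = np.argsort(xi1, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    n_late = n // 4
    n_early = n // 4
    labels = np.full(n, "middle", dtype=object)
    labels[ranks < n_late] = "late"          # lowest quartile: mildest decline
    labels[ranks >= n - n_early] = "early"   # highest quartile: most rapid
    return labels


def _draw_center_pool(rng: np.random.Generator, config: GeneratorConfig) -> list[tuple[str, int]]:
    """Centers with target capacities straddling the 30/150 boundaries."""
    size_ranges = {"small": (8, 26), "medium": (40, 140), "large": (160, 230)}
    categories = ["small", "medium", "large"]
    pool: list[tuple[str, int]] = []
    capacity = 0
    # guarantee each category occurs once when the cohort can hold it
    forced = [c for c in categories if size_ranges[c][0] <= config.n_patients]
    k = 0
    while capacity < config.n_patients:
        if forced:
            cat = forced.pop(0)
        else:
            cat = rng.choice(categories, p=np.asarray(config.center_size_mix))
        lo, hi = size_ranges[cat]
        target = int(rng.integers(lo, hi + 1))
        pool.append((f"C{k:03d}", target))
        capacity += target
        k += 1
    return pool


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort of encounter records plus its ground truth.

    Deterministic given ``config.seed``. Returns a DataFrame with columns
    patient_id, year, center_id, encounter_age, fev1pp.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    K = len(config.eigenfunctions)

    pool = _draw_center_pool(rng, config)
    center_ids = [c for c, _ in pool]
    targets = np.array([t for _, t in pool], dtype=float)
    slots = np.repeat(np.arange(len(pool)), [t for _, t in pool])
    rng.shuffle(slots)
    home_center = slots[:n]

    scores = rng.normal(size=(n, K)) * np.asarray(config.score_sds) if K else np.zeros((n, 0))
    entry_ages = rng.uniform(*config.age_entry_range, size=n)
    if config.small_center_age_shift or config.small_center_score_shift:
        small_home = np.array([targets[c] < 30 for c in home_center])
        entry_ages = np.where(
            small_home, np.minimum(entry_ages + config.small_center_age_shift, 13.0),
            entry_ages)
        if K:
            scores[small_home, 0] -= config.small_center_score_shift
    fl, fh = config.followup_years_range
    followups = rng.integers(fl, fh + 1, size=n)
    entry_years = rng.integers(1997, 2007, size=n)

    pids = [f"P{i:05d}" for i in range(n)]
    rec_pid, rec_year, rec_center, rec_age, rec_val = [], [], [], [], []
    cby_pid, cby_year, cby_center = [], [], []

    for i in range(n):
        center = int(home_center[i])
        for y in range(int(followups[i])):
            if y > 0 and len(pool) > 1 and rng.uniform() < config.transfer_prob:
                # destination proportional to center size: patients who move
                # overwhelmingly move to larger programs, so the center size
                # distribution is preserved
                p = targets.copy()
                p[center] = 0.0
                center = int(rng.choice(len(pool), p=p / p.sum()))
            year = int(entry_years[i] + y)
            cby_pid.append(pids[i]); cby_year.append(year); cby_center.append(center_ids[center])
            n_visits = max(1, int(rng.poisson(config.visits_per_year)))
            ages = entry_ages[i] + y + np.sort(rng.uniform(0.0, 1.0, size=n_visits))
            ages = ages[ages <= AGE_MAX]
            if ages.size == 0:
                continue
            vals = config.mean_curve(ages)
            for k in range(K):
                vals = vals + scores[i, k] * config.eigenfunctions[k](ages)
            vals = vals + rng.normal(scale=config.noise_sd, size=ages.size)
            rec_pid.extend([pids[i]] * ages.size)
            rec_year.extend([year] * ages.size)
            rec_center.extend([center_ids[center]] * ages.size)
            rec_age.extend(ages.tolist())
            rec_val.extend(vals.tolist())

    records = pd.DataFrame({
        "patient_id": rec_pid,
        "year": rec_year,
        "center_id": rec_center,
        "encounter_age": rec_age,
        "fev1pp": rec_val,
    })

    grid = REFERENCE_GRID.copy()
    phi_grid = np.vstack([f(grid) for f in config.eigenfunctions]) if K else np.zeros((0, grid.size))
    truth = SyntheticTruth(
        scores=pd.DataFrame(scores, index=pids, columns=[f"xi{k+1}" for k in range(K)]),
        labels=pd.Series(_quartile_labels(scores[:, 0]) if K else np.full(n, "middle", dtype=object),
                         index=pids, name="label"),
        centers_by_year=pd.DataFrame({"patient_id": cby_pid, "year": cby_year, "center_id": cby_center}),
        grid=grid,
        mean_on_grid=config.mean_curve(grid),
        eigenfunctions_on_grid=phi_grid,
        score_sds=np.asarray(config.score_sds, dtype=float),
        noise_sd=config.noise_sd,
        config=config,
    )
    return records, truth


def true_trajectory(truth: SyntheticTruth, patient_id: str, grid: np.ndarray) -> np.ndarray:
    """Noiseless latent curve mu + sum_k xi_k phi_k at the requested ages."""
    if patient_id not in truth.scores.index:
        raise KeyError(f"unknown patient {patient_id!r}")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    xi = truth.scores.loc[patient_id].to_numpy()
    out = truth.config.mean_curve(grid)
    for k, f in enumerate(truth.config.eigenfunctions):
        out = out + xi[k] * f(grid)
    return out


def true_derivative(truth: SyntheticTruth, patient_id: str, grid: np.ndarray,
                    eps: float = 1e-5) -> np.ndarray:
    """Central-difference derivative of the noiseless latent curve (%pred/year)."""
    g = np.atleast_1d(np.asarray(grid, dtype=float))
    lo = np.maximum(g - eps, AGE_MIN)
    hi = np.minimum(g + eps, AGE_MAX)
    return (true_trajectory(truth, patient_id, hi) - true_trajectory(truth, patient_id, lo)) / (hi - lo)


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    cols = ["patient_id", "year", "center_id", "encounter_age", "fev1pp"]
    records[cols].to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, directory: str | Path) -> None:
    """Truth tables as CSV plus a structured-text sidecar of scalar metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tab = truth.scores.copy()
    tab["label"] = truth.labels
    tab.to_csv(d / "truth_scores.csv", index_label="patient_id")
    truth.centers_by_year.to_csv(d / "truth_centers_by_year.csv", index=False)
    curves = pd.DataFrame({"age": truth.grid, "mean": truth.mean_on_grid})
    for k in range(truth.eigenfunctions_on_grid.shape[0]):
        curves[f"phi{k+1}"] = truth.eigenfunctions_on_grid[k]
    curves.to_csv(d / "truth_curves.csv", index=False)
    lines = [
        f"noise_sd = {truth.noise_sd}",
        f"score_sds = {','.join(str(s) for s in truth.score_sds)}",
        f"n_patients = {len(truth.scores)}",
        f"seed = {truth.config.seed}",
    ]
    (d / "truth_meta.txt").write_text("\n".join(lines) + "\n")


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Convenience: same study conditions, different random seed."""
    return replace(config, seed=seed)
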