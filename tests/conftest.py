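"""Shared fixtures: synthetic cohorts fitted once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from declinefpca import benchmark as bm
from declinefpca import cohort as ch
from declinefpca import fpca as fp
from declinefpca import phenotyping as ph
from declinefpca import synthetic as sg


class Run:
    """Bundle of a generated cohort and everything fitted from it."""

    def __init__(self, config: sg.GeneratorConfig):
        self.config = config
        self.records, self.truth = sg.generate_cohort(config)
        self.cohort = ch.build_cohort(self.records)
        self.model = fp.fit_fpca(self.cohort.records)
        self.curves, self.derivatives = fp.fitted_curves(self.model)
        assignments = ph.classify_decliners(self.model.scores["fpc1"])
        self.assignments = assignments
        self.labels = pd.Series({a.patient_id: a.label for a in assignments},
                                name="label")


@pytest.fixture(scope="session")
def default_run() -> Run:
    """Default two-component cohort (n=500, noise SD 5, seed 0)."""
    return Run(sg.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def lownoise_run() -> Run:
    """Dense, low-noise cohort for curve/peak recovery checks."""
    return Run(sg.GeneratorConfig(n_patients=500, seed=0, noise_sd=1.0,
                                  visits_per_year=3.0, age_entry_range=(6.0, 8.0),
                                  followup_years_range=(10, 13)))


@pytest.fixture(scope="session")
def bench_run() -> Run:
    """Multi-center cohort with small-center case-mix effects.

    Small centers are seeded with older entry ages and milder
    first-component loadings; all three size categories occur with at least
    three centers each.
    """
    return Run(sg.GeneratorConfig(n_patients=1200, seed=0,
                                  center_size_mix=(0.4, 0.3, 0.3),
                                  small_center_age_shift=3.0,
                                  small_center_score_shift=20.0))


@pytest.fixture(scope="session")
def bench_profiles(bench_run) -> list[bm.CenterProfile]:
    return bm.build_center_profiles(bench_run.curves, bench_run.derivatives,
                                    bench_run.labels, bench_run.cohort,
                                    bench_run.model.scores["fpc1"])
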