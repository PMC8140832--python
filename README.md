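# declinefpca

Center-level clustering of rapid lung-function decline in cystic fibrosis
(CF) via sparse functional principal components analysis (FPCA).

CF lung function, measured as FEV₁ % predicted at clinic encounters, is
noisy, irregularly sampled, and declines at patient-specific times and
rates — steepest in adolescence. This package is for biostatisticians and
CF quality-improvement teams who want to (1) fit smooth per-patient
trajectories and rate-of-change curves from encounter-level registry data,
(2) classify patients into **early / middle / late** rapid-decline
phenotypes, and (3) benchmark care centers against each other, including an
animated static-HTML dashboard. Because encounter-level CF registry data
cannot be shared, the package ships a synthetic registry generator with
known latent structure, so the entire pipeline is testable end to end.

## Model

For patient *i* at encounter ages *t_ij* ∈ [6, 21] years:

    Y_ij = μ(t_ij) + Σ_k ξ_ik φ_k(t_ij) + ε_ij,
    ξ_ik ~ N(0, λ_k),  ε_ij ~ N(0, σ²)

μ is the population mean curve, φ_k orthonormal eigenfunctions of the
between-patient covariance, ξ_ik the patient's component scores, ε
measurement error. Estimation: penalized-spline mean and covariance
smoothing (same-encounter products excluded so measurement error stays out
of the surface), quadrature eigendecomposition, reduced-rank maximum
likelihood refinement, and conditional-expectation (BLUP) scoring

    ξ̂_i = Λ Φ_iᵀ (Φ_i Λ Φ_iᵀ + σ̂² I)⁻¹ (Y_i − μ̂_i).

Components are oriented so a higher first score means more rapid decline;
patients with ξ̂₁ above the cohort's third quartile are **early** (rapid)
decliners, below the first quartile **late**, between the quartiles
**middle** (50% of the cohort by construction). Peak decline is the
minimum of the fitted trajectory's derivative and the age at which it
occurs. See `docs/methods.md` for details and design rationale.

## Worked example

```python
import pandas as pd
from declinefpca import (GeneratorConfig, generate_cohort, build_cohort,
                         fit_fpca, classify_decliners)

records, truth = generate_cohort(GeneratorConfig(n_patients=500, seed=0))
cohort = build_cohort(records)          # age window, ≥7 encounters, primary centers
model = fit_fpca(cohort.records)
print("K =", model.n_components)
print("eigenvalues =", model.eigenvalues.round(1))
print("error variance =", round(model.error_variance, 2))

assignments = classify_decliners(model.scores["fpc1"])
labels = pd.Series({a.patient_id: a.label for a in assignments})
print(labels.value_counts().to_dict())
```

prints

```
K = 2
eigenvalues = [601.6 138.5]
error variance = 23.76
{'middle': 250, 'early': 125, 'late': 125}
```

The model selects two components by the 90% variance-explained rule. The
generator's truth for this cohort is λ = (625, 144) and σ² = 25: the
first component (timing/severity of adolescent decline) and the second
(stable level differences) are both recovered within a few percent, and the
quartile rule splits the 500 patients exactly 125/250/125. Averaging each
patient's peak decline by phenotype:

```
        peak_extent  peak_age
early         -4.80     13.79
middle        -3.44     14.26
late          -2.43     15.88
```

early decliners lose up to ~4.8 % predicted/year around age 13.8, while
late decliners decline mildly and ~2 years later — the clinical pattern the
phenotypes are meant to capture.

## Pipeline from the shell

```sh
declinefpca simulate --seed 0 --out run/sim
declinefpca fit --encounters run/sim/encounters.csv --out run/fit
declinefpca classify --model run/fit --out run/labels.csv
declinefpca benchmark --encounters run/sim/encounters.csv \
    --model run/fit --labels run/labels.csv --out run/bench
declinefpca report --encounters run/sim/encounters.csv \
    --model run/fit --labels run/labels.csv --seed 0 --out run/dashboard
```

`benchmark` writes the size-category summary table (small <30, medium
30–150, large >150 patients; Welch t-tests with Bonferroni adjustment) and
the long-format curve/patient CSVs. `report` renders the dashboard: a
landing page with five links (FPCA animations, rate-of-change animations,
mean trajectories, mean rates, additional displays), nine selected centers
(three per size category), and per-center GIFs that highlight, smooth, and
collapse each phenotype's curves in late → middle → early order
(early = red, middle = yellow, late = green).

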