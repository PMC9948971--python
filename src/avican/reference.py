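"""Published reference statistics from the avian comparative-oncology study.

These are printed summary statistics of the original 26-analysis battery
(univariate and mass-adjusted phylogenetic regressions of neoplasia and
malignancy prevalence on life-history covariates, plus the two paired
sex-bias sign tests). They serve as fixed inputs for checking the
multiple-testing machinery against the published analysis — they are data,
not values this package computes.
"""

from __future__ import annotations

#: Primary-variable p-values of the 26 reference analyses, in report order:
#: mass, lifespan, incubation, clutch, clutch+mass, clutch (no domesticated),
#: clutch+mass (no domesticated), dimorphism in brightness/hue/mass/tail,
#: sex sign tests, mass·lifespan — each for neoplasia then malignancy.
REFERENCE_P_VALUES: tuple[float, ...] = (
    0.07, 0.29,        # log10 adult mass
    0.82, 0.69,        # lifespan^0.425
    0.49, 0.10,        # incubation length
    0.005, 0.0019,     # clutch (Tukey-transformed)
    0.005, 0.0014,     # clutch + log10 mass
    0.06, 0.004,       # clutch, domesticated excluded
    0.05, 0.004,       # clutch + mass, domesticated excluded
    0.33, 0.76,        # dimorphism in brightness
    0.76, 0.69,        # dimorphism in hue
    0.28, 0.74,        # dimorphism in mass
    0.84, 0.73,        # dimorphism in tail size
    0.16, 0.66,        # sex sign tests
    0.79, 0.97,        # log10 (mass x lifespan)
)

#: Indices (into REFERENCE_P_VALUES) reported as significant after FDR
#: control in the reference analysis: every clutch-size model except the
#: two that lost significance without domesticated species.
REFERENCE_FDR_SIGNIFICANT: tuple[int, ...] = (6, 7, 8, 9, 11, 13)

#: Species pairs entering the reference sex-bias sign tests.
REFERENCE_SIGN_TEST_N_SPECIES: int = 31

#: Reference dataset descriptives (percent scale): mean and maximum
#: neoplasia/malignancy prevalence over the 108-species dataset and the
#: extreme per-order mean malignancy prevalences.
REFERENCE_SUMMARY = {
    "mean_neoplasia_prevalence_pct": 4.4,
    "mean_malignancy_prevalence_pct": 2.3,
    "max_neoplasia_prevalence_pct": 29.03,
    "order_mean_malignancy_max_pct": 2.84,   # Anseriformes
    "order_mean_malignancy_min_pct": 1.12,   # Columbiformes
}
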