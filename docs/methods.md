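# Methods

## Prevalence from necropsy records

The estimand is per-species tumor prevalence in a managed population:
neoplasia prevalence counts any tumor (benign or malignant), malignancy
prevalence only malignant ones, each divided by the species' total necropsy
count after filtering. Counts and proportions are stored together so every
reported prevalence is recomputable from its integer counts.

Filtering happens in a fixed order: infant removal, then origin/species
exclusions, then the minimum-count threshold. A record is an infant when its
age at death is less than or equal to the species' infancy age, taken as the
mean of female and male age at maturity (using whichever is available). When
no numeric age exists, a case-insensitive whole-word search of the free-text
age description against ten keywords (infant, juvenile, immature, adolescent,
hatchling, subadult, neonate, newborn, offspring, fledgling) decides;
hyphenated spellings ("sub-adult", "new-born") also match, substrings
("mature" inside "immature") do not. Records whose species is missing from
the metadata are kept and logged rather than silently dropped — losing them
would bias prevalence for exactly the species with the poorest metadata.
Keyword matching applies only when the numeric age is absent; a numeric adult
age wins over a stray keyword.

For sex comparisons, species need at least 10 necropsies of each sex, and
reproductive-tract tumors are *neutralized* (the record becomes
tumor-negative) rather than deleted, so denominators remain the total
necropsied females and males. Deleting the rows instead would change the
denominators and conflate reproductive management with sex effects.

Thresholds (min 20 necropsies per species, min 10 per sex) are configuration
values with those defaults.

## Trait transforms

Fixed covariate transforms: log10 of adult mass, log10 of mass·lifespan,
lifespan^0.425, and −clutch^−0.125 (the negative sign keeps every rung of the
ladder monotone increasing, so larger clutches remain larger after
transformation). `tukey_select` recovers such exponents from data: it scans
λ from −2 to 2 in steps of 0.025 and returns the grid member maximizing
Shapiro–Wilk W of the transformed sample, breaking ties toward λ = 1. The
λ = 0 rung uses the natural log inside the selector (W is scale-invariant,
so the base is immaterial there), while the fixed mass transform is log10 by
convention; both conventions coexist deliberately. Note the W(λ) profile is
nearly flat when the sample's coefficient of variation is small — with ~100
observations the selected exponent can wander by several grid steps around
the optimum, and only the broad location of λ (near 0 vs near 1 vs negative)
is reliably identified.

Sexual dimorphism is ln(male)/ln(female) per biometric trait; a female value
of exactly 1 makes the score undefined and the pair is dropped (NaN) in the
table builder, or raises in the scalar API.

Outlier screening offers both the two-sided Grubbs test (G = max|x−x̄|/s
against its t-based critical value at α = 0.05) and Rosner's generalized ESD
for up to k = 3 suspects (defaults; both configurable). Rosner's declared
outlier count is the largest step whose statistic exceeds its critical value,
so a masked pair of outliers is caught even when the first step alone is not
significant. Removal never touches non-flagged values.

## Weighted PGLS with Pagel's λ

`vcv_from_tree` builds C by a single post-order traversal: C[i,j] is the
root-to-MRCA depth, C[i,i] the tip depth. Trees lacking branch lengths (NCBI
common-tree topologies) get unit edge lengths by default, or Grafen node
heights (descendant-tip counts) as an alternative; ultrametric matrices are
rescaled to unit depth so λ and σ² are comparable across trees. Tip names are
matched after underscore/space and case normalization.

The error covariance is V(λ) = D·C_λ·D with D = diag(wᵢ), wᵢ = nᵢ^(−1/2).
Placing the weights multiplicatively makes residual variance proportional to
1/nᵢ — the binomial sampling variance of a prevalence estimated from nᵢ
records — and leaves the fit invariant to rescaling all weights (absorbed by
σ²). Estimation whitens through a Cholesky factor of V rather than forming
V⁻¹; when nearly coincident tips make V numerically semidefinite at λ ≈ 1, a
ridge at relative machine scale (1e−10 of the mean diagonal) restores
positive definiteness. A design whose whitened normal matrix has condition
number above 1e12 is rejected as collinear.

λ is estimated by bounded scalar maximization (Brent) of the profile
log-likelihood ℓ(λ) = −½[n log(2πσ̂²(λ)) + log det V(λ) + n] with σ̂²(λ) the
ML (divide-by-n) variance, over [1e−6, 1] with tolerance 1e−6; the bound
endpoints are evaluated explicitly because bounded Brent can stall short of
them. Reported σ̂² for standard errors uses the unbiased n−p divisor. F for
the slopes compares against the V-weighted intercept-only model on
(p−1, n−p) degrees of freedom. Two R² definitions are reported: the V-metric
(generalized) R² about the V-weighted mean, and the ordinary-scale
1 − RSS/TSS of the raw response — the two can differ wildly when λ̂ is small
and weights vary, which is why both are kept.

Known limitation: with λ estimated by profile ML the slope test is slightly
anticonservative at small species counts; the null-calibration test in this
repository runs at 100 species, where the rejection rate at nominal 0.05
stays within Monte-Carlo error, but analyses of a few dozen species should
expect somewhat inflated type-I error (a property of the estimator class,
not of this implementation).

## The 26-analysis battery and multiple testing

The default battery: for each response (neoplasia, malignancy prevalence) —
log10 mass; lifespan^0.425; incubation length; transformed clutch; clutch +
mass; clutch excluding domesticated species; clutch + mass excluding
domesticated; four dimorphism scores (brightness, hue, mass, tail); the
paired sex sign test; and log10(mass·lifespan). Species with missing values
drop listwise per analysis, so per-row species counts differ. The FDR family
is the 26 primary-variable p-values (the first covariate of each model); the
adjusted-for covariate's p is reported but not in the family. The
Benjamini–Hochberg step-up runs at q = 0.05.

The sex comparison is an exact paired sign test: zero differences are
dropped, p = 2·min(tail probabilities) of Binomial(n, ½) capped at 1. The
confidence interval for the median difference is the order-statistic
interval (d₍ₖ₎, d₍ₙ₋ₖ₊₁₎) at the smallest exactly achievable level at or
above the nominal 95% — at n = 31 pairs that level is 97.06%, printed as
97.1%. (Selecting the achievable level *closest* to nominal gives the same
interval at n = 31.)

## Synthetic studies and what they do (not) show

The generator draws a Yule tree (tips S0001…, unit depth; the stem edge is
discarded and the process runs past the n-th speciation so no tip edge has
zero length), traits from N(0, σ²·C_λ), and a latent per-species prevalence
through a logit link: inverse-logit(a + Σb·trait + phylogenetic deviation on
the logit scale). Defaults are study-scaled: 100 species, 20–500 necropsies
per species (uniform; a log-uniform option mirrors real collections' skew),
intercept logit(0.044) for a ~4.4% baseline neoplasia prevalence, malignant
share of tumors 0.5, infant fraction 0.15, reproductive-tumor fraction 0.10
among positives, equal sex ratio, clutch-trait slope 0.8 logit units (chosen
to give ≥ 80% power for the clutch regression at 100 species — the
repository's fixed power target).

The logit link deliberately differs from the linear-Gaussian model PGLS
assumes, so pipeline tests run under realistic misspecification; an exact
`simulate_linear_gaussian` mode (y = Xβ + MVN(0, σ²C_λ)) exists for clean
parameter-recovery checks. Monte-Carlo problem sizes used by the test suite
and acceptance script — 50 random oracle instances at n ≤ 12, 200 recovery
replicates and 1000 null replicates on 100-tip trees — were chosen as the
smallest sizes at which the corresponding Monte-Carlo errors are decisively
below the asserted tolerances.

What passing synthetic tests does *not* show about real data: the generator
has no institution effects, no diagnostic drift over 25 years of records, no
per-tissue tumor taxonomy, no correlation structure among life-history
traits beyond what the tree induces, and its infant labels are clean —
real free-text age fields are messier than the ten keywords.

## Degenerate inputs and tie-breaks

Records with malignancy or a reproductive tumor but no neoplasia flag are
rejected at parse time as internally inconsistent. Zero-variance vectors are
errors for all normality/outlier tests. A sign test with all pairs tied is
an error ("all pairs tied"), not p = 1. Tukey selection ties resolve toward
the identity transform. `compute_prevalence` of an empty table is an empty
table; a pipeline whose filters leave no species aborts with a stage-named
error and removes partial outputs.
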