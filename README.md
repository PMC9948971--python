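# avican

Comparative oncology of birds under managed care: does life history predict
cancer? `avican` turns raw veterinary necropsy records into species-level
tumor prevalence estimates and asks which life-history traits — clutch size,
body mass, lifespan, incubation length, sexual dimorphism — explain the
variation across species, while correcting for the shared evolutionary
history that makes species non-independent data points.

It is written for comparative biologists and veterinary epidemiologists who
have (a) a table of individual necropsies with tumor flags, (b) a species
life-history table, and (c) a phylogeny, and who want the full analysis —
filtering rules, prevalence weights, phylogenetic regression, multiple-testing
control — as a tested, scriptable pipeline rather than a one-off analysis.

## The model

For species *i* with *nᵢ* necropsies of which *kᵢ* report a tumor, neoplasia
prevalence is *pᵢ = kᵢ/nᵢ* (malignancy prevalence analogously, counting only
malignant tumors). Prevalence is regressed on transformed life-history
covariates by **weighted phylogenetic generalized least squares (PGLS)**:

    y = Xβ + ε,   ε ~ N(0, σ² · D C(λ) D)

where `C` is the phylogenetic variance–covariance matrix (shared root-to-MRCA
branch length between species pairs), **Pagel's λ ∈ [0, 1]** scales its
off-diagonal entries (λ=0: star phylogeny, λ=1: pure Brownian motion) and is
estimated by maximizing the profile log-likelihood

    ℓ(λ) = −½ [ n log(2πσ̂²(λ)) + log det V(λ) + n ],

and `D = diag(wᵢ)` with `wᵢ = nᵢ^(−1/2)` downweights species whose prevalence
rests on few necropsies (the binomial sampling scale). Covariates are
normalized on the Tukey ladder of powers (x^λ, log x at λ=0, −x^λ for λ<0);
sexual dimorphism is scored as ln(male)/ln(female). A battery of 26 analyses
(two responses × thirteen models, including paired female-vs-male exact sign
tests) is controlled by Benjamini–Hochberg FDR at q = 0.05.

Before any regression, records are filtered: infants are removed (age at
death at or below the species' mean age at maturity, or an age-description
keyword such as "fledgling" when no age is recorded), wild-origin necropsies
are dropped, chickens (*Gallus gallus*) are excluded by default, and species
need ≥ 20 necropsies (≥ 10 per sex for the sex comparisons, which also
neutralize reproductive-tract tumors).

A synthetic-study generator (`avican.synth`) produces Yule trees, traits with
tunable phylogenetic signal, latent logit-linear prevalences, and individual
necropsy records with exact bookkeeping, so every stage is testable against
known ground truth.

## Worked example

```bash
# generate a synthetic 100-species study with a known clutch-size effect
avican synth --seed 3 --out-dir study/    # writes records.csv, meta.csv, tree.nwk, ...

# species-level prevalence after all filters
avican prevalence --records study/records.csv --meta study/meta.csv \
    --min-n 20 --out study/prevalence.tsv
```

which reports, for example:

```
wrote 100 species to study/prevalence.tsv
```

and a `prevalence.tsv` whose first rows look like

```
species  n    n_neoplasia  n_malignant  neoplasia_prev  malignancy_prev  weight
S0001    314  7            5            0.022293        0.015924         0.056433
S0002    402  10           6            0.024876        0.014925         0.049875
```

`n` counts adult, managed-origin necropsies; `weight = n^(−1/2)` is the PGLS
weight. From Python the same objects are DataFrames:

```python
from avican import synth, records, phylo
import numpy as np

bundle = synth.generate_study(synth.SynthConfig(n_species=100, seed=3))
adults = records.filter_infants(bundle["records"], bundle["meta"])
prev   = records.compute_prevalence(adults)               # one row per species
data   = prev.merge(bundle["traits"], on="species")
vcv    = phylo.vcv_from_tree(bundle["tree"], tips=list(data["species"]))
X      = np.column_stack([np.ones(len(data)), data["clutch_trait"]])
fit    = phylo.ml_lambda(data["neoplasia_prev"].to_numpy(), X, vcv,
                         weights=data["weight"].to_numpy())
print(f"slope={fit.coefficients[1]:.4f}  lambda={fit.lambda_hat:.3f}  "
      f"p={fit.p_values[1]:.2e}")
```

prints (seed 3):

```
slope=0.0271  lambda=0.000  p=7.22e-24
```

— the generated clutch→prevalence effect is recovered: prevalence rises by
about 2.7 percentage points per unit of the latent clutch trait, and
the residual phylogenetic signal λ̂ collapses to the lower bound because the
binomial record-sampling noise dominates after the trait is accounted for.
The full 26-analysis battery with FDR flags comes from `avican battery` or
`avican run --config pipeline.yaml`.

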