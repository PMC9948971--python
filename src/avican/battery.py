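"""The regression battery: 26 analyses, FDR control, and sex-bias sign tests.

The default battery mirrors the study design: univariate weighted PGLS of
neoplasia and malignancy prevalence on each transformed life-history covariate
(log10 mass, lifespan^0.425, incubation length, the Tukey-transformed clutch
size, log10 mass·lifespan), clutch-size models additionally adjusted for mass
and refit excluding domesticated species, four sexual-dimorphism scores, and
paired female-vs-male sign tests — 26 primary p-values in all, controlled by
Benjamini–Hochberg FDR at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import phylo
from .phylo import PGLSFit, PhyloCovariance


class BatteryError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisSpec:
    """One row of the battery: a model to fit and the response it explains."""

    model_id: str
    response: str  # neoplasia_prev | malignancy_prev
    covariates: tuple[str, ...] = ()
    exclude_domesticated: bool = False
    test: str = "pgls"  # pgls | sign_test

    def __post_init__(self):
        if self.test == "pgls" and not self.covariates:
            raise BatteryError(f"{self.model_id}: pgls requires covariates")
        if self.test == "sign_test" and self.covariates:
            raise BatteryError(f"{self.model_id}: sign_test takes no covariates")


def _both(model_id, covariates, **kw):
    return [
        AnalysisSpec(f"{model_id}_neo", "neoplasia_prev", tuple(covariates), **kw),
        AnalysisSpec(f"{model_id}_mal", "malignancy_prev", tuple(covariates), **kw),
    ]


#: The 26-analysis default battery, in report order.
DEFAULT_BATTERY: tuple[AnalysisSpec, ...] = tuple(
    _both("mass", ["log10_mass"])
    + _both("lifespan", ["lifespan_pow"])
    + _both("incubation", ["incubation_months"])
    + _both("clutch", ["clutch_tukey"])
    + _both("clutch_mass", ["clutch_tukey", "log10_mass"])
    + _both("clutch_nodom", ["clutch_tukey"], exclude_domesticated=True)
    + _both("clutch_mass_nodom", ["clutch_tukey", "log10_mass"],
            exclude_domesticated=True)
    + _both("dim_brightness", ["dim_brightness"])
    + _both("dim_hue", ["dim_hue"])
    + _both("dim_mass", ["dim_mass"])
    + _both("dim_tail", ["dim_tail"])
    + [AnalysisSpec("sex_neo", "neoplasia_prev", (), test="sign_test"),
       AnalysisSpec("sex_mal", "malignancy_prev", (), test="sign_test")]
    + _both("mass_lifespan", ["log10_mass_lifespan"])
)
assert len(DEFAULT_BATTERY) == 26


@dataclass
class SignTestResult:
    """Exact paired sign test with an order-statistic CI for the median difference."""

    n_pairs: int
    n_nonzero: int
    n_positive: int
    p_value: float
    ci_level: float
    ci_lower: float
    ci_upper: float


@dataclass
class BatteryResult:
    rows: list[tuple[AnalysisSpec, object]]
    p_values: np.ndarray
    p_adjusted: np.ndarray
    fdr_pass: np.ndarray
    q: float
    report: pd.DataFrame = field(default=None)


def bh_fdr(p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (pass flags, adjusted p-values). Flags mark every p at or below
    the largest p(i) with p(i) ≤ i·q/m.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p <= 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise BatteryError("p-values must lie in (0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def sign_test_ci_level(n: int, nominal: float = 0.95) -> tuple[int, float]:
    """Order-statistic index k and exact coverage for a median CI at size n.

    The interval (d_(k), d_(n−k+1)) has exact binomial coverage
    1 − 2·F(k−1; n, ½); k is the largest index whose coverage is still ≥
    *nominal*, i.e. the smallest achievable level at or above the nominal one.
    """
    if n < 1:
        raise BatteryError("need at least one pair")
    ks = np.arange(1, n // 2 + 2)
    levels = 1.0 - 2.0 * stats.binom.cdf(ks - 1, n, 0.5)
    ok = ks[levels >= nominal]
    if ok.size == 0:
        k = 1
    else:
        k = int(ok.max())
    return k, float(1.0 - 2.0 * stats.binom.cdf(k - 1, n, 0.5))


def paired_sign_test(female, male, nominal: float = 0.95) -> SignTestResult:
    """Exact two-sided paired sign test of female − male differences.

    Zero differences are dropped; p = 2·min(tail probabilities) of
    Binomial(n_nonzero, ½), capped at 1. The CI is the order-statistic
    interval for the median difference at the smallest exactly-achievable
    confidence level ≥ *nominal*.
    """
    female = np.asarray(female, dtype=float)
    male = np.asarray(male, dtype=float)
    if female.shape != male.shape:
        raise BatteryError("paired vectors must have equal length")
    d = female - male
    d = d[np.isfinite(d)]
    n_pairs = d.size
    nz = d[d != 0]
    n_nonzero = nz.size
    if n_nonzero == 0:
        raise BatteryError("all pairs tied")
    n_pos = int(np.sum(nz > 0))
    cdf = stats.binom.cdf
    sf = stats.binom.sf
    p = min(1.0, 2.0 * min(cdf(n_pos, n_nonzero, 0.5),
                           sf(n_pos - 1, n_nonzero, 0.5)))
    k, level = sign_test_ci_level(n_pairs, nominal)
    ds = np.sort(d)
    return SignTestResult(
        n_pairs=n_pairs, n_nonzero=n_nonzero, n_positive=n_pos,
        p_value=float(p), ci_level=level,
        ci_lower=float(ds[k - 1]), ci_upper=float(ds[n_pairs - k]),
    )


def _pgls_row(spec: AnalysisSpec, data: pd.DataFrame, vcv: PhyloCovariance,
              lambda_bounds) -> tuple[PGLSFit, int]:
    cols = ["species", spec.response, "weight", *spec.covariates]
    sub = data[cols].dropna()
    n = len(sub)
    if n < len(spec.covariates) + 3:
        raise BatteryError(
            f"{spec.model_id}: only {n} species with complete data")
    C = vcv.reorder(sub["species"].tolist())
    X = phylo.design_matrix(sub, list(spec.covariates))
    fit = phylo.ml_lambda(
        sub[spec.response].to_numpy(), X, C,
        weights=sub["weight"].to_numpy(), bounds=tuple(lambda_bounds),
        term_names=["intercept", *spec.covariates])
    return fit, n


def run_battery(
    prevalence: pd.DataFrame,
    covariates: pd.DataFrame,
    tree,
    specs: tuple[AnalysisSpec, ...] = DEFAULT_BATTERY,
    q: float = 0.05,
    sex_table: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    lambda_bounds: tuple[float, float] = (1e-6, 1.0),
) -> BatteryResult:
    """Fit every analysis in *specs* and apply BH-FDR over the primary p-values.

    *prevalence* is the per-species prevalence table (with weights),
    *covariates* the transformed-trait table (including dimorphism scores),
    *tree* a newick tree/path covering all species, *sex_table* the paired
    female/male prevalences for the sign tests, and *meta* supplies the
    ``domesticated`` flag for specs that exclude domesticated species.
    The FDR family is the primary-variable p-value of each row, in spec order.
    """
    specs = tuple(specs)
    if not specs:
        return BatteryResult([], np.zeros(0), np.zeros(0),
                             np.zeros(0, dtype=bool), q,
                             pd.DataFrame())
    known = set(covariates.columns) - {"species"}
    for s in specs:
        bad = [c for c in s.covariates if c not in known]
        if bad:
            raise BatteryError(f"{s.model_id}: unknown covariates {bad}")
        if s.exclude_domesticated and meta is None:
            raise BatteryError(f"{s.model_id}: needs meta for domesticated flag")
        if s.test == "sign_test" and sex_table is None:
            raise BatteryError(f"{s.model_id}: needs sex_table for sign test")

    data = prevalence.merge(covariates, on="species", how="left")
    needs_pgls = any(s.test == "pgls" for s in specs)
    vcv = phylo.vcv_from_tree(tree, tips=data["species"].tolist()) if needs_pgls else None

    rows, pvals, reported = [], [], []
    for spec in specs:
        if spec.test == "sign_test":
            res = paired_sign_test(sex_table[f"{spec.response}_f"],
                                   sex_table[f"{spec.response}_m"])
            rows.append((spec, res))
            pvals.append(res.p_value)
            reported.append({
                "model": spec.model_id, "response": spec.response,
                "n": res.n_pairs, "R2": np.nan, "F": np.nan,
                "df1": np.nan, "df2": np.nan, "lambda": np.nan,
                "sign": "+" if res.n_positive > res.n_nonzero / 2 else "-",
                "p_A": res.p_value, "p_B": np.nan,
                "ci": f"{res.ci_level:.1%} CI = {res.ci_lower:.4g} - {res.ci_upper:.4g}",
            })
        else:
            df = data
            if spec.exclude_domesticated:
                dom = meta.set_index("species")["domesticated"]
                df = data[~data["species"].map(dom).astype("boolean").fillna(False).astype(bool)]
            fit, n = _pgls_row(spec, df, vcv, lambda_bounds)
            rows.append((spec, fit))
            pvals.append(float(fit.p_values[1]))
            reported.append({
                "model": spec.model_id, "response": spec.response, "n": n,
                "R2": fit.r_squared, "F": fit.f_statistic,
                "df1": fit.df_num, "df2": fit.df_den,
                "lambda": fit.lambda_hat,
                "sign": fit.association_signs[0],
                "p_A": float(fit.p_values[1]),
                "p_B": float(fit.p_values[2]) if len(fit.p_values) > 2 else np.nan,
                "ci": "",
            })

    p = np.asarray(pvals)
    flags, p_adj = bh_fdr(p, q=q)
    report = pd.DataFrame(reported)
    report["p_adj"] = p_adj
    report["fdr_pass"] = flags
    return BatteryResult(rows=rows, p_values=p, p_adjusted=p_adj,
                         fdr_pass=flags, q=q, report=report)
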