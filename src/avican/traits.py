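"""Life-history trait transforms, dimorphism scores, and normality/outlier checks.

Regression covariates are power-transformed toward normality on the Tukey
ladder of powers: x^λ for λ>0, log(x) for λ=0, and −x^λ for λ<0 (the sign
flip keeps every rung monotone increasing). The fixed transforms used for the
avian life-history covariates are log10 body mass, log10(mass·lifespan),
lifespan^0.425 and −clutch^−0.125; :func:`tukey_select` recovers such
exponents from data by maximizing Shapiro–Wilk W over a grid of λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = [
    "species", "mass_g", "lifespan_months", "incubation_months", "clutch",
    "brightness_m", "brightness_f", "hue_m", "hue_f",
    "massdim_m", "massdim_f", "tail_m", "tail_f",
]

#: fixed ladder exponents for the standard covariates
LIFESPAN_EXPONENT = 0.425
CLUTCH_EXPONENT = -0.125


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class TransformSpec:
    """A rung of the Tukey ladder: the exponent and the functional form."""

    name: str
    lam: float
    form: str  # power | neg_power | log10 | natural_log

    def __post_init__(self):
        if self.form == "neg_power" and not self.lam < 0:
            raise TraitError("neg_power requires lam < 0")
        if self.form in ("log10", "natural_log") and self.lam != 0:
            raise TraitError("log forms require lam == 0")
        if self.form == "power" and not self.lam > 0:
            raise TraitError("power requires lam > 0")

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x[np.isfinite(x)] <= 0):
            raise TraitError("ladder transforms require strictly positive values")
        if self.form == "power":
            return x ** self.lam
        if self.form == "neg_power":
            return -(x ** self.lam)
        if self.form == "log10":
            return np.log10(x)
        return np.log(x)


def ladder_spec(name: str, lam: float, log_base: str = "natural_log") -> TransformSpec:
    """Build the TransformSpec for a ladder exponent λ."""
    if lam > 0:
        return TransformSpec(name, lam, "power")
    if lam < 0:
        return TransformSpec(name, lam, "neg_power")
    return TransformSpec(name, 0.0, log_base)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitError(f"trait table missing columns: {missing}")
    for col in TRAIT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if (df[col].dropna() <= 0).any():
            raise TraitError(f"{col} must be positive where present")
    return df


def _safe(values: pd.Series, fn) -> pd.Series:
    """Apply fn where values are positive; nonpositive/missing become NaN."""
    x = pd.to_numeric(values, errors="coerce")
    ok = x > 0
    out = pd.Series(np.nan, index=values.index, dtype=float)
    out[ok] = fn(x[ok].to_numpy(dtype=float))
    return out


def fixed_transforms(table: pd.DataFrame) -> pd.DataFrame:
    """Transformed covariates for the regression battery.

    Emits ``log10_mass``, ``log10_mass_lifespan``, ``lifespan_pow`` (^0.425),
    and ``clutch_tukey`` (−clutch^−0.125), plus untouched ``incubation_months``.
    Missing inputs propagate as NaN.
    """
    out = pd.DataFrame({"species": table["species"]})
    out["log10_mass"] = _safe(table["mass_g"], np.log10)
    out["log10_mass_lifespan"] = _safe(
        table["mass_g"] * table["lifespan_months"], np.log10)
    out["lifespan_pow"] = _safe(table["lifespan_months"],
                                lambda v: v ** LIFESPAN_EXPONENT)
    out["clutch_tukey"] = _safe(table["clutch"],
                                lambda v: -(v ** CLUTCH_EXPONENT))
    out["incubation_months"] = pd.to_numeric(table["incubation_months"],
                                             errors="coerce")
    return out


DEFAULT_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.025), 3)


def tukey_select(x, grid=DEFAULT_GRID, name: str = "tukey") -> TransformSpec:
    """Pick the ladder exponent that makes *x* most normal.

    Scans *grid* and returns the λ whose transformed sample maximizes
    Shapiro–Wilk W; ties break toward the λ closest to 1 (no transform).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise TraitError("need at least 4 observations for Shapiro-Wilk W")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise TraitError("tukey_select requires finite positive values")
    best_lam, best_w = None, -np.inf
    for lam in grid:
        w = stats.shapiro(ladder_spec("t", float(lam)).apply(x)).statistic
        # strict improvement, or tie resolved toward lam nearest 1
        if w > best_w + 1e-12 or (
            abs(w - best_w) <= 1e-12 and abs(lam - 1) < abs(best_lam - 1)
        ):
            best_lam, best_w = float(lam), w
    return ladder_spec(name, best_lam)


def dimorphism_score(male, female):
    """Sexual dimorphism as ln(male)/ln(female).

    Scores above 1 indicate the trait is relatively larger in males. Undefined
    when female = 1 (ln = 0); inputs must be positive.
    """
    male = np.asarray(male, dtype=float)
    female = np.asarray(female, dtype=float)
    valid = np.isfinite(male) & np.isfinite(female)
    if np.any((male[valid] <= 0) | (female[valid] <= 0)):
        raise TraitError("dimorphism_score requires positive inputs")
    if np.any(female[valid] == 1):
        raise TraitError("female trait value of 1 makes ln(female)=0; score undefined")
    with np.errstate(invalid="ignore"):
        out = np.log(male) / np.log(female)
    return out if out.ndim else float(out)


def dimorphism_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-species dimorphism scores for brightness, hue, mass and tail size.

    Pairs with a missing sex, a nonpositive value, or a female value of 1
    yield NaN (that species drops from the corresponding analysis).
    """
    out = pd.DataFrame({"species": traits["species"]})
    for trait, (m_col, f_col) in {
        "dim_brightness": ("brightness_m", "brightness_f"),
        "dim_hue": ("hue_m", "hue_f"),
        "dim_mass": ("massdim_m", "massdim_f"),
        "dim_tail": ("tail_m", "tail_f"),
    }.items():
        m = pd.to_numeric(traits[m_col], errors="coerce").to_numpy(dtype=float)
        f = pd.to_numeric(traits[f_col], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(m) & np.isfinite(f) & (m > 0) & (f > 0) & (f != 1)
        score = np.full(len(traits), np.nan)
        score[ok] = np.log(m[ok]) / np.log(f[ok])
        out[trait] = score
    return out


def grubbs_test(x, alpha: float = 0.05) -> dict:
    """Two-sided Grubbs test for a single outlier.

    G = max|x − x̄| / s against the t-based critical value
    ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) quantile on n−2 df.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise TraitError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise TraitError("zero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / s
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    return {"statistic": float(g), "critical": float(crit),
            "outlier_index": idx if g > crit else None,
            "significant": bool(g > crit)}


def rosner_test(x, k: int = 3, alpha: float = 0.05) -> dict:
    """Rosner's generalized extreme studentized deviate test for up to *k* outliers.

    At step i the most deviant remaining point is removed and
    R_i = max|x − x̄|/s compared with λ_i; the declared outliers are those up
    to the largest i with R_i > λ_i.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < k + 3:
        raise TraitError(f"Rosner test with k={k} needs n >= {k + 3}")
    if x.std(ddof=1) == 0:
        raise TraitError("zero variance")
    work = x.copy()
    live = np.arange(n)
    steps = []
    for i in range(1, k + 1):
        s = work.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(work - work.mean())
        j = int(np.argmax(dev))
        r = dev[j] / s
        m = work.size
        p = 1 - alpha / (2 * m)
        t = stats.t.ppf(p, m - 2)
        lam = (m - 1) * t / np.sqrt((m - 2 + t**2) * m)
        steps.append({"i": i, "index": int(live[j]), "value": float(work[j]),
                      "R": float(r), "critical": float(lam),
                      "significant": bool(r > lam)})
        work = np.delete(work, j)
        live = np.delete(live, j)
    n_out = max((s["i"] for s in steps if s["significant"]), default=0)
    outliers = [s["index"] for s in steps[:n_out]]
    return {"steps": steps, "n_outliers": n_out, "outlier_indices": outliers}


def normality_and_outliers(x, alpha: float = 0.05, max_outliers: int = 3) -> dict:
    """Shapiro–Wilk normality check plus Grubbs and Rosner outlier screens.

    Returns the test reports and the input with Rosner-significant outliers
    removed (at most *max_outliers*; non-flagged values untouched).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise TraitError("need at least 4 observations")
    if x.std(ddof=1) == 0:
        raise TraitError("zero variance")
    sw = stats.shapiro(x)
    grubbs = grubbs_test(x, alpha=alpha)
    rosner = rosner_test(x, k=max_outliers, alpha=alpha)
    keep = np.ones(x.size, dtype=bool)
    keep[rosner["outlier_indices"]] = False
    return {
        "shapiro_w": float(sw.statistic),
        "shapiro_p": float(sw.pvalue),
        "grubbs": grubbs,
        "rosner": rosner,
        "cleaned": x[keep],
        "removed_indices": rosner["outlier_indices"],
    }
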