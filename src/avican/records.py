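"""Necropsy-record handling: parsing, exclusion filters, and prevalence estimation.

The unit of observation is a single necropsy (animal postmortem). Species-level
neoplasia and malignancy prevalence are the fraction of a species' necropsies
reporting any tumor, respectively a malignant tumor. Records from infants, from
wild-origin birds, and (optionally) from domesticated species are excluded
before prevalence is computed, and only species with a minimum number of
necropsies enter downstream regressions.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Free-text markers of pre-adult age used when a numeric age at death is missing.
INFANT_KEYWORDS = (
    "infant",
    "juvenile",
    "immature",
    "adolescent",
    "hatchling",
    "subadult",
    "neonate",
    "newborn",
    "offspring",
    "fledgling",
)

# whole-word, case-insensitive; tolerate hyphenated compounds ("sub-adult", "new-born")
_KEYWORD_RE = re.compile(
    r"\b(?:" + "|".join(k[:3] + "-?" + k[3:] if k in ("subadult", "newborn") else k
                        for k in INFANT_KEYWORDS) + r")\b",
    re.IGNORECASE,
)

RECORD_COLUMNS = [
    "species", "common_name", "sex", "age_months", "age_text",
    "neoplasia", "malignancy", "reproductive", "origin", "institution",
]

META_COLUMNS = [
    "species", "order", "female_maturity_months", "male_maturity_months",
    "lifespan_months", "domesticated",
]


class RecordValidationError(ValueError):
    """Raised when a necropsy or species-meta table violates its invariants."""


def _as_bool(series: pd.Series, name: str) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    if not vals.isin([0, 1]).all():
        bad = series[~vals.isin([0, 1])].index.tolist()[:5]
        raise RecordValidationError(f"column {name!r} must be 0/1; bad rows {bad}")
    return vals.astype(bool)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw necropsy table and coerce dtypes.

    Enforces: malignancy ⇒ neoplasia, reproductive tumor ⇒ neoplasia,
    nonnegative ages, sex in {female, male, unknown}, origin in {managed, wild}.
    Returns a typed copy; raises :class:`RecordValidationError` on violation.
    """
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"records table missing columns: {missing}")
    out = df.copy()
    out["species"] = out["species"].astype(str).str.strip()
    for col in ("neoplasia", "malignancy", "reproductive"):
        out[col] = _as_bool(out[col], col)
    out["age_months"] = pd.to_numeric(out["age_months"], errors="coerce")
    if (out["age_months"].dropna() < 0).any():
        raise RecordValidationError("age_months must be nonnegative")
    sex = out["sex"].fillna("unknown").astype(str).str.lower()
    if not sex.isin(["female", "male", "unknown"]).all():
        raise RecordValidationError("sex must be female/male/unknown")
    out["sex"] = sex
    origin = out["origin"].astype(str).str.lower()
    if not origin.isin(["managed", "wild"]).all():
        raise RecordValidationError("origin must be managed/wild")
    out["origin"] = origin
    if (out["malignancy"] & ~out["neoplasia"]).any():
        raise RecordValidationError("malignancy=1 with neoplasia=0 is inconsistent")
    if (out["reproductive"] & ~out["neoplasia"]).any():
        raise RecordValidationError("reproductive=1 with neoplasia=0 is inconsistent")
    return out


def validate_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a species life-history/taxonomy metadata table."""
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"meta table missing columns: {missing}")
    out = df.copy()
    out["species"] = out["species"].astype(str).str.strip()
    if out["species"].duplicated().any():
        raise RecordValidationError("duplicate species in meta table")
    for col in ("female_maturity_months", "male_maturity_months", "lifespan_months"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
        if (out[col].dropna() <= 0).any():
            raise RecordValidationError(f"{col} must be positive where present")
    out["domesticated"] = _as_bool(out["domesticated"], "domesticated")
    return out


def read_records(path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path))


def read_meta(path) -> pd.DataFrame:
    return validate_meta(pd.read_csv(path))


def _infancy_age(meta: pd.DataFrame) -> pd.Series:
    """Per-species infancy cutoff: mean of male and female maturity (months)."""
    fem = meta["female_maturity_months"]
    mal = meta["male_maturity_months"]
    return pd.concat([fem, mal], axis=1).mean(axis=1, skipna=True)


def filter_infants(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Drop necropsies of pre-adult individuals.

    A record is infant if its age at death is ≤ the species' infancy age
    (the mean of male and female maturity); when no numeric age is recorded,
    a whole-word keyword match on the free-text age description
    (:data:`INFANT_KEYWORDS`) is used instead. Records of species absent from
    *meta* are retained with a warning. Input row order is preserved.
    """
    meta = meta.set_index("species") if "species" in meta.columns else meta
    cutoff = _infancy_age(meta)

    unknown = set(records["species"]) - set(meta.index)
    if unknown:
        logger.warning("species missing from meta, retained unfiltered: %s",
                       sorted(unknown))

    cut = records["species"].map(cutoff)  # NaN for unknown species / no maturity data
    age = records["age_months"]
    by_age = age.notna() & cut.notna() & (age <= cut)
    text = records["age_text"].fillna("").astype(str)
    by_keyword = age.isna() & text.str.contains(_KEYWORD_RE)
    return records.loc[~(by_age | by_keyword)].copy()


def apply_exclusions(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    exclude_domesticated: bool = False,
    exclude_species: tuple[str, ...] = ("Gallus gallus",),
) -> pd.DataFrame:
    """Drop wild-origin necropsies, named excluded species, and optionally
    all domesticated species."""
    keep = records["origin"] != "wild"
    if exclude_species:
        keep &= ~records["species"].isin(set(exclude_species))
    if exclude_domesticated:
        dom = meta.set_index("species")["domesticated"]
        keep &= ~records["species"].map(dom).astype("boolean").fillna(False).astype(bool)
    return records.loc[keep].copy()


def compute_prevalence(records: pd.DataFrame, min_n: int = 20) -> pd.DataFrame:
    """Species-level prevalence estimates with regression weights.

    One row per species with at least *min_n* necropsies, sorted by species.
    The weight column is n^(-1/2), the residual-SD scale of a prevalence
    estimated from n binomial trials.
    """
    if records.empty:
        return pd.DataFrame(columns=["species", "n", "n_neoplasia", "n_malignant",
                                     "neoplasia_prev", "malignancy_prev", "weight"])
    grp = records.groupby("species", sort=True)
    out = pd.DataFrame({
        "n": grp.size(),
        "n_neoplasia": grp["neoplasia"].sum(),
        "n_malignant": grp["malignancy"].sum(),
    })
    out = out[out["n"] >= min_n]
    out["neoplasia_prev"] = out["n_neoplasia"] / out["n"]
    out["malignancy_prev"] = out["n_malignant"] / out["n"]
    out["weight"] = out["n"] ** -0.5
    return out.reset_index().rename(columns={"index": "species"})


def sex_prevalence(
    records: pd.DataFrame,
    min_n_per_sex: int = 10,
    drop_reproductive: bool = True,
) -> pd.DataFrame:
    """Paired female/male prevalence per species.

    Only species with at least *min_n_per_sex* necropsies of each sex are
    retained; unknown-sex records are ignored. With *drop_reproductive*,
    reproductive-tract tumors are treated as tumor-negative (the record stays
    in the denominator), so denominators remain the total necropsied females
    and males.
    """
    sexed = records[records["sex"].isin(["female", "male"])].copy()
    if drop_reproductive:
        repro = sexed["reproductive"]
        sexed.loc[repro, "neoplasia"] = False
        sexed.loc[repro, "malignancy"] = False

    rows = []
    for sp, sub in sexed.groupby("species", sort=True):
        f = sub[sub["sex"] == "female"]
        m = sub[sub["sex"] == "male"]
        if len(f) < min_n_per_sex or len(m) < min_n_per_sex:
            continue
        rows.append({
            "species": sp,
            "n_female": len(f), "n_male": len(m),
            "neoplasia_prev_f": f["neoplasia"].mean(),
            "neoplasia_prev_m": m["neoplasia"].mean(),
            "malignancy_prev_f": f["malignancy"].mean(),
            "malignancy_prev_m": m["malignancy"].mean(),
        })
    cols = ["species", "n_female", "n_male", "neoplasia_prev_f", "neoplasia_prev_m",
            "malignancy_prev_f", "malignancy_prev_m"]
    return pd.DataFrame(rows, columns=cols)


def age_death_fractions(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    bins: int = 10,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-record age at death as a fraction of species lifespan.

    Returns the per-record fractions (index aligned to *records*) and a
    normalized frequency table over *bins* equal-width bins on [0, max].
    Fractions may exceed 1 because reported maximum lifespan is a point
    estimate. Records lacking an age or a species lifespan are skipped.
    """
    lifespan = meta.set_index("species")["lifespan_months"]
    ls = records["species"].map(lifespan)
    ok = records["age_months"].notna() & ls.notna()
    n_missing = int((records["age_months"].notna() & ls.isna()).sum())
    if n_missing:
        logger.warning("%d aged records skipped: species lifespan unknown", n_missing)
    frac = (records.loc[ok, "age_months"] / ls[ok]).rename("lifespan_fraction")
    if frac.empty:
        return frac, pd.DataFrame(columns=["bin_left", "bin_right", "frequency"])
    edges = np.linspace(0.0, float(frac.max()), bins + 1)
    counts, _ = np.histogram(frac, bins=edges)
    table = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "frequency": counts / counts.sum(),
    })
    return frac, table


def per_order_summary(
    prevalence: pd.DataFrame,
    meta: pd.DataFrame,
    min_species: int = 10,
) -> pd.DataFrame:
    """Mean ± SD of prevalence by taxonomic order, for orders with at least
    *min_species* species in the prevalence table."""
    order = meta.set_index("species")["order"]
    df = prevalence.assign(order=prevalence["species"].map(order))
    grp = df.dropna(subset=["order"]).groupby("order")
    out = grp.agg(
        n_species=("species", "size"),
        neoplasia_mean=("neoplasia_prev", "mean"),
        neoplasia_sd=("neoplasia_prev", "std"),
        malignancy_mean=("malignancy_prev", "mean"),
        malignancy_sd=("malignancy_prev", "std"),
    )
    return out[out["n_species"] >= min_species].reset_index()


def dataset_summary(prevalence: pd.DataFrame) -> dict:
    """Dataset-wide descriptives: species count and mean/max prevalences."""
    return {
        "n_species": int(len(prevalence)),
        "n_necropsies": int(prevalence["n"].sum()),
        "mean_neoplasia_prev": float(prevalence["neoplasia_prev"].mean()),
        "mean_malignancy_prev": float(prevalence["malignancy_prev"].mean()),
        "max_neoplasia_prev": float(prevalence["neoplasia_prev"].max()),
        "max_malignancy_prev": float(prevalence["malignancy_prev"].max()),
    }
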