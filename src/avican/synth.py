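"""Synthetic study generator with known ground truth.

Emulates the structure of a managed-population comparative-oncology study:
a Yule (pure-birth) species tree, life-history traits evolving with tunable
phylogenetic signal, a latent per-species tumor prevalence linked to a focal
trait, and individual necropsy records — including infant records carrying
age keywords, sexes, and reproductive-tumor labels — with exact bookkeeping
of every generated count so each pipeline stage can be tested against truth.

Two prevalence links are provided. The default ``logit`` link draws latent
prevalence as inverse-logit(a + Σ b·trait + phylogenetic deviation) and then
samples binomial tumor flags, which deliberately differs from the linear
Gaussian model the regression assumes (realistic misspecification). The
``linear`` mode returns a Gaussian response y = Xb + MVN(0, σ²·C_λ) directly
and is meant for exact parameter-recovery checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .phylo import PhyloCovariance, lambda_scale, vcv_from_tree
from .records import INFANT_KEYWORDS

#: logit-scale intercept matching a 4.4% baseline neoplasia prevalence
DEFAULT_INTERCEPT = float(np.log(0.044 / (1 - 0.044)))


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults reflect a mid-sized managed-bird study: ~100 species, 20–500
    necropsies each, mean neoplasia prevalence near 4.4% with malignant
    tumors about half of all tumors, moderate phylogenetic signal, and a
    modest fraction of infant and reproductive-tumor records.
    """

    n_species: int = 100
    birth_rate: float = 1.0
    lambda_true: float = 0.5
    sigma2: float = 1.0
    intercept: float = DEFAULT_INTERCEPT
    slopes: dict = field(default_factory=lambda: {"clutch_trait": 0.8})
    logit_sigma: float = 0.3  # SD scale of the phylogenetic deviation (logit units)
    necropsy_range: tuple[int, int] = (20, 500)
    necropsy_distribution: str = "uniform"  # uniform | log_uniform
    infant_fraction: float = 0.15
    reproductive_fraction: float = 0.10
    sex_ratio: float = 0.5
    malignant_given_neoplasia: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.necropsy_range[0] < 1 or self.necropsy_range[0] > self.necropsy_range[1]:
            raise ValueError("invalid necropsy_range")
        for name, val, lo, hi in [
            ("lambda_true", self.lambda_true, 0, 1),
            ("infant_fraction", self.infant_fraction, 0, 1),
            ("reproductive_fraction", self.reproductive_fraction, 0, 1),
            ("sex_ratio", self.sex_ratio, 0, 1),
            ("malignant_given_neoplasia", self.malignant_given_neoplasia, 0, 1),
        ]:
            if not lo <= val <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}]")
        if self.birth_rate <= 0 or self.sigma2 < 0:
            raise ValueError("birth_rate must be > 0 and sigma2 >= 0")


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> str:
    """Ultrametric Yule tree with tips S0001…, scaled to unit depth.

    Returns a rooted newick string (deterministic for a given seed).
    """
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=rng)
    # drop the stem edge (no covariance is shared above the root) and run the
    # process past the n-th speciation so no tip edge has zero length
    tree.seed_node.edge.length = None
    extra = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:04d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_traits(
    tree,
    lambda_true: float = 1.0,
    sigma2: float = 1.0,
    seed: int = 0,
    n_traits: int = 1,
    trait_names: list[str] | None = None,
) -> pd.DataFrame:
    """Traits from a multivariate normal with covariance σ²·C_λ on the tree.

    One independent draw per trait; species order follows the tree's tips.
    """
    vcv = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    C = lambda_scale(vcv, lambda_true).matrix * sigma2
    rng = np.random.default_rng(seed)
    n = len(vcv.species)
    if sigma2 == 0:
        draws = np.zeros((n, n_traits))
    else:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
        draws = L @ rng.standard_normal((n, n_traits))
    names = trait_names or [f"trait_{j}" for j in range(n_traits)]
    out = pd.DataFrame(draws, columns=names)
    out.insert(0, "species", vcv.species)
    return out


def simulate_linear_gaussian(
    tree, beta, lambda_true: float = 0.5, sigma2: float = 1.0, seed: int = 0,
    x: np.ndarray | None = None,
) -> dict:
    """Gaussian response y = β0 + β1·x + MVN(0, σ²·C_λ) for recovery tests.

    When *x* is omitted a Brownian (λ=1) covariate is simulated on the tree.
    Returns species order, x, y and the truth used.
    """
    vcv = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    n = len(vcv.species)
    rng = np.random.default_rng(seed)
    if x is None:
        Lx = np.linalg.cholesky(vcv.matrix + 1e-12 * np.eye(n))
        x = Lx @ rng.standard_normal(n)
    beta = np.asarray(beta, dtype=float)
    C = lambda_scale(vcv, lambda_true).matrix * sigma2
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    y = beta[0] + beta[1] * x + L @ rng.standard_normal(n)
    return {"species": list(vcv.species), "x": np.asarray(x, float), "y": y,
            "beta": beta, "lambda_true": lambda_true, "sigma2": sigma2}


def _latent_prevalence(vcv: PhyloCovariance, traits: pd.DataFrame,
                       cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    eta = np.full(len(vcv.species), cfg.intercept)
    for trait, slope in cfg.slopes.items():
        eta = eta + slope * traits[trait].to_numpy()
    if cfg.logit_sigma > 0:
        C = lambda_scale(vcv, cfg.lambda_true).matrix * cfg.logit_sigma**2
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(eta)))
        eta = eta + L @ rng.standard_normal(len(eta))
    return expit(eta)


def simulate_records(truth: dict, cfg: SynthConfig) -> dict:
    """Individual necropsy records from per-species latent prevalences.

    Adults carry tumor flags drawn at the species' true prevalence; infant
    records (a configurable fraction) get ages at or below maturity or an
    age keyword and are always tumor-free; reproductive-tumor labels are
    assigned among tumor-positive records. Returns records, species meta,
    and a bookkeeping table with every true adult count.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    species = truth["species"]
    prev = np.asarray(truth["true_prevalence"], dtype=float)

    lo, hi = cfg.necropsy_range
    if cfg.necropsy_distribution == "log_uniform":
        n_total = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), len(species)))
        n_total = np.clip(n_total.astype(int), lo, hi)
    else:
        n_total = rng.integers(lo, hi + 1, len(species))

    maturity = 12.0  # months; shared infancy cutoff for the synthetic clade
    lifespan = 240.0
    chunks, book_rows, meta_rows = [], [], []
    for i, sp in enumerate(species):
        n_inf = int(round(cfg.infant_fraction * n_total[i]))
        na = int(n_total[i]) - n_inf
        neo = rng.random(na) < prev[i]
        mal = neo & (rng.random(na) < cfg.malignant_given_neoplasia)
        repro = neo & (rng.random(na) < cfg.reproductive_fraction)
        sex_adult = np.where(rng.random(na) < cfg.sex_ratio, "female", "male")
        ages = np.round(rng.uniform(maturity + 1, lifespan, na), 1)

        inf_by_age = rng.random(n_inf) < 0.5
        inf_ages = np.where(inf_by_age, np.round(rng.uniform(0, maturity, n_inf), 1),
                            np.nan)
        inf_text = np.where(inf_by_age, "",
                            rng.choice(INFANT_KEYWORDS, size=n_inf))
        inf_sex = np.where(rng.random(n_inf) < cfg.sex_ratio, "female", "male")

        chunks.append(pd.DataFrame({
            "species": sp, "common_name": sp,
            "sex": np.concatenate([sex_adult, inf_sex]),
            "age_months": np.concatenate([ages, inf_ages]),
            "age_text": np.concatenate([np.full(na, ""), inf_text]),
            "neoplasia": np.concatenate([neo.astype(int), np.zeros(n_inf, int)]),
            "malignancy": np.concatenate([mal.astype(int), np.zeros(n_inf, int)]),
            "reproductive": np.concatenate([repro.astype(int), np.zeros(n_inf, int)]),
            "origin": "managed", "institution": "synthetic_zoo",
        }))
        f_mask = sex_adult == "female"
        book_rows.append({
            "species": sp, "n_adult": na, "n_infant": n_inf,
            "n_neoplasia": int(neo.sum()), "n_malignant": int(mal.sum()),
            "n_reproductive": int(repro.sum()),
            "true_prevalence": float(prev[i]),
            "n_female": int(f_mask.sum()), "n_male": int((~f_mask).sum()),
            "n_neoplasia_f": int(neo[f_mask].sum()),
            "n_neoplasia_m": int(neo[~f_mask].sum()),
            "n_malignant_f": int(mal[f_mask].sum()),
            "n_malignant_m": int(mal[~f_mask].sum()),
        })
        meta_rows.append({
            "species": sp, "order": f"Order{(i % 4) + 1}",
            "female_maturity_months": maturity, "male_maturity_months": maturity,
            "lifespan_months": lifespan, "domesticated": int(i % 10 == 0),
        })

    records = pd.concat(chunks, ignore_index=True)
    return {
        "records": records,
        "meta": pd.DataFrame(meta_rows),
        "bookkeeping": pd.DataFrame(book_rows),
    }


def generate_study(cfg: SynthConfig) -> dict:
    """Full synthetic study: tree, traits, latent prevalences, records, truth."""
    newick = simulate_tree(cfg.n_species, cfg.birth_rate, cfg.seed)
    vcv = vcv_from_tree(newick)
    trait_names = list(cfg.slopes) or ["clutch_trait"]
    traits = simulate_traits(vcv, cfg.lambda_true, cfg.sigma2,
                             seed=cfg.seed + 2, n_traits=len(trait_names),
                             trait_names=trait_names)
    rng = np.random.default_rng(cfg.seed + 3)
    prev = _latent_prevalence(vcv, traits, cfg, rng)
    truth = {"species": list(vcv.species), "true_prevalence": prev.tolist(),
             "config": asdict(cfg)}
    bundle = simulate_records({"species": vcv.species, "true_prevalence": prev}, cfg)
    bundle.update(tree=newick, traits=traits, truth=truth)
    return bundle


def write_study(bundle: dict, out_dir) -> dict:
    """Write a generated study to CSV/newick/JSON files; returns the paths."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "meta": out / "meta.csv",
        "traits": out / "traits.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
        "bookkeeping": out / "bookkeeping.csv",
    }
    bundle["records"].to_csv(paths["records"], index=False)
    bundle["meta"].to_csv(paths["meta"], index=False)
    bundle["traits"].to_csv(paths["traits"], index=False)
    paths["tree"].write_text(bundle["tree"] + "\n")
    paths["truth"].write_text(json.dumps(bundle["truth"], indent=2))
    bundle["bookkeeping"].to_csv(paths["bookkeeping"], index=False)
    return {k: str(v) for k, v in paths.items()}
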