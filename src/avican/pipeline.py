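"""End-to-end pipeline: filters → prevalence → transforms → battery → reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, battery, records, traits

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    records_path: str
    meta_path: str
    traits_path: str
    tree_path: str
    out_dir: str = "avican_out"
    min_n: int = 20
    min_n_per_sex: int = 10
    exclude_species: tuple[str, ...] = ("Gallus gallus",)
    exclude_domesticated: bool = False
    drop_reproductive_for_sex: bool = True
    fdr_q: float = 0.05
    lambda_bounds: tuple[float, float] = (1e-6, 1.0)
    min_species_per_order: int = 10
    age_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.min_n <= 0 or self.min_n_per_sex <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "exclude_species" in raw:
            raw["exclude_species"] = tuple(raw["exclude_species"])
        if "lambda_bounds" in raw:
            raw["lambda_bounds"] = tuple(raw["lambda_bounds"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Outputs in ``config.out_dir``: ``prevalence.tsv``, ``battery_report.tsv``,
    ``order_summary.tsv``, ``sex_comparison.tsv``, ``age_fractions.tsv``, and
    ``manifest.json``. Returns the in-memory results keyed the same way.
    Any stage failure aborts with a stage-named error and removes partial
    outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        recs = _stage("read_records")(records.read_records)(config.records_path)
        meta = _stage("read_meta")(records.read_meta)(config.meta_path)
        trait_tab = _stage("read_traits")(traits.read_traits)(config.traits_path)

        adults = _stage("filter_infants")(records.filter_infants)(recs, meta)
        kept = _stage("apply_exclusions")(records.apply_exclusions)(
            adults, meta, exclude_domesticated=config.exclude_domesticated,
            exclude_species=config.exclude_species)
        logger.info("records: %d read, %d after infant filter, %d after exclusions",
                    len(recs), len(adults), len(kept))

        prevalence = _stage("compute_prevalence")(records.compute_prevalence)(
            kept, min_n=config.min_n)
        if prevalence.empty:
            raise PipelineError("stage 'compute_prevalence' failed: "
                                "no species passed filters")
        sex_tab = _stage("sex_prevalence")(records.sex_prevalence)(
            kept, min_n_per_sex=config.min_n_per_sex,
            drop_reproductive=config.drop_reproductive_for_sex)

        cov = _stage("fixed_transforms")(traits.fixed_transforms)(trait_tab)
        dim = _stage("dimorphism")(traits.dimorphism_table)(trait_tab)
        covariates = cov.merge(dim, on="species", how="outer")

        result = _stage("battery")(battery.run_battery)(
            prevalence, covariates, config.tree_path,
            q=config.fdr_q, sex_table=sex_tab if not sex_tab.empty else None,
            meta=meta, lambda_bounds=config.lambda_bounds)

        order_summary = _stage("order_summary")(records.per_order_summary)(
            prevalence, meta, min_species=config.min_species_per_order)
        _, age_table = _stage("age_fractions")(records.age_death_fractions)(
            kept, meta, bins=config.age_bins)

        def _write(name, df):
            path = out / name
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)

        _write("prevalence.tsv", prevalence)
        _write("battery_report.tsv", result.report)
        _write("order_summary.tsv", order_summary)
        _write("sex_comparison.tsv", sex_tab)
        _write("age_fractions.tsv", age_table)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.digest(),
            "n_records_in": int(len(recs)),
            "n_records_analyzed": int(len(kept)),
            "n_species": int(len(prevalence)),
            "summary": records.dataset_summary(prevalence),
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(mpath)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {
        "prevalence": prevalence,
        "battery": result,
        "order_summary": order_summary,
        "sex_comparison": sex_tab,
        "age_fractions": age_table,
        "manifest": manifest,
        "out_dir": str(out),
    }
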