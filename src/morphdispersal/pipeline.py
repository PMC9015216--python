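"""End-to-end orchestration: ingest -> covariates -> models -> randomization -> report.

The pipeline reads the four input tables (nest-box registry, recruit table,
climate series, prey trapping record), validates and cross-references them,
derives covariates and dispersal distances, and runs the three analyses:

* descriptive statistics of dispersal (overall, by sex, by morph, by age);
* the binomial GLM of yearly brown proportion on winter anomaly;
* the dispersal mixed model for each configured analysis set;
* the randomization test overall and per morph.

Filter bookkeeping is part of the result: the report records how many
recruits were ingested, how many had complete model information, and how
many entered each analysis set, and these counts are checked to reconcile.
Every report embeds the config hash and input-file checksums so any number
in it is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .covariates import ClimateSeries
from .geometry import BoxRegistry, ValidationError, natal_dispersal_distance
from .models import GlmFit, LmmFit, fit_brown_proportion_glm, fit_dispersal_lmm
from .randomization import (
    RandomizationResult,
    candidate_distances,
    morph_stratified_test,
    randomization_test,
)

__all__ = [
    "PipelineConfig",
    "DataBundle",
    "ReportBundle",
    "PipelineError",
    "ingest",
    "descriptives",
    "run_pipeline",
]

log = logging.getLogger("morphdispersal")

_MODEL_VARS = [
    "dispersal_km", "morph", "sex", "body_mass_g", "age_at_recruitment",
    "hatch_year", "brood_id", "natal_box_id", "anomaly_c", "prey_index",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, analysis settings and the mandatory seed for one pipeline run."""

    registry_csv: str
    recruits_csv: str
    climate_csv: str
    prey_csv: str
    seed: int  # mandatory: no silent clock seeding
    out_dir: str = "pipeline_out"
    era_cutoff_year: int = 1987
    baseline_start: int = 1981
    baseline_end: int = 2010
    reps: int = 999
    tail: str = "lower"
    analysis_sets: tuple = ("all-ages", "one-year-olds")
    include_self_distance: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "analysis_sets" in data:
            data["analysis_sets"] = tuple(data["analysis_sets"])
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DataBundle:
    """Validated, cross-referenced inputs with derived columns attached."""

    registry: BoxRegistry
    recruits: pd.DataFrame  # with dispersal_km, anomaly_c, prey_index, complete flag
    climate: ClimateSeries
    prey: pd.DataFrame
    covariates: pd.DataFrame  # winter_year, mean_temp_c, anomaly_c, prey_index
    n_ingested: int
    n_complete: int


@dataclass
class ReportBundle:
    """All pipeline results, JSON-serializable via :meth:`to_dict`."""

    descriptives: dict
    glm: GlmFit | None
    lmm: dict  # analysis set -> LmmFit
    randomization: dict  # stratum -> RandomizationResult
    config_hash: str
    input_checksums: dict
    n_ingested: int
    n_complete: int
    seed: int

    def to_dict(self) -> dict:
        out = {
            "config_hash": self.config_hash,
            "input_checksums": self.input_checksums,
            "seed": self.seed,
            "n_ingested": self.n_ingested,
            "n_complete": self.n_complete,
            "descriptives": self.descriptives,
            "randomization": {
                k: r.summary_row() for k, r in self.randomization.items()
            },
        }
        if self.glm is not None:
            out["brown_proportion_glm"] = {
                "slope_estimate": self.glm.slope_estimate,
                "slope_se": self.glm.slope_se,
                "z_value": self.glm.z_value,
                "p": self.glm.p,
                "n_years": self.glm.n_years,
            }
        out["lmm"] = {
            name: {
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "fixed_effects": fit.fixed_table().to_dict(orient="records"),
                "variance_components": fit.varcomp_table().to_dict(orient="records"),
                "reml_loglik": fit.loglik,
            }
            for name, fit in self.lmm.items()
        }
        return out


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def ingest(config: PipelineConfig) -> DataBundle:
    """Read, validate and cross-reference the four input tables."""
    registry = BoxRegistry.from_csv(
        config.registry_csv, era_cutoff_year=config.era_cutoff_year
    )
    recruits = pd.read_csv(config.recruits_csv, dtype={"recruit_id": str})
    if recruits.empty:
        raise ValidationError("recruit table is empty")
    problems: list[str] = []
    dupes = recruits["recruit_id"][recruits["recruit_id"].duplicated()]
    for rid in dupes:
        problems.append(f"duplicate recruit id {rid!r}")
    for col in ("natal_box_id", "breeding_box_id"):
        for rid, box in zip(recruits["recruit_id"], recruits[col]):
            if pd.notna(box) and str(box) not in registry:
                problems.append(f"recruit {rid!r}: unknown {col} {box!r}")
    for col, levels in (("morph", {"gray", "brown"}), ("sex", {"female", "male"})):
        vals = recruits[col].dropna().astype(str)
        for rid, v in zip(recruits.loc[vals.index, "recruit_id"], vals):
            if v not in levels:
                problems.append(f"recruit {rid!r}: unparseable {col} {v!r}")
    if problems:
        raise ValidationError(
            "input validation failed:\n  " + "\n  ".join(problems)
        )
    recruits = recruits.copy()
    recruits["natal_box_id"] = recruits["natal_box_id"].astype(str)
    recruits["breeding_box_id"] = recruits["breeding_box_id"].astype(str)
    recruits["dispersal_km"] = [
        natal_dispersal_distance(registry[a], registry[b])
        for a, b in zip(recruits["natal_box_id"], recruits["breeding_box_id"])
    ]
    climate = ClimateSeries.from_csv(
        config.climate_csv,
        baseline_start=config.baseline_start,
        baseline_end=config.baseline_end,
    )
    prey = pd.read_csv(config.prey_csv)
    prey["prey_index"] = 100.0 * prey["captures"] / prey["trap_nights"]
    years = sorted(recruits["hatch_year"].unique())
    covariates = climate.anomaly_table(years).merge(
        prey[["year", "prey_index"]].rename(columns={"year": "winter_year"}),
        on="winter_year",
        how="left",
    )
    recruits = recruits.merge(
        covariates.rename(columns={"winter_year": "hatch_year"})[
            ["hatch_year", "anomaly_c", "prey_index"]
        ],
        on="hatch_year",
        how="left",
    )
    recruits["complete_case"] = recruits[_MODEL_VARS].notna().all(axis=1)
    n_in, n_complete = len(recruits), int(recruits["complete_case"].sum())
    log.info("ingest: %d recruits, %d complete cases", n_in, n_complete)
    return DataBundle(
        registry=registry,
        recruits=recruits,
        climate=climate,
        prey=prey,
        covariates=covariates,
        n_ingested=n_in,
        n_complete=n_complete,
    )


def _dist_stats(d: pd.Series) -> dict:
    d = d.dropna()
    return {
        "n": int(d.size),
        "mean_km": float(d.mean()) if d.size else None,
        "sd_km": float(d.std(ddof=1)) if d.size > 1 else None,
        "min_km": float(d.min()) if d.size else None,
        "max_km": float(d.max()) if d.size else None,
    }


def descriptives(recruits: pd.DataFrame) -> dict:
    """Descriptive block: dispersal overall / by sex / by morph, age classes."""
    out = {"overall": _dist_stats(recruits["dispersal_km"])}
    for by in ("sex", "morph"):
        out[f"by_{by}"] = {
            str(level): _dist_stats(grp["dispersal_km"])
            for level, grp in recruits.groupby(by, dropna=True)
        }
    ages = recruits["age_at_recruitment"].astype(str)
    n = len(recruits)
    out["age_classes"] = {
        level: {
            "count": int((ages == level).sum()),
            "percent": _round_half_up(100.0 * (ages == level).sum() / n, 1),
        }
        for level in ("1", "2", "3+")
    }
    out["morph_counts"] = {
        "gray": int((recruits["morph"] == "gray").sum()),
        "brown": int((recruits["morph"] == "brown").sum()),
        "unscored": int(recruits["morph"].isna().sum()),
    }
    total = sum(v["count"] for v in out["age_classes"].values())
    if total != n:
        raise ValidationError(
            f"age-class counts ({total}) do not sum to the ingested total ({n})"
        )
    return out


def _yearly_morph_table(recruits: pd.DataFrame) -> pd.DataFrame:
    scored = recruits.dropna(subset=["morph", "anomaly_c"])
    g = scored.groupby("hatch_year").agg(
        n_brown=("morph", lambda m: int((m == "brown").sum())),
        n_total=("morph", "size"),
        anomaly_c=("anomaly_c", "first"),
    )
    return g.reset_index()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage in order and write all outputs under ``config.out_dir``.

    On a stage failure, partial outputs are moved to ``out_dir/failed/`` and
    a :class:`PipelineError` naming the stage is raised.  Reruns with the
    same config and seed produce byte-identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "ingest"
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    try:
        bundle = ingest(config)

        stage = "covariates"
        _write_csv(bundle.covariates, "covariates.csv")

        stage = "descriptives"
        desc = descriptives(bundle.recruits)
        p = out / "descriptives.json"
        p.write_text(json.dumps(desc, indent=2))
        written.append(p)

        stage = "brown_proportion_glm"
        yearly = _yearly_morph_table(bundle.recruits)
        glm = fit_brown_proportion_glm(yearly) if len(yearly) >= 2 else None

        stage = "dispersal_lmm"
        complete = bundle.recruits[bundle.recruits["complete_case"]]
        lmms: dict[str, LmmFit] = {}
        for aset in config.analysis_sets:
            fit = fit_dispersal_lmm(complete, analysis_set=aset)
            lmms[aset] = fit
            tag = aset.replace("-", "_")
            _write_csv(fit.fixed_table(), f"lmm_{tag}_fixed.csv")
            _write_csv(fit.varcomp_table(), f"lmm_{tag}_varcomps.csv")
            log.info("lmm %s: n=%d", aset, fit.n_obs)

        stage = "randomization"
        rng = np.random.default_rng(config.seed)
        with_dist = bundle.recruits.dropna(subset=["dispersal_km"])
        sets = candidate_distances(
            with_dist, bundle.registry, include_self=config.include_self_distance
        )
        results: dict[str, RandomizationResult] = {}
        results["all"] = randomization_test(
            with_dist["dispersal_km"].to_numpy(float),
            sets,
            m=config.reps,
            tail=config.tail,
            seed=rng,
        )
        for morph in ("gray", "brown"):
            if (with_dist["morph"] == morph).any():
                results[morph] = morph_stratified_test(
                    with_dist,
                    bundle.registry,
                    morph,
                    m=config.reps,
                    tail=config.tail,
                    seed=rng,
                    include_self=config.include_self_distance,
                )
        _write_csv(
            pd.DataFrame([r.summary_row() for r in results.values()]),
            "randomization.csv",
        )
        _write_csv(
            pd.DataFrame(
                {k: r.random_medians for k, r in results.items()}
            ),
            "randomization_null_medians.csv",
        )

        stage = "report"
        report = ReportBundle(
            descriptives=desc,
            glm=glm,
            lmm=lmms,
            randomization=results,
            config_hash=config.hash(),
            input_checksums={
                k: _checksum(getattr(config, k))
                for k in ("registry_csv", "recruits_csv", "climate_csv", "prey_csv")
            },
            n_ingested=bundle.n_ingested,
            n_complete=bundle.n_complete,
            seed=config.seed,
        )
        p = out / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2))
        written.append(p)
        (out / "run_log.txt").write_text(
            "\n".join(
                [
                    f"config_hash: {config.hash()}",
                    f"seed: {config.seed}",
                    f"n_ingested: {bundle.n_ingested}",
                    f"n_complete: {bundle.n_complete}",
                    *(f"n_{k}: {fit.n_obs}" for k, fit in lmms.items()),
                    f"elapsed_s: {time.time() - t0:.2f}",
                ]
            )
            + "\n"
        )
        return report
    except Exception as exc:  # preserve partial outputs for post-mortem
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                shutil.move(str(p), failed / p.name)
        raise PipelineError(stage, exc) from exc
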