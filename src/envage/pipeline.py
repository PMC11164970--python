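"""End-to-end orchestration: simulate -> score -> WQS -> SOM -> associate.

One :class:`RunConfig` (YAML-serializable) plus a global seed fully
determine every output.  Each stage draws its randomness from a child seed
of the global seed, outputs land in the configured directory, and a manifest
records the config hash, per-stage seeds, row counts at each exclusion step
and a SHA-256 checksum of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, som, wqs
from .aging_metrics import compute_phenoage, frailty_score, zscore
from .synthetic_cohort import (
    EXPOSURES,
    PROTECTIVE,
    GeneratorConfig,
    generate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    n: int = 5000
    out_dir: str = "envage_run"
    stages: dict = field(default_factory=lambda: {"simulate": True, "score": True,
                                                  "wqs": True, "som": True, "associate": True})
    wqs_outcomes: list = field(default_factory=lambda: ["phenoage", "brain_age_gap"])
    wqs_n_boot: int = 100
    wqs_direction: str = "positive"
    som_grid: tuple = (10, 10)
    som_k_range: tuple = (2, 8)
    covariates: list = field(default_factory=lambda: list(associations.DEFAULT_COVARIATES))
    exposure_mode: str = "archetypes"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        unknown = set(raw) - set(cfg.__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            expected = type(getattr(cfg, key))
            if expected in (tuple,):
                value = tuple(value)
            elif not isinstance(value, expected) and expected is not type(None):
                raise TypeError(f"config key {key!r} expects {expected.__name__}, got {type(value).__name__}")
            setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["som_grid"] = list(self.som_grid)
        d["som_k_range"] = list(self.som_k_range)
        return d

    def fingerprint(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _child_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(names, ss.spawn(len(names)))}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the manifest (also written to disk).

    Any stage failure aborts with a stage-named error; files already written
    by earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, ["simulate", "wqs", "som", "associate"])
    manifest = {"config": config.to_dict(), "config_hash": config.fingerprint(),
                "stage_seeds": seeds, "row_counts": {}, "outputs": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    cohort = None
    stage = "simulate"
    try:
        if config.stages.get("simulate", True):
            gen = GeneratorConfig(n=config.n, seed=seeds["simulate"], exposure_mode=config.exposure_mode)
            cohort = generate_cohort(gen)
            manifest["row_counts"]["simulated"] = len(cohort)
            write_cohort(cohort, out / "cohort.csv", gen)
            record("cohort", out / "cohort.csv")

        stage = "score"
        if config.stages.get("score", True) and cohort is not None:
            panel = cohort[["albumin", "creatinine", "glucose", "crp", "lymphocyte_pct",
                            "mcv", "rdw", "alp", "wbc", "age"]]
            cohort["phenoage_recomputed"] = compute_phenoage(panel)
            cohort["frailty_score"] = frailty_score(cohort)
            for col in ["brain_age_gap", "gm_volume_z"]:
                if col in cohort:
                    cohort[f"{col}_z"] = zscore(cohort[col].to_numpy())
            manifest["row_counts"]["scored_complete"] = int(cohort.dropna(subset=["phenoage", "frailty_score"]).shape[0])
            cohort.to_csv(out / "scored.csv", index=False)
            record("scored", out / "scored.csv")

        stage = "wqs"
        if config.stages.get("wqs", True) and cohort is not None:
            wqs_cfg = wqs.WQSConfig(n_boot=config.wqs_n_boot, seed=seeds["wqs"],
                                    direction=config.wqs_direction)
            report = {}
            for outcome in config.wqs_outcomes:
                res = wqs.run_wqs(cohort, outcome, list(EXPOSURES), config.covariates,
                                  wqs_cfg, reverse=list(PROTECTIVE))
                results = res if isinstance(res, dict) else {res.direction: res}
                report[outcome] = {
                    d: {"weights": dict(zip(r.exposures, np.round(r.weights, 6).tolist())),
                        "beta": r.beta, "se": r.se, "ci": list(r.ci), "p_value": r.p_value,
                        "n_converged": r.n_converged, "n_train": r.n_train, "n_validation": r.n_validation}
                    for d, r in results.items()
                }
            (out / "wqs.json").write_text(json.dumps(report, indent=1))
            record("wqs", out / "wqs.json")

        stage = "som"
        if config.stages.get("som", True) and cohort is not None:
            Xz = som.standardize(cohort[list(EXPOSURES)])
            model = som.train_som(Xz.to_numpy(), grid=tuple(config.som_grid), seed=seeds["som"])
            selection = som.select_k(model, Xz.to_numpy(),
                                     k_range=range(config.som_k_range[0], config.som_k_range[1] + 1))
            labels = som.assign(Xz.to_numpy(), model, selection)
            assignment = som.name_subpopulations(labels, Xz)
            pd.DataFrame({"label": labels, "subpopulation": assignment.named_labels()}).to_csv(
                out / "subpopulations.csv", index=False)
            record("subpopulations", out / "subpopulations.csv")
            manifest["som"] = {"selected_k": selection.selected_k, "trace": selection.trace,
                               "names": assignment.names, "reference": assignment.reference}
            contrasts = pd.concat([
                som.compare_subpopulations(assignment, cohort, outcome, config.covariates)
                for outcome in config.wqs_outcomes + ["frailty_score"] if outcome in cohort
            ], ignore_index=True)
            contrasts.to_csv(out / "subpopulation_contrasts.csv", index=False)
            record("subpopulation_contrasts", out / "subpopulation_contrasts.csv")

        stage = "associate"
        if config.stages.get("associate", True) and cohort is not None:
            outcomes = [c for c in config.wqs_outcomes + ["frailty_score"] if c in cohort]
            scan = associations.single_exposure_scan(cohort, list(EXPOSURES), outcomes, config.covariates)
            scan.to_csv(out / "associations.csv", index=False)
            record("associations", out / "associations.csv")
            manifest["row_counts"]["association_models"] = len(scan)
            manifest["fdr_family_size"] = int(len(scan))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
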