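"""End-to-end orchestration: simulate -> preprocess -> grid search -> SPA
-> clinical table, with a run manifest for reproducibility.

The single run seed is expanded into independent per-stage substreams via
numpy's SeedSequence with a fixed stage counter, so adding a stage does not
shift the randomness of the ones downstream. Identical config + seed gives
byte-identical outputs.
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

from . import clinical, model_selection, preprocess, simulate, spa
from .peaktable import read_peak_table, write_peak_table

logger = logging.getLogger("koplspa")

# fixed stage counters for seed substreams; append-only
_STAGE_IDS = {"simulate": 0, "folds": 1, "spa": 2, "clinical": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    outdir: Path
    design: dict = field(default_factory=dict)
    peak_table: Path | None = None
    sigma_grid: tuple = model_selection.DEFAULT_SIGMA_GRID
    ao_grid: tuple = model_selection.DEFAULT_AO_GRID
    folds: int = 10
    spa: dict = field(default_factory=dict)
    clinical_variables: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw or "outdir" not in raw:
            raise ValueError("config must define 'seed' and 'outdir'")
        grid = raw.get("grid", {})
        cfg = cls(
            seed=int(raw["seed"]),
            outdir=Path(raw["outdir"]),
            design=raw.get("design", {}),
            peak_table=Path(raw["peak_table"]) if raw.get("peak_table") else None,
            sigma_grid=tuple(grid.get("sigma", model_selection.DEFAULT_SIGMA_GRID)),
            ao_grid=tuple(grid.get("ao", model_selection.DEFAULT_AO_GRID)),
            folds=int(grid.get("folds", 10)),
            spa=raw.get("spa", {}),
            clinical_variables=raw.get("clinical_variables", []),
        )
        if cfg.peak_table is not None and not cfg.peak_table.exists():
            raise FileNotFoundError(f"peak table not found: {cfg.peak_table}")
        if cfg.peak_table is None and not cfg.design and "design" not in raw:
            raise ValueError("config needs either 'peak_table' or 'design'")
        return cfg

    def config_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing TSV outputs plus ``manifest.json``.

    Returns the manifest dict. A stage failure aborts with the stage named;
    outputs of completed stages are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    def run_stage(name, func):
        t0 = time.perf_counter()
        try:
            result = func()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        elapsed = time.perf_counter() - t0
        logger.info("stage=%s elapsed=%.2fs", name, elapsed)
        manifest["stages"].append({"name": name, "elapsed_s": round(elapsed, 3)})
        return result

    # --- input peak table -------------------------------------------
    def _get_table():
        if config.peak_table is not None:
            return read_peak_table(config.peak_table)
        design = simulate.SyntheticDesign(
            **{**config.design, "seed": stage_seed(config.seed, "simulate")}
        )
        table = simulate.generate_peak_table(design)
        write_peak_table(table, out / "peaks.tsv")
        manifest["outputs"]["peaks.tsv"] = None
        return table

    table = run_stage("simulate", _get_table)

    # --- preprocessing ----------------------------------------------
    def _preprocess():
        conc = preprocess.normalize_internal_standard(table)
        conc.to_frame().to_csv(out / "concentrations.tsv", sep="\t", index=False)
        scaled = preprocess.autoscale(conc)
        scaled.to_frame().to_csv(out / "scaled.tsv", sep="\t", index=False)
        manifest["outputs"]["concentrations.tsv"] = None
        manifest["outputs"]["scaled.tsv"] = None
        return conc

    conc = run_stage("preprocess", _preprocess)

    # --- grid search -------------------------------------------------
    def _grid():
        result = model_selection.grid_search(
            conc.values,
            conc.labels,
            sigma_grid=config.sigma_grid,
            ao_grid=config.ao_grid,
            k=config.folds,
            seed=stage_seed(config.seed, "folds"),
        )
        report = result.grid.copy()
        report.to_csv(out / "accv_grid.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {
                    "sigma": result.best_sigma,
                    "Ao": result.best_Ao,
                    "ACCV": result.best_accv,
                    "R2X": result.stats.R2X,
                    "R2Y": result.stats.R2Y,
                    "Q2Y": result.stats.Q2Y,
                }
            ]
        )
        summary.to_csv(out / "model_summary.tsv", sep="\t", index=False)
        manifest["outputs"]["accv_grid.tsv"] = None
        manifest["outputs"]["model_summary.tsv"] = None
        return result

    grid_result = run_stage("gridsearch", _grid)

    # --- SPA ----------------------------------------------------------
    def _spa():
        spa_cfg = spa.SPAConfig(
            sigma=grid_result.best_sigma,
            ao=grid_result.best_Ao,
            seed=stage_seed(config.seed, "spa"),
            **config.spa,
        )
        scores = spa.run_spa(conc.values, conc.labels, conc.metabolite_names, spa_cfg)
        spa.scores_to_frame(scores).to_csv(out / "spa.tsv", sep="\t", index=False)
        manifest["outputs"]["spa.tsv"] = None
        return scores

    run_stage("spa", _spa)

    # --- clinical table ----------------------------------------------
    if config.clinical_variables:
        def _clinical():
            variables = [
                simulate.ClinicalVariableSpec(**v) for v in config.clinical_variables
            ]
            design = simulate.SyntheticDesign(**{**config.design, "seed": 0}) \
                if config.peak_table is None else None
            n1 = design.n_group1 if design else int((table.labels == np.unique(table.labels)[1]).sum())
            n2 = design.n_group2 if design else int((table.labels == np.unique(table.labels)[0]).sum())
            frame = simulate.generate_clinical_table(
                variables, n1, n2, seed=stage_seed(config.seed, "clinical")
            )
            summary = clinical.build_table(frame, "label")
            summary.table.to_csv(out / "table1.tsv", sep="\t", index=False)
            manifest["outputs"]["table1.tsv"] = None

        run_stage("table1", _clinical)

    for name in manifest["outputs"]:
        manifest["outputs"][name] = _sha256(out / name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
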