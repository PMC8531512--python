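"""End-to-end pipeline orchestration, configuration and report tables.

The full run mirrors the analysis workflow of a multi-environment trial:
QC -> imputation -> GRM -> stage-1 trial models (within/across
heritability tables) -> trait correlations and PCA -> the three genomic
prediction schemes -> accuracy tables.  Every stage logs its parameters
and record counts into ``run_log.txt``; expensive stage outputs are
cached on disk keyed by a content hash of their inputs, so partial
reruns resume instead of recomputing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cv as cvmod
from . import genotypes as gt
from . import phenotypes as ph
from . import simulate as sim

__all__ = ["PipelineConfig", "run_pipeline", "cmd_simulate", "StageCache"]

logger = logging.getLogger(__name__)

_DEFAULT_SCHEMES = ("SE_CV1", "ME_CV1", "ME_CV2")


@dataclass
class PipelineConfig:
    """Flat configuration for a pipeline run (one nesting level)."""

    outdir: str = "megblup_out"
    genotypes: str | None = None
    genotype_format: str = "matrix"
    phenotypes: str | None = None
    traits: list | None = None
    qc: dict = field(default_factory=dict)            # QCThresholds fields
    impute_method: str = "marker_mean"
    grm_method: str = "vanraden1"
    cv: dict = field(default_factory=dict)            # schemes, folds, repeats, seed
    simulate: dict = field(default_factory=dict)      # preset and/or SimulationConfig fields

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @property
    def cv_seed(self) -> int:
        if "seed" not in self.cv:
            raise ValueError("cv.seed is mandatory for the stochastic CV stage")
        return int(self.cv["seed"])


class StageCache:
    """Content-hash keyed stage cache under ``<outdir>/cache``.

    A stage result (a CSV-serializable frame) is reused only when the
    recorded input hash matches the recomputed one; a tampered or stale
    manifest entry triggers recomputation.
    """

    def __init__(self, outdir: Path):
        self.dir = Path(outdir) / "cache"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = {}
        if self.manifest_path.exists():
            try:
                self.manifest = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                self.manifest = {}

    @staticmethod
    def hash_inputs(*parts) -> str:
        h = hashlib.sha256()
        for part in parts:
            if isinstance(part, (bytes, bytearray)):
                h.update(part)
            elif isinstance(part, pd.DataFrame):
                h.update(pd.util.hash_pandas_object(part, index=True).to_numpy().tobytes())
            elif isinstance(part, np.ndarray):
                h.update(np.ascontiguousarray(part).tobytes())
            else:
                h.update(json.dumps(part, sort_keys=True, default=str).encode())
        return h.hexdigest()

    def get(self, stage: str, key: str) -> pd.DataFrame | None:
        entry = self.manifest.get(stage)
        path = self.dir / f"{stage}.csv"
        if entry and entry.get("hash") == key and path.exists():
            logger.info("stage %s: cache hit (%s)", stage, key[:12])
            return pd.read_csv(path)
        return None

    def put(self, stage: str, key: str, frame: pd.DataFrame) -> None:
        frame.to_csv(self.dir / f"{stage}.csv", index=False)
        self.manifest[stage] = {"hash": key}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))


def cmd_simulate(config: sim.SimulationConfig, outdir) -> dict[str, Path]:
    """Simulate a trial and write genotypes, map, phenotypes and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, table, truth = sim.simulate_trial(config)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "map": outdir / "genotypes.tsv.map",
        "phenotypes": outdir / "phenotypes.csv",
        "truth_gebv": outdir / "truth_gebv.csv",
        "truth_summary": outdir / "truth_summary.json",
    }
    gt.write_genotypes(g, paths["genotypes"], paths["map"])
    table.to_csv(paths["phenotypes"])
    truth_frame = pd.DataFrame({"gebv": truth.true_gebv}).join(
        truth.true_env_deviation.add_prefix("gE_")
    )
    truth_frame.to_csv(paths["truth_gebv"], index_label="genotype")
    summary = {
        "trait": config.trait,
        "realized_h2_within": truth.realized_h2_within.to_dict(),
        "realized_h2_across": truth.realized_h2_across,
        "var_g": config.var_g, "var_ge": config.var_ge, "var_e": config.var_e,
        "seed": config.seed,
    }
    paths["truth_summary"].write_text(json.dumps(summary, indent=1))
    return paths


def _heritability_tables(table: ph.PhenotypeTable, traits) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    within_rows, across_rows, across_fits = [], [], {}
    multi_env = len(table.environments) >= 2
    for trait in traits:
        for env in table.environments:
            fit = ph.fit_within_env(table, env, trait)
            v = fit.components
            within_rows.append(
                {
                    "trait": trait, "environment": env,
                    "H2": ph.heritability_within(v),
                    "sigma2_g": v.sigma2_g, "sigma2_e": v.sigma2_e,
                    "n_reps": v.n_reps, "grand_mean": fit.mu,
                }
            )
        if multi_env:
            fit = ph.fit_across_env(table, trait)
            v = fit.components
            across_rows.append(
                {
                    "trait": trait, "H2": ph.heritability_across(v),
                    "sigma2_g": v.sigma2_g, "sigma2_ge": v.sigma2_ge,
                    "sigma2_e": v.sigma2_e, "n_envs": v.n_envs,
                    "n_reps": v.n_reps, "grand_mean": fit.mu,
                }
            )
            across_fits[trait] = fit
    return pd.DataFrame(within_rows), pd.DataFrame(across_rows), across_fits


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report tables in memory.

    Writes CSV reports plus a human-readable summary into
    ``config.outdir``.  Raises with the failing stage's name on error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"{stage}: {message}"
        logger.info(line)
        log_lines.append(line)

    stage = "setup"
    try:
        if config.genotypes is None or config.phenotypes is None:
            stage = "simulate"
            if not config.simulate:
                raise ValueError("no genotype/phenotype paths and no simulate block")
            simcfg = _simulation_config(config.simulate)
            paths = cmd_simulate(simcfg, outdir / "simulated")
            config.genotypes = str(paths["genotypes"])
            config.genotype_format = "matrix"
            config.phenotypes = str(paths["phenotypes"])
            log(stage, f"preset inputs written under {outdir / 'simulated'} "
                       f"(seed={simcfg.seed})")

        stage = "read_genotypes"
        g = gt.read_genotypes(config.genotypes, format=config.genotype_format)
        log(stage, f"{g.n_lines} lines x {g.n_markers} markers, "
                   f"{g.n_missing} missing calls ({config.genotypes})")

        stage = "qc"
        thresholds = gt.QCThresholds(**config.qc) if config.qc else gt.QCThresholds()
        g, qc_report = gt.qc_filter(g, thresholds)
        qc_frame = qc_report.to_frame()
        qc_frame.to_csv(outdir / "qc_report.csv", index=False)
        log(stage, f"thresholds={thresholds}; kept {g.n_lines} lines x {g.n_markers} markers")

        stage = "impute"
        g = gt.impute_missing(g, config.impute_method)
        log(stage, f"method={config.impute_method}")

        stage = "grm"
        grm = gt.compute_grm(g, method=config.grm_method)
        grm.to_frame().to_csv(outdir / "grm.csv")
        log(stage, f"method={config.grm_method}, eps={grm.epsilon}, "
                   f"mean diagonal={float(np.mean(np.diag(grm.values))):.3f}")

        stage = "read_phenotypes"
        table = ph.PhenotypeTable.read_csv(config.phenotypes)
        genotyped = set(g.line_ids)
        table = ph.PhenotypeTable(table.data[table.data["genotype"].isin(genotyped)])
        traits = config.traits or table.traits
        log(stage, f"{len(table.data)} plot records, traits={traits}, "
                   f"environments={table.environments}")

        stage = "stage1_models"
        within_tab, across_tab, across_fits = _heritability_tables(table, traits)
        within_tab.to_csv(outdir / "heritability_within.csv", index=False)
        across_tab.to_csv(outdir / "heritability_across.csv", index=False)
        log(stage, f"{len(within_tab)} within-environment fits, "
                   f"{len(across_tab)} across-environment fits")

        stage = "correlations"
        corr_gen = corr_phe = pca = None
        if len(across_fits) >= 2:
            corr = ph.trait_correlations(across_fits, table)
            corr_gen, corr_phe = corr.genetic, corr.phenotypic
            corr_gen.to_csv(outdir / "correlations_genetic.csv")
            corr_phe.to_csv(outdir / "correlations_phenotypic.csv")
            pca_summary = ph.trait_pca(pd.DataFrame({t: f.blups for t, f in across_fits.items()}))
            pca = pd.DataFrame({"explained_pct": pca_summary.explained_pct})
            pca.to_csv(outdir / "pca_explained.csv")
            log(stage, "genetic/phenotypic correlations and PCA written")
        else:
            log(stage, "skipped (fewer than two traits)")

        stage = "cv"
        schemes = list(config.cv.get("schemes", _DEFAULT_SCHEMES))
        folds = int(config.cv.get("folds", 5))
        repeats = int(config.cv.get("repeats", 50))
        seed = config.cv_seed if schemes else 0
        cache = StageCache(outdir)
        cv_key = StageCache.hash_inputs(
            grm.values, table.data, sorted(schemes), folds, repeats, seed, traits
        )
        records = cache.get("cv", cv_key)
        if records is None:
            all_records = []
            multi_env = len(table.environments) >= 2
            for trait in traits:
                blups = cvmod.stage1_blups(table, trait)
                if "SE_CV1" in schemes:
                    sch = cvmod.CVScheme("SE_CV1", folds, repeats, seed)
                    all_records.append(cvmod.run_se_cv1(blups, grm, sch, trait).records)
                if "ME_CV1" in schemes and multi_env:
                    sch = cvmod.CVScheme("ME_CV1", folds, repeats, seed)
                    all_records.append(cvmod.run_me_cv1(blups, grm, sch, trait).records)
                if "ME_CV2" in schemes and multi_env:
                    all_records.append(cvmod.run_me_cv2(blups, grm, trait).records)
            records = (
                pd.concat(all_records, ignore_index=True)
                if all_records
                else pd.DataFrame(columns=cvmod.RECORD_COLUMNS)
            )
            cache.put("cv", cv_key, records)
            log(stage, f"schemes={schemes}, folds={folds}, repeats={repeats}, seed={seed}")
        else:
            log(stage, f"reused cached records (hash {cv_key[:12]})")
        records.to_csv(outdir / "cv_records.csv", index=False)
        cv_summary = (
            records.groupby(["trait", "environment", "scheme"], observed=True)["accuracy"]
            .agg(["mean", "std", "count"]).reset_index()
            if len(records)
            else pd.DataFrame()
        )
        cv_summary.to_csv(outdir / "cv_summary.csv", index=False)
        accuracy_table = (
            records.pivot_table(index="trait", columns="scheme", values="accuracy")
            if len(records)
            else pd.DataFrame()
        )
        accuracy_table.to_csv(outdir / "accuracy_by_scheme.csv")

        stage = "report"
        _write_summary(outdir, within_tab, across_tab, corr_gen, accuracy_table, log_lines)
    except Exception as exc:
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + f"\nFAILED at {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "heritability_within": within_tab,
        "heritability_across": across_tab,
        "correlations_genetic": corr_gen,
        "correlations_phenotypic": corr_phe,
        "pca": pca,
        "cv_records": records,
        "cv_summary": cv_summary,
        "accuracy_by_scheme": accuracy_table,
        "outdir": outdir,
    }


def _simulation_config(block: dict) -> sim.SimulationConfig:
    block = dict(block)
    preset = block.pop("preset", None)
    if preset:
        return sim.get_preset(preset, **block)
    return sim.SimulationConfig(**block)


def _write_summary(outdir, within_tab, across_tab, corr_gen, accuracy_table, log_lines):
    lines = ["megblup pipeline summary", "=" * 30, ""]
    lines.append("Within-environment heritability (2 d.p.):")
    if len(within_tab):
        piv = within_tab.pivot(index="trait", columns="environment", values="H2").round(2)
        lines.append(piv.to_string())
    lines.append("")
    if len(across_tab):
        lines.append("Across-environment heritability (2 d.p.):")
        lines.append(across_tab.set_index("trait")["H2"].round(2).to_string())
        lines.append("")
    if corr_gen is not None:
        lines.append("Genetic correlations (BLUP-BLUP):")
        lines.append(corr_gen.round(2).to_string())
        lines.append("")
    if len(accuracy_table):
        lines.append("Mean prediction accuracy per scheme:")
        lines.append(accuracy_table.round(2).to_string())
        lines.append("")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    (outdir / "run_log.txt").write_text(f"run completed {stamp}\n" + "\n".join(log_lines) + "\n")
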