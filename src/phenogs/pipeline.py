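"""End-to-end pipeline: simulate-or-read, indices, adjustment, QC, GRM,
model fitting, cross-validation, and the accuracy summary table.

Each stage writes its artifact into the output directory together with a
run manifest (seed, version, config hash); a stage failure aborts with
the stage name while earlier outputs are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, genomics, io, spectral, trial
from .evaluation import CVConfig, kfold_cv
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    out_dir: str
    seed: int = 0
    simulation: dict | None = None       # SimulationConfig overrides, or None
    geno_path: str | None = None
    plots_path: str | None = None
    reflectance_path: str | None = None
    primary_traits: tuple = ("yield", "GPC")
    models: tuple = ("unigs", "srir", "gs_sri", "multigs")
    stages: tuple = ("heading", "grain_filling")
    sri: str = "all"
    qc: dict = dataclasses.field(default_factory=dict)
    cv: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        obj = cls(**cfg)
        obj.validate()
        return obj

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("geno_path", "plots_path", "reflectance_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(
                        f"{name} is required when no simulation block is given"
                    )
                if not Path(p).exists():
                    raise ValueError(f"{name}: {p} does not exist")
        for m in self.models:
            if m not in evaluation.MODELS:
                raise ValueError(f"unknown model {m!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory result bundle.

    Artifacts written: genotype/plot/reflectance CSVs (when simulated),
    per-trait BLUE tables, the QC report, the accuracy table in tidy
    form, a wide accuracy summary (model x stage x environment), and the
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_run = []
    bundle: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        markers, values, plots, reflectance, truth = _simulate(sim_cfg)
        bundle["truth"] = truth
        io.write_genotypes(markers, out / "genotypes.csv")
        plots.to_csv(out / "plots.csv", index=False)
        reflectance.to_csv(out / "reflectance.csv", index=False)
    else:
        markers = io.read_genotypes(config.geno_path)
        plots = io.read_plots(config.plots_path)
        reflectance = io.read_reflectance(config.reflectance_path)
    stages_run.append("inputs")

    # --- spectral indices -------------------------------------------------
    panel, excl = _average(reflectance)
    sri_plot = _indices(panel)
    sri_plot.to_csv(out / "sri_plots.csv", index=False)
    if len(excl):
        excl.to_csv(out / "sri_exclusions.csv", index=False)
    stages_run.append("sri")

    # --- adjustment to BLUEs ---------------------------------------------
    blue = _adjust(plots, sri_plot, config)
    io.write_phenotypes(blue, out / "blue.csv")
    stages_run.append("adjust")

    # --- marker QC + GRM --------------------------------------------------
    filtered, report = _qc(markers, config)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    grm = _grm(filtered)
    stages_run += ["qc", "grm"]

    # --- cross-validation -------------------------------------------------
    acc = _cross_validate(blue, grm, config)
    acc_df = _accuracy_frame(acc)
    acc_df.to_csv(out / "accuracy.csv", index=False)
    summary = _summary_view(acc_df)
    summary.to_csv(out / "accuracy_summary.csv")
    stages_run.append("cv")

    io.write_manifest(out, config.as_dict(), config.seed, stages_run)
    bundle.update({
        "markers": filtered, "grm": grm, "blue": blue,
        "qc_report": report, "accuracy": acc_df, "summary": summary,
    })
    return bundle


_simulate = _stage("simulate")(simulate_study)
_average = _stage("sri")(spectral.average_plot_reflectance)
_indices = _stage("sri")(spectral.compute_indices)


@_stage("adjust")
def _adjust(plots, sri_plot, config: PipelineConfig) -> pd.DataFrame:
    """BLUEs for primary traits and for each index x stage."""
    frames = []
    for trait in config.primary_traits:
        if trait in plots.columns:
            frames.append(trial.fit_acbd_blue(plots, trait))
    meta = plots[["plot_id", "environment", "block_id", "genotype_id", "is_check"]]
    for stage in config.stages:
        stage_df = sri_plot[sri_plot["stage"] == stage]
        merged = stage_df.merge(meta, on=["plot_id", "environment", "genotype_id"])
        for idx in spectral.INDEX_NAMES:
            if idx not in merged.columns:
                continue
            b = trial.fit_acbd_blue(merged, idx)
            b["trait"] = f"{idx}@{stage}"
            frames.append(b)
    return pd.concat(frames, ignore_index=True)


@_stage("qc")
def _qc(markers, config: PipelineConfig):
    imputed_ready, report = genomics.qc_filter(markers, **config.qc)
    return genomics.impute_missing(imputed_ready), report


_grm = _stage("grm")(genomics.compute_grm)


@_stage("cv")
def _cross_validate(blue: pd.DataFrame, grm, config: PipelineConfig) -> list:
    entries = blue[~blue["is_check"].astype(bool)]
    wide_all = entries.pivot_table(
        index=["environment", "genotype_id"], columns="trait", values="value"
    )
    results = []
    for env, wide in wide_all.groupby(level="environment"):
        wide = wide.droplevel("environment")
        lines = wide.index.intersection(grm.line_ids)
        G = grm.subset(lines)
        for trait in config.primary_traits:
            if trait not in wide.columns:
                continue
            y = wide.loc[lines, trait].to_numpy()
            for stage in config.stages:
                sri_cols = [
                    c for c in wide.columns if c.endswith(f"@{stage}")
                    and (config.sri == "all" or c.startswith(config.sri + "@"))
                ]
                X = wide.loc[lines, sri_cols].to_numpy() if sri_cols else None
                for model in config.models:
                    if model != "unigs" and X is None:
                        continue
                    if model == "unigs" and stage != config.stages[0]:
                        continue   # markers-only: stage-invariant
                    cfg = CVConfig(
                        model=model, seed=config.seed, stage=stage,
                        **config.cv,
                    )
                    results.append(kfold_cv(
                        y, G, X_sri=X, cfg=cfg, trait=trait, environment=env,
                    ))
    return results


def _accuracy_frame(results: list) -> pd.DataFrame:
    rows = [{
        "trait": r.trait, "model": r.model, "stage": r.stage or "",
        "environment": r.environment, "mean_accuracy": r.mean, "se": r.se,
        "n_replicates": len(r.accuracies),
    } for r in results]
    return pd.DataFrame(rows)


def _summary_view(acc_df: pd.DataFrame) -> pd.DataFrame:
    """Wide accuracy summary: one row per trait x model x stage."""
    view = acc_df.copy()
    view["cell"] = view.apply(
        lambda r: f"{r.mean_accuracy:.2f} ({r.se:.3f})", axis=1
    )
    return view.pivot_table(
        index=["trait", "model", "stage"], columns="environment",
        values="cell", aggfunc="first",
    )
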