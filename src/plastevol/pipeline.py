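"""End-to-end orchestration: simulate (or load) -> preprocess -> analyses.

`run_pipeline` executes the enabled stages in dependency order, writes every
result as TSV into the output directory, and records a manifest (seeds,
config hash, package versions, per-stage row counts) so that any numeric
output is traceable.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .commongarden import fit_commongarden_model
from .design import (
    SALINITY_LEVELS,
    common_garden_design_frame,
    enumerate_common_garden_design,
    enumerate_selection_design,
    selection_design_frame,
)
from .mixedmodel import InsufficientData, compute_r2
from .partition import ADMISSIBLE_TEST_ENVS, partition_all, partition_results_frame
from .preprocess import DEFAULT_MIN_BIOAREA, DEFAULT_VOLUME_UL, prepare_analysis_table
from .robustness import DEFAULT_FRACTIONS, DEFAULT_N_BOOT, bootstrap_robustness
from .selection import fit_temporal_model, summarize_temporal, temporal_model_spec
from .simulate import TRAITS, default_params, simulate_experiment


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "plastevol_run"
    seed: int = 0
    input_table: Optional[str] = None  # TSV of trait records; None -> simulate
    salinities: tuple[float, ...] = SALINITY_LEVELS
    n_replicates: int = 3
    n_cg_replicates: int = 2
    mean_count: float = 40.0
    species: tuple[str, ...] = ("PA", "ST")
    traits: tuple[str, ...] = TRAITS
    min_bioarea: float = DEFAULT_MIN_BIOAREA
    volume_ul: float = DEFAULT_VOLUME_UL
    df_method: str = "satterthwaite"
    run_temporal: bool = True
    run_commongarden: bool = True
    run_partition: bool = True
    run_robustness: bool = False
    partition_envs: tuple[float, ...] = ADMISSIBLE_TEST_ENVS
    robustness_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    robustness_n_boot: int = DEFAULT_N_BOOT
    robustness_species: str = "PA"
    robustness_trait: str = "bio_area"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("salinities", "species", "traits", "partition_envs",
                    "robustness_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to disk).

    On stage failure, partial outputs and a manifest naming the failed stage
    are persisted before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "versions": _library_versions(),
        "stages": {},
        "skipped": [],
    }

    def finish(stage, **info):
        manifest["stages"][stage] = info
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "design"
    try:
        selection = enumerate_selection_design(
            config.salinities, n_replicates=config.n_replicates
        )
        cg = enumerate_common_garden_design(
            selection, config.salinities, n_cg_replicates=config.n_cg_replicates
        )
        finish(stage,
               n_selection=_write_tsv(selection_design_frame(selection),
                                      out / "design_selection.tsv"),
               n_common_garden=_write_tsv(common_garden_design_frame(cg),
                                          out / "design_common_garden.tsv"))

        stage = "records"
        if config.input_table is not None:
            records = pd.read_csv(config.input_table, sep="\t")
        else:
            params = default_params(seed=config.seed)
            params.mean_count = config.mean_count
            records = simulate_experiment(params, selection, cg, seed=config.seed)
            _write_tsv(records, out / "simulated_records.tsv")
        finish(stage, n_records=len(records))

        stage = "preprocess"
        table = prepare_analysis_table(records, config.min_bioarea, config.volume_ul)
        finish(stage, n_rows=_write_tsv(table, out / "analysis_table.tsv"),
               n_removed=len(records) - len(table))

        r2_rows = []
        if config.run_temporal:
            stage = "temporal"
            fits = {}
            for sp in config.species:
                for trait in config.traits:
                    fit = fits[(sp, trait)] = fit_temporal_model(
                        table, sp, trait, df_method=config.df_method
                    )
                    if not isinstance(fit, InsufficientData) and fit.converged \
                            and not fit.degenerate:
                        r2 = compute_r2(fit)
                        r2_rows.append(dict(analysis="temporal", species=sp,
                                            trait=trait,
                                            r2_marginal=r2.r2_marginal,
                                            r2_conditional=r2.r2_conditional))
            finish(stage, n_rows=_write_tsv(summarize_temporal(fits),
                                            out / "temporal_effects.tsv"))
        else:
            manifest["skipped"].append("temporal")

        if config.run_commongarden:
            stage = "common_garden"
            rows = []
            for sp in config.species:
                for trait in config.traits:
                    fit = fit_commongarden_model(table, sp, trait,
                                                 df_method=config.df_method)
                    frame = fit.summary_frame()
                    frame.insert(0, "trait", trait)
                    frame.insert(0, "species", sp)
                    rows.append(frame)
                    if fit.converged and not fit.degenerate:
                        r2 = compute_r2(fit)
                        r2_rows.append(dict(analysis="common_garden", species=sp,
                                            trait=trait,
                                            r2_marginal=r2.r2_marginal,
                                            r2_conditional=r2.r2_conditional))
            finish(stage, n_rows=_write_tsv(pd.concat(rows, ignore_index=True),
                                            out / "commongarden_effects.tsv"))
        else:
            manifest["skipped"].append("common_garden")

        if r2_rows:
            _write_tsv(pd.DataFrame(r2_rows), out / "r2_table.tsv")

        if config.run_partition:
            stage = "partition"
            frames = []
            for sp in config.species:
                for trait in config.traits:
                    for env in config.partition_envs:
                        for history in (False, True):
                            batch = partition_all(table, sp, trait, env, history,
                                                  df_method=config.df_method)
                            frame = partition_results_frame(batch)
                            if len(frame):
                                frame.insert(0, "species", sp)
                                frames.append(frame)
            part = (pd.concat(frames, ignore_index=True)
                    if frames else pd.DataFrame())
            finish(stage, n_rows=_write_tsv(part, out / "partition_components.tsv"))
        else:
            manifest["skipped"].append("partition")

        if config.run_robustness:
            stage = "robustness"
            sub = table[(table["species"] == config.robustness_species)
                        & (table["phase"] != "common_garden_day82")].copy()
            sub["time"] = sub["time"].astype(int)
            sub["competition"] = sub["competition"].astype(int)
            spec = temporal_model_spec(config.robustness_trait, df_method="normal")
            summary = bootstrap_robustness(
                sub, spec, fractions=config.robustness_fractions,
                n_boot=config.robustness_n_boot, seed=config.seed,
            )
            finish(stage, n_rows=_write_tsv(summary.table, out / "robustness.tsv"),
                   n_boot=config.robustness_n_boot)
        else:
            manifest["skipped"].append("robustness")

        finish("complete", ok=True)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    return manifest


def _library_versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
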