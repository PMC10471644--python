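"""Reproducible pipeline orchestration: simulate/load → classify → metrics →
PERMANOVA → Bayesian fit/selection, with a run manifest.

A single structured config (YAML or an equivalent dict) governs all stages;
every stochastic stage takes an explicit seed derived from the top-level one
(no wall-clock seeding).  The manifest records the config snapshot, input
digests, seeds, per-stage timings and output paths, so a run can be
reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import community_metrics, hier_bayes, permanova as permanova_mod, pufa_classes, synthetic_data
from .data_model import (
    load_reference_profiles,
    read_survey,
    read_taxon_table,
    write_responses,
    write_survey,
    write_taxon_table,
)

logger = logging.getLogger("pufalakes")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def package_version() -> str:
    try:
        return _pkg_version("pufalakes")
    except PackageNotFoundError:  # pragma: no cover - editable-install oddity
        return "unknown"


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise PipelineError("config file must contain a mapping")
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("simulate", "permanova", "fa_samples", "fit")
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(names, children)}


def validate_config(config: Mapping[str, Any]) -> None:
    """Fail before any stage runs if the config cannot support the pipeline."""
    if "seed" not in config:
        raise PipelineError("config requires an explicit top-level seed")
    survey = config.get("survey", {}) or {}
    simulate = config.get("simulate", {}) or {}
    if not survey.get("path") and not simulate.get("enabled", False):
        raise PipelineError(
            "config must provide survey.path or enable the simulate stage"
        )
    fit_cfg = config.get("fit", {}) or {}
    if fit_cfg.get("enabled", False) and "response" not in fit_cfg:
        raise PipelineError("fit stage requires a response name")


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    validate_config(config)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "pufalakes_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    seeds = _stage_seeds(seed)
    manifest: dict[str, Any] = {
        "package_version": package_version(),
        "config": json.loads(json.dumps(config, default=str)),
        "seed": seed,
        "stage_seeds": seeds,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, started: float, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.perf_counter() - started, 3),
        }
        for name, path in outputs.items():
            manifest["outputs"][name] = str(path)

    def run_stage(stage: str, func):
        started = time.perf_counter()
        logger.info("stage %s: started", stage)
        try:
            outputs = func()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, started, outputs)
        logger.info("stage %s: complete", stage)

    state: dict[str, Any] = {}

    # --- taxon profiles -----------------------------------------------------
    taxon_path = (config.get("inputs", {}) or {}).get("taxon_table")
    if taxon_path:
        state["profiles"] = read_taxon_table(taxon_path)
        manifest["inputs"]["taxon_table"] = _digest(Path(taxon_path))
    else:
        state["profiles"] = load_reference_profiles()
        manifest["inputs"]["taxon_table"] = "packaged reference table"

    # --- survey: simulate or load -------------------------------------------
    simulate_cfg = dict(config.get("simulate", {}) or {})
    survey_cfg = dict(config.get("survey", {}) or {})
    if simulate_cfg.pop("enabled", False):
        def stage_simulate():
            known = {f.name for f in dataclasses.fields(synthetic_data.GeneratorConfig)}
            unknown = set(simulate_cfg) - known
            if unknown:
                raise ValueError(f"unknown generator options {sorted(unknown)}")
            gen_config = synthetic_data.GeneratorConfig(**simulate_cfg)
            samples = synthetic_data.generate_survey(
                gen_config, seed=seeds["simulate"], profiles=state["profiles"]
            )
            state["samples"] = samples
            path = out / "survey.csv"
            write_survey(samples, path)
            return {"survey": path}

        run_stage("simulate", stage_simulate)
    else:
        def stage_load():
            path = Path(survey_cfg["path"])
            state["samples"] = read_survey(path, survey_cfg.get("layout", "wide"))
            manifest["inputs"]["survey"] = _digest(path)
            return {}

        run_stage("load_survey", stage_load)

    # --- classify -------------------------------------------------------------
    def stage_classify():
        result = pufa_classes.classify_all(state["profiles"])
        state["classification"] = result
        boundaries_path = out / "class_boundaries.csv"
        pd.DataFrame(
            [dataclasses.asdict(result.boundaries[p]) for p in sorted(result.boundaries)]
        ).to_csv(boundaries_path, index=False)
        classified_path = out / "classified_profiles.csv"
        write_taxon_table(result.profiles, classified_path)
        report_path = out / "class_consistency.csv"
        pd.DataFrame(
            [dataclasses.asdict(m) for m in result.mismatches],
            columns=[f.name for f in dataclasses.fields(pufa_classes.ClassMismatch)],
        ).to_csv(report_path, index=False)
        return {
            "class_boundaries": boundaries_path,
            "classified_profiles": classified_path,
            "class_consistency": report_path,
        }

    run_stage("classify", stage_classify)

    # --- community metrics ----------------------------------------------------
    def stage_metrics():
        metrics_cfg = dict(config.get("metrics", {}) or {})
        responses = community_metrics.responses_for_survey(
            state["samples"],
            state["classification"].profiles,
            fa_score=metrics_cfg.get("fa_score", "class"),
            missing=metrics_cfg.get("missing", "error"),
        )
        state["responses"] = responses
        path = out / "responses.csv"
        write_responses(responses, path)
        return {"responses": path}

    run_stage("metrics", stage_metrics)

    # --- PERMANOVA on per-sample fatty-acid values ------------------------------
    permanova_cfg = dict(config.get("permanova", {}) or {})
    if permanova_cfg.get("enabled", True):
        def stage_permanova():
            fa_table = synthetic_data.generate_fa_samples(
                state["profiles"], seed=seeds["fa_samples"]
            )
            fa_path = out / "fa_samples.csv"
            fa_table.to_csv(fa_path, index=False, float_format="%.10g")
            rows = []
            for pufa in ("ara", "epa", "dha"):
                transformed = permanova_mod.log1_transform(fa_table[pufa].to_numpy())
                result = permanova_mod.one_way_permanova(
                    transformed,
                    fa_table["taxon"].to_numpy(),
                    n_perm=int(permanova_cfg.get("n_perm", 9999)),
                    seed=seeds["permanova"],
                )
                rows.append(
                    {
                        "pufa": pufa,
                        "df_between": result.df_between,
                        "df_within": result.df_within,
                        "ss_between": result.ss_between,
                        "ss_within": result.ss_within,
                        "ms_between": result.ms_between,
                        "ms_within": result.ms_within,
                        "pseudo_f": result.pseudo_f,
                        "p_perm": result.p_perm,
                        "p_mc": result.p_mc,
                        "effect_size": result.effect_size,
                    }
                )
            path = out / "permanova.csv"
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
            return {"fa_samples": fa_path, "permanova": path}

        run_stage("permanova", stage_permanova)

    # --- Bayesian fit / model selection ----------------------------------------
    fit_cfg = dict(config.get("fit", {}) or {})
    if fit_cfg.pop("enabled", False):
        def stage_fit():
            responses_frame = community_metrics.responses_for_survey(
                state["samples"], state["classification"].profiles
            )
            from .data_model import responses_to_frame

            frame = responses_to_frame(responses_frame)
            spec = hier_bayes.ModelSpec(
                response=fit_cfg["response"],
                family=fit_cfg.get("family", "poisson"),
                categorical_terms=tuple(fit_cfg.get("categorical_terms", ())),
                continuous_terms=tuple(fit_cfg.get("continuous_terms", ())),
                shared_lake_variance=fit_cfg.get("shared_lake_variance", False),
            )
            fit_kwargs = {
                key: int(fit_cfg[key])
                for key in ("n_iter", "n_chains", "n_adapt", "burn_in", "thin")
                if key in fit_cfg
            }
            select_cfg = dict(config.get("select", {}) or {})
            outputs: dict[str, Path] = {}
            if select_cfg.get("enabled", False):
                ranking = hier_bayes.select_model(
                    spec,
                    state["samples"],
                    frame,
                    select_cfg.get("candidate_continuous"),
                    select_cfg.get("candidate_categorical", ()),
                    budget=select_cfg.get("budget"),
                    seed=seeds["fit"],
                    **fit_kwargs,
                )
                rank_path = out / "dic_ranking.csv"
                pd.DataFrame(
                    [
                        {
                            "continuous_terms": "+".join(e["continuous_terms"]) or "(none)",
                            "categorical_terms": "+".join(e["categorical_terms"]) or "(none)",
                            "dic": e["dic"],
                            "dbar": e["dbar"],
                            "pd": e["pd"],
                        }
                        for e in ranking.entries
                    ]
                ).to_csv(rank_path, index=False, float_format="%.6g")
                outputs["dic_ranking"] = rank_path
            result = hier_bayes.fit(spec, state["samples"], frame, seed=seeds["fit"], **fit_kwargs)
            summary_path = out / "posterior_summary.csv"
            result.summary().to_csv(summary_path, float_format="%.6g")
            draws_path = out / "draws.csv"
            pd.DataFrame(result.pooled(), columns=result.param_names).to_csv(
                draws_path, index=False, float_format="%.6g"
            )
            dic_path = out / "dic.json"
            dic_path.write_text(
                json.dumps(
                    {"dbar": result.dbar, "pd": result.pd, "dic": result.dic}, indent=2
                )
            )
            outputs.update(
                {"posterior_summary": summary_path, "draws": draws_path, "dic": dic_path}
            )
            return outputs

        run_stage("fit", stage_fit)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
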