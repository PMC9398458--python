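"""End-to-end pipeline: simulate -> calibrate -> DIF scan -> Monte-Carlo
thresholds -> link -> hybrid -> impact -> reference values.

Every stage writes its outputs as delimited or structured text under the
configured output directory, and a run manifest records the effective
configuration, seeds and stage timings so a re-run with the same
configuration reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibrate import fit_grm
from .data import ResponseMatrix
from .dif import DIFScanConfig, iterative_dif_scan, monte_carlo_thresholds
from .grm import eap_scores
from .impact import InstrumentVersion, compare_approaches, default_short_forms
from .linking import build_hybrid, stocking_lord, transform_parameters
from .parameters import ParameterSet
from .quadrature import QuadratureGrid
from .reference import classify_scores, reference_table, severity_thresholds
from .simulate import DIFSpec, SimulationDesign, simulate_two_group_study

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run.

    Either ``responses_path`` points at an existing response CSV, or
    ``simulate`` describes a synthetic study to generate first.
    """

    output_dir: str = "promirt_output"
    responses_path: str | None = None
    parameters_path: str | None = None  # reference-metric parameters, optional
    simulate: dict | None = None  # SimulationDesign fields
    seed: int | None = None
    r2_threshold: float = 0.02
    alpha: float = 0.01
    n_replications: int = 100
    run_monte_carlo: bool = True
    em_tol: float = 1e-3
    em_max_cycles: int = 200
    short_forms: dict[str, list[str]] | None = None
    reference_mean: float = 50.0
    reference_sd: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.responses_path is None and self.simulate is None:
            raise ValueError("config needs either responses_path or a simulate block")
        if self.responses_path is not None and not Path(self.responses_path).exists():
            raise FileNotFoundError(self.responses_path)
        stochastic = self.simulate is not None or self.run_monte_carlo
        if stochastic and self.seed is None:
            raise ValueError("a seed is required when simulation or Monte-Carlo stages run")


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "promirt_version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    grid = QuadratureGrid.normal()

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return result

        return wrap

    # ------------------------------------------------------------ simulate
    truth = None
    if config.simulate is not None:
        def do_simulate():
            sim_kwargs = dict(config.simulate)
            dif_spec = tuple(DIFSpec(**d) for d in sim_kwargs.pop("dif_spec", []))
            design = SimulationDesign(seed=config.seed, dif_spec=dif_spec, **sim_kwargs)
            matrix, tr = simulate_two_group_study(design)
            matrix.to_csv(out / "responses.csv")
            tr.to_json(out / "truth.json")
            return matrix, tr

        responses, truth = stage("simulate")(do_simulate)
    else:
        responses = stage("read")(lambda: ResponseMatrix.from_csv(config.responses_path))

    # ------------------------------------------------------------ calibrate
    def do_calibrate():
        fit = fit_grm(responses, grid=grid, tol=config.em_tol, max_cycles=config.em_max_cycles)
        fit.parameters.to_csv(out / "parameters_pooled.csv")
        return fit

    pooled_fit = stage("calibrate")(do_calibrate)

    if config.parameters_path:
        params_reference = ParameterSet.from_csv(config.parameters_path)
    else:
        params_reference = pooled_fit.parameters.with_metric_tag("reference")

    # ------------------------------------------------------------ dif scan
    def do_dif():
        scan = iterative_dif_scan(
            responses,
            DIFScanConfig(
                r2_threshold=config.r2_threshold,
                alpha=config.alpha,
                em_tol=config.em_tol,
                em_max_cycles=config.em_max_cycles,
                grid=grid,
            ),
            params_reference=params_reference,
        )
        scan.to_frame().to_csv(out / "dif_report.csv", index=False)
        return scan

    scan = stage("dif")(do_dif)
    flagged = sorted(scan.flagged_items)

    # ------------------------------------------------ monte-carlo thresholds
    if config.run_monte_carlo:
        def do_mc():
            groups = responses.groups
            mc = monte_carlo_thresholds(
                params_reference,
                group_sizes=(int((groups == 0).sum()), int((groups == 1).sum())),
                n_replications=config.n_replications,
                alpha=config.alpha,
                seed=config.seed,
                grid=grid,
            )
            (out / "monte_carlo_thresholds.json").write_text(
                json.dumps(
                    {
                        "n_replications": mc.n_replications,
                        "alpha": mc.alpha,
                        "p_thresholds": mc.p_thresholds,
                        "r2_quantiles": mc.r2_quantiles,
                        "seed": mc.seed,
                    },
                    indent=2,
                )
            )
            return mc

        stage("monte_carlo")(do_mc)

    # ------------------------------------------------------- link + hybrid
    def do_link():
        if not flagged:
            return None, params_reference.with_metric_tag("hybrid")
        focal = responses.subset_persons(responses.groups == 1)
        focal_fit = fit_grm(focal, grid=grid, tol=config.em_tol, max_cycles=config.em_max_cycles)
        matching_k = {
            i for i in responses.item_columns
            if focal_fit.parameters[i].n_categories == params_reference[i].n_categories
        }
        anchors = [i for i in responses.item_columns if i not in flagged and i in matching_k]
        replaceable = [i for i in flagged if i in matching_k]
        constants = stocking_lord(focal_fit.parameters, params_reference, anchors)
        rescaled = transform_parameters(focal_fit.parameters, constants, items=replaceable)
        hybrid = build_hybrid(params_reference, rescaled, replaceable)
        (out / "linking_constants.json").write_text(json.dumps(constants.to_dict(), indent=2))
        hybrid.to_csv(out / "parameters_hybrid.csv")
        return constants, hybrid

    _, params_hybrid = stage("link")(do_link)

    # ------------------------------------------------------------- impact
    def do_impact():
        if config.short_forms:
            versions = [InstrumentVersion("full_bank", tuple(responses.item_columns))] + [
                InstrumentVersion(name, tuple(ids)) for name, ids in config.short_forms.items()
            ]
        else:
            versions = default_short_forms(responses.item_columns)
        summaries, per_person = compare_approaches(
            responses, params_reference, params_hybrid, versions, grid
        )
        import pandas as pd

        pd.DataFrame([s.as_row() for s in summaries]).to_csv(out / "impact_summary.csv", index=False)
        per_person.to_csv(out / "impact_per_person.csv", index=False)
        return summaries

    stage("impact")(do_impact)

    # ---------------------------------------------------- reference values
    def do_reference():
        scores = eap_scores(responses, params_reference, grid)
        scores.to_csv(out / "scores.csv")
        table = reference_table(scores, responses.df[["age_bin", "gender"]])
        table.to_csv(out / "reference_table.csv")
        thresholds = severity_thresholds(config.reference_mean, config.reference_sd)
        pct, labels = classify_scores(scores, thresholds)
        (out / "severity.json").write_text(
            json.dumps(
                {
                    "thresholds": {
                        "mild": thresholds.mild,
                        "moderate": thresholds.moderate,
                        "severe": thresholds.severe,
                    },
                    "category_percent": pct,
                },
                indent=2,
            )
        )
        return table

    stage("reference")(do_reference)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
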