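"""Scenario runner and end-to-end pipeline with a reproducible manifest.

Ties the stages together: an oxygen scenario config is built into a stack,
solved, and reduced to the check-point pass/fail table; a spike config
generates (or loads) a session, detects spikes if a trace is present, and
produces PSTH, classification and viability tables.  Every run writes a
manifest (config hash, seed, stage list, outputs, version) so that re-running
with the same manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import SlabProblem
from .mea import default_mea_design, uniform_mea_design
from .params import (
    CheckpointRequirements,
    GeometryParams,
    PhysicalParams,
    geometry_params_from_config,
    henry_tension,
    load_config,
    physical_params_from_config,
    requirements_from_config,
    save_config,
)
from .solver import (
    CheckpointReport,
    ConfigurationError,
    OxygenField,
    axial_profile,
    build_slab_problem,
    build_stack,
    conservation_error,
    extract_checkpoints,
    paper_stack,
    single_mea_stack,
    solve_steady,
)
from .spikes import (
    SpikeTrain,
    StimulusProtocol,
    align_and_bin,
    classify_response,
    detect_spikes,
    rate_timecourse,
    write_spike_table,
)
from .synth import NoiseModel, generate_session, type_i_response, type_iii_response

__all__ = ["ScenarioResult", "RunManifest", "run_scenario", "run_pipeline"]


@dataclass
class ScenarioResult:
    name: str
    field: OxygenField
    report: CheckpointReport | None
    conservation: float


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, str]
    version: str = __version__

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_scenario(cfg: dict) -> ScenarioResult:
    """Build, solve and post-process one oxygen scenario config."""
    phys = physical_params_from_config(cfg)
    geom = geometry_params_from_config(cfg)
    reqs = requirements_from_config(cfg)
    inlet = henry_tension(cfg.get("inlet_o2_mg_per_l", 18.0) / 1000.0, phys.k_h)
    stack_kind = cfg.get("stack", "mtm")
    name = cfg.get("scenario", stack_kind)

    if stack_kind == "slab":
        slab = SlabProblem(
            length_cm=cfg.get("slab_length_um", 170.0) * 1e-4,
            p_left=cfg.get("slab_p_left_mmHg", 100.0),
            p_right=cfg.get("slab_p_right_mmHg", 100.0),
            q=cfg.get("slab_q_ml_per_100g_min", phys.q_nr),
            dk=phys.dk,
        )
        problem = build_slab_problem(slab, n_cells=int(cfg.get("slab_n_cells", 400)))
        field = solve_steady(problem)
        return ScenarioResult(name, field, None, conservation_error(field))

    if stack_kind == "mtm":
        stack = paper_stack(geom)
        n_mea = 2
    elif stack_kind == "single_mea":
        stack = single_mea_stack(geom)
        n_mea = 1
    else:
        raise ConfigurationError(f"unknown stack kind {stack_kind!r}")

    if cfg.get("mea_design", "default") == "uniform":
        design = uniform_mea_design(
            cfg["mea_uniform_oar"],
            window_diameter_mm=geom.window_diameter_mm,
            thickness_um=geom.mea_thickness_um,
        )
    else:
        design = default_mea_design(
            window_diameter_mm=geom.window_diameter_mm,
            thickness_um=geom.mea_thickness_um,
        )
    problem = build_stack(
        stack,
        [design] * n_mea,
        phys,
        inlet_tension=inlet,
        fluid_model=cfg.get("fluid_model", "film"),
        film_thickness_cm=cfg.get("film_thickness_mm", 0.3) * 0.1,
        grid_refine=float(cfg.get("grid_refine", 1.0)),
    )
    field = solve_steady(problem)
    report = extract_checkpoints(field, reqs)
    return ScenarioResult(name, field, report, conservation_error(field))


def _run_oxygen_stage(cfg: dict, out: Path, outputs: dict[str, str]) -> None:
    result = run_scenario(cfg)
    profile_path = out / f"{result.name}_profile.tsv"
    axial_profile(result.field).to_csv(profile_path, sep="\t", index=False)
    outputs["oxygen_profile"] = str(profile_path)
    if result.report is not None:
        report_path = out / f"{result.name}_checkpoints.tsv"
        result.report.to_frame().to_csv(report_path, sep="\t", index=False)
        outputs["checkpoint_report"] = str(report_path)


def _run_spike_stage(cfg: dict, out: Path, seed: int, outputs: dict[str, str]) -> None:
    cell_type = cfg.get("spike_cell_type", "III")
    response = (
        type_iii_response() if cell_type == "III" else type_i_response()
    )
    if cfg.get("spike_decline_onset_min") is not None:
        from dataclasses import replace

        response = replace(
            response,
            decline_onset_min=float(cfg["spike_decline_onset_min"]),
            decline_tau_min=float(cfg.get("spike_decline_tau_min", 5.0)),
        )
    protocol = StimulusProtocol(n_blocks=int(cfg.get("spike_n_blocks", 2)))
    noise = NoiseModel(seed=seed)
    render = bool(cfg.get("spike_render_trace", False))
    train, trace = generate_session(
        response, protocol, noise, seed=seed, render=render
    )
    if trace is not None:
        detected = detect_spikes(trace, noise.sampling_rate_khz)
        train_used = detected
    else:
        train_used = train

    spikes_path = out / "spikes.tsv"
    write_spike_table([train_used], spikes_path)
    outputs["spike_table"] = str(spikes_path)

    psth, _ = align_and_bin(train_used, protocol)
    psth_path = out / "psth.tsv"
    psth.to_frame().to_csv(psth_path, sep="\t", index=False)
    outputs["psth"] = str(psth_path)
    outputs["response_type"] = classify_response(psth)

    if protocol.n_blocks >= 2:
        tc = rate_timecourse(train_used, protocol)
        tc_path = out / "timecourse.tsv"
        tc.to_frame().to_csv(tc_path, sep="\t", index=False)
        outputs["timecourse"] = str(tc_path)
        outputs["decline_onset_min"] = (
            "none" if tc.decline_onset_min is None else f"{tc.decline_onset_min:g}"
        )


def run_pipeline(
    config: dict | str | Path, out_dir: str | Path, seed: int = 0
) -> RunManifest:
    """Execute the configured stages and write tables + manifest.

    ``config`` may be a flat dict or a path to a YAML config.  Stage toggles:
    ``run_oxygen`` (default true) and ``run_spikes`` (default true).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages: list[str] = []
    outputs: dict[str, str] = {}
    if cfg.get("run_oxygen", True):
        stages.append("oxygen")
        try:
            _run_oxygen_stage(cfg, out, outputs)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(f"stage 'oxygen' failed: {exc}") from exc
    if cfg.get("run_spikes", True):
        stages.append("spikes")
        try:
            _run_spike_stage(cfg, out, seed, outputs)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'spikes' failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=_config_hash(cfg), seed=seed, stages=stages, outputs=outputs
    )
    manifest.write(out / "manifest.json")
    return manifest
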