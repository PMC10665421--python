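"""End-to-end orchestration of the in silico trial experiment.

One run executes population synthesis -> landmark loads -> surrogate gap
mechanics -> strain invariants -> descriptive summaries -> correlation
battery, writes plain-text outputs (CSV/JSON) and a run manifest whose
record counts make the bookkeeping auditable: with the defaults, 300
avatars times 5 stance-phase landmarks give exactly 1500 simulation
records.

All randomness flows from the single master seed via named streams, so a
rerun with the same config produces byte-identical CSV files.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import stream
from .config import PipelineConfig
from .gait_loads import LANDMARKS, load_landmark_table, scale_loads
from .population import generate_population
from .strain_invariants import invariant_table
from .summary_stats import SUMMARY_FIELDS, correlation_battery, summarize_field
from .surrogate_mechanics import (
    build_mesh,
    cell_strain_field,
    gap_kinematics,
    section_properties,
    strain_tensors,
)

__all__ = [
    "RunManifest",
    "ExperimentResults",
    "run_pipeline",
    "run_experiment",
    "simulate_avatars",
    "cohort_correlations",
]

logger = logging.getLogger("fractrial")


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config_hash: str
    master_seed: int
    n_avatars: int
    landmarks: list[str]
    record_counts: dict[str, int] = field(default_factory=dict)
    started_utc: str = ""
    finished_utc: str = ""
    version: str = __version__

    @property
    def simulation_records(self) -> int:
        return self.record_counts.get("simulations", 0)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "n_avatars": self.n_avatars,
            "landmarks": self.landmarks,
            "record_counts": self.record_counts,
            "simulation_records": self.simulation_records,
            "started_utc": self.started_utc,
            "finished_utc": self.finished_utc,
            "version": self.version,
        }


def _write_atomic(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def simulate_avatars(
    config: PipelineConfig,
    avatars: pd.DataFrame,
    collect_fields: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Run the surrogate mechanics for every avatar at every landmark.

    Returns (loads table, invariant summaries, optional cell-level fields).
    Summaries hold one row per avatar x landmark x region x invariant with
    the six descriptive statistics.
    """
    base_loads = load_landmark_table(config.loads)
    load_rows = []
    summary_rows = []
    field_frames = [] if collect_fields else None
    for row in avatars.itertuples(index=False):
        geom = config.geometry.model_copy(update={"tibia_length": float(row.tibia_length_mm)})
        stiff = section_properties(geom, config.materials)
        mesh = build_mesh(geom)
        scaled = scale_loads(base_loads, row.weight_kg)
        for lm in LANDMARKS:
            force, moment = scaled[lm]
            load_rows.append((row.id, lm, *force, *moment))
            motion = gap_kinematics(force, moment, stiff)
            cells = cell_strain_field(motion, geom, config.materials, mesh)
            invariants = invariant_table(strain_tensors(cells))
            region = cells["region"].to_numpy()
            for reg in ("gap", "callus"):
                mask = region == reg
                for quantity, vals in invariants.items():
                    summary_rows.append(
                        (row.id, lm, reg, quantity, *summarize_field(vals[mask]).values())
                    )
            if collect_fields:
                cells = cells.assign(avatar_id=row.id, landmark=lm, **invariants)
                field_frames.append(cells)
    loads = pd.DataFrame(
        load_rows,
        columns=["avatar_id", "landmark", "Fx_N", "Fy_N", "Fz_N", "Mx_Nm", "My_Nm", "Mz_Nm"],
    )
    summaries = pd.DataFrame(
        summary_rows,
        columns=["avatar_id", "landmark", "region", "quantity", *SUMMARY_FIELDS],
    )
    fields = pd.concat(field_frames, ignore_index=True) if collect_fields else None
    return loads, summaries, fields


@dataclass
class ExperimentResults:
    """In-memory outputs of one full run."""

    manifest: RunManifest
    avatars: pd.DataFrame
    loads: pd.DataFrame
    summaries: pd.DataFrame
    correlations: pd.DataFrame
    fields: pd.DataFrame | None = None


def run_experiment(config: PipelineConfig, out_dir: str | Path | None = None) -> ExperimentResults:
    """Execute the full experiment; optionally write all outputs.

    With ``out_dir`` set, writes ``avatars.csv``, ``loads.csv``,
    ``strain_summary.csv``, ``correlations.csv``, optionally
    ``strain_field.csv``, and ``manifest.json`` (atomically, at run end).
    """
    manifest = RunManifest(
        config_hash=config.content_hash(),
        master_seed=config.seed,
        n_avatars=config.n_avatars,
        landmarks=list(LANDMARKS),
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    stage = "population"
    try:
        rng = stream(config.seed, "population")
        avatars = generate_population(config.population, config.n_avatars, rng=rng)
        manifest.record_counts["avatars"] = len(avatars)
        logger.info("population: %d avatars", len(avatars))

        stage = "mechanics"
        loads, summaries, fields = simulate_avatars(
            config, avatars, collect_fields=config.export_strain_field
        )
        n_sim = len(avatars) * len(LANDMARKS)
        manifest.record_counts["loads"] = len(loads)
        manifest.record_counts["simulations"] = n_sim
        manifest.record_counts["summaries"] = len(summaries)
        logger.info("mechanics: %d simulations, %d summary rows", n_sim, len(summaries))

        stage = "correlation"
        if len(avatars) >= 3:
            correlations = correlation_battery(summaries, avatars)
        else:
            # Pearson needs n >= 3; tiny runs still produce the mechanics outputs
            correlations = pd.DataFrame(
                columns=["parameter", "landmark", "region", "quantity", "r", "p", "n", "significant"]
            )
            logger.warning("fewer than 3 avatars: correlation battery skipped")
        manifest.record_counts["correlations"] = len(correlations)
        logger.info("correlation battery: %d rows", len(correlations))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        avatars.to_csv(out / "avatars.csv", index=False)
        loads.to_csv(out / "loads.csv", index=False)
        summaries.to_csv(out / "strain_summary.csv", index=False)
        correlations.to_csv(out / "correlations.csv", index=False)
        if fields is not None:
            fields.to_csv(out / "strain_field.csv", index=False)
        manifest.finished_utc = datetime.now(timezone.utc).isoformat()
        _write_atomic(out / "manifest.json", json.dumps(manifest.to_dict(), indent=2))
    else:
        manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    return ExperimentResults(
        manifest=manifest,
        avatars=avatars,
        loads=loads,
        summaries=summaries,
        correlations=correlations,
        fields=fields,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full experiment, write outputs, return the manifest."""
    return run_experiment(config, out_dir).manifest


def cohort_correlations(
    summaries: pd.DataFrame,
    population: pd.DataFrame,
    cohort_ids,
    statistic: str = "median",
) -> pd.DataFrame:
    """Correlation battery restricted to one cohort (Algorithm A follow-up)."""
    ids = set(int(i) for i in cohort_ids)
    sub_pop = population[population["id"].isin(ids)]
    sub_sum = summaries[summaries["avatar_id"].isin(ids)]
    return correlation_battery(sub_sum, sub_pop, statistic=statistic)
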