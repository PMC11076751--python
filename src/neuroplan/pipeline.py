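"""End-to-end workflow: phantom -> cohort -> metrics -> comparison.

Thin orchestration over the library modules; the CLI and the numbered
analysis scripts both call these functions so that every pathway produces
identical, seed-reproducible artifacts.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as npio
from . import metrics as npmetrics
from . import phantom as npphantom
from . import stats as npstats
from .io import RunConfig, config_hash

__all__ = ["build_phantom_artifacts", "simulate_cohort_artifacts", "assess_annotations", "run_report"]


def _write_meta(outdir: Path, config: RunConfig, stage: str) -> None:
    import neuroplan

    meta = {
        "stage": stage,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config_hash(config),
        "versions": {"neuroplan": neuroplan.__version__, "python": platform.python_version()},
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def build_phantom_artifacts(outdir, config: RunConfig = RunConfig()) -> npphantom.PhantomModel:
    """Build the default phantom; write meshes (STL + PLY) and the label volume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = npphantom.PhantomSpec(voxel_pitch=config.voxel_pitch_mm)
    model = npphantom.build_phantom(spec)
    for name, mesh in (("scalp", model.scalp_mesh), ("skull", model.skull_mesh), ("tumor", model.tumor_mesh)):
        npio.write_mesh(mesh, outdir / f"{name}.stl")
        npio.write_mesh(mesh, outdir / f"{name}.ply")
    npio.write_volume(npphantom.voxelize(spec), outdir / "labels.nii.gz")
    _write_meta(outdir, config, "phantom")
    return model


def simulate_cohort_artifacts(
    model: npphantom.PhantomModel, outdir, config: RunConfig = RunConfig()
) -> list:
    """Simulate the cohort and write one annotation JSON per drawing set."""
    outdir = Path(outdir)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)
    cohort = npphantom.default_cohort_spec(
        model, seed=config.seed, n_residents=config.n_residents, n_interns=config.n_interns
    )
    records = npphantom.simulate_cohort(model, cohort)
    manifest = []
    for rec in records:
        for ann in (rec.pre, rec.post):
            fname = f"{rec.participant_id}_{ann.assessment}.json"
            npio.write_annotation(ann, outdir / "annotations" / fname)
            manifest.append(
                {
                    "participant_id": rec.participant_id,
                    "group": rec.group,
                    "assessment": ann.assessment,
                    "substream_seed": rec.substream_seed,
                    "file": f"annotations/{fname}",
                }
            )
    npio.write_table(pd.DataFrame(manifest), outdir / "cohort.csv", config)
    _write_meta(outdir, config, "simulate")
    return records


def assess_annotations(
    model: npphantom.PhantomModel, records, outdir, config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Score a cohort and write the per-participant metric table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = npmetrics.assess_cohort(
        records,
        model,
        standard_margin=config.standard_margin_mm,
        convention=config.margin_convention,
    )
    npio.write_table(table, outdir / "metrics.csv", config, units="see column suffixes (mm, mm2, pct, points)")
    return table


def compare_metrics(table: pd.DataFrame):
    """Cohort-level comparison table plus the resident/intern incision stratification."""
    comparison = npstats.compare_table(table)
    strata = npstats.stratified_compare(table, "incision_deviation_mm")
    strata_rows = [
        {
            "group": g,
            "n": r.n,
            "AA1": str(r.summary_aa1),
            "AA2": str(r.summary_aa2),
            "test": r.test,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for g, r in strata.items()
    ]
    return comparison, pd.DataFrame(strata_rows)


def _report_text(comparison: pd.DataFrame, strata: pd.DataFrame, config: RunConfig) -> str:
    lines = [
        "neuroplan planning-accuracy report",
        f"seed={config.seed} config_hash={config_hash(config)}",
        "",
        "Paired AA1 (post-MRI) vs AA2 (post-3D-model) comparison:",
        comparison.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        "",
        "Linear-incision deviation by group:",
        strata.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        "",
        "Note: no multiple-testing correction applied across metrics.",
    ]
    return "\n".join(lines) + "\n"


def run_report(outdir, config: RunConfig = RunConfig()) -> dict:
    """Full pipeline under one seed; bit-reproducible for a fixed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_phantom_artifacts(outdir / "phantom", config)
    records = simulate_cohort_artifacts(model, outdir, config)
    table = assess_annotations(model, records, outdir, config)
    comparison, strata = compare_metrics(table)
    npio.write_table(comparison, outdir / "comparison.csv", config)
    npio.write_table(strata, outdir / "incision_by_group.csv", config)
    (outdir / "report.txt").write_text(_report_text(comparison, strata, config))
    _write_meta(outdir, config, "report")
    return {"model": model, "records": records, "metrics": table, "comparison": comparison, "strata": strata}
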