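"""Result-file writing with a replayable manifest.

Every run directory carries a ``manifest.json`` listing the files
written, the seeds used, a hash of the resolved configuration and the
package version, so that any output can be regenerated from config +
master seed alone.  CSV dialect: comma-separated, dot decimal, header
row, UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .pk import ConcentrationSeries, DoseSchedule
from .trial import CaseResult, CohortResult

__all__ = ["write_outputs", "write_case_outputs", "write_cohort_outputs"]


def _write_one(name: str, artifact: Any, outdir: Path) -> str:
    if isinstance(artifact, pd.DataFrame):
        path = outdir / f"{name}.csv"
        artifact.to_csv(path, index=False, float_format="%.6f")
    elif isinstance(artifact, (DoseSchedule, ConcentrationSeries)):
        path = outdir / f"{name}.csv"
        artifact.to_csv(path)
    elif isinstance(artifact, Mapping):
        path = outdir / f"{name}.json"
        path.write_text(json.dumps(artifact, indent=2, sort_keys=True, default=float))
    else:
        raise TypeError(f"cannot serialise artifact {name!r} of type {type(artifact)}")
    return path.name


def write_outputs(
    artifacts: Mapping[str, Any],
    outdir: str | Path,
    config: RunConfig | None = None,
    seeds: list[int] | None = None,
) -> dict[str, Any]:
    """Write named artifacts into ``outdir`` and return the manifest.

    DataFrames, dose schedules and concentration series become CSV files;
    mappings become JSON.  The manifest (also written as
    ``manifest.json``) lists files, seeds, config hash and version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = [_write_one(name, art, outdir) for name, art in artifacts.items()]
    manifest: dict[str, Any] = {
        "files": sorted(files),
        "seeds": seeds or [],
        "config_hash": config_hash(config) if config is not None else None,
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def write_case_outputs(
    case: CaseResult, outdir: str | Path, config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    artifacts: dict[str, Any] = {
        "dose_schedule": case.schedule,
        "twitch": case.twitch,
        "controller_events": case.controller_log,
        "sampling_records": case.records_frame(),
        "case_summary": {
            "events": case.events,
            "flags": case.flags,
            "induction_dose_mg": case.induction_dose_mg,
            "in_band_fraction": case.in_band_fraction,
            "recovery_time_min": case.recovery_time_min,
            "sugammadex_doses_mg": case.sugammadex_doses_mg,
        },
    }
    if case.series_nominal is not None:
        artifacts["concentrations_predicted"] = case.series_nominal
        artifacts["concentrations_true"] = case.series_true
    return write_outputs(artifacts, outdir, config,
                         seeds=[seed] if seed is not None else [])


def write_cohort_outputs(
    cohort: CohortResult, outdir: str | Path, config: RunConfig | None = None
) -> dict[str, Any]:
    return write_outputs(
        {
            "sampling_records": cohort.records,
            "metrics": cohort.metrics,
            "patients": cohort.patients,
        },
        outdir,
        config,
        seeds=[cohort.master_seed],
    )
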