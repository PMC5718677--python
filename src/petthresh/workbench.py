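"""End-to-end calibration workflow: simulate -> calibrate -> fit -> report.

The workflow reproduces the full phantom protocol in software: one
simulated acquisition per (TB ratio, reconstruction scheme) pair, optimal
thresholds per sphere, split-model fits (per scheme and pooled), ANCOVA
over the reconstruction factors, and the cross-validation shrinkage of the
pooled models.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .calibration import (
    CalibrationResult,
    SearchSettings,
    ThresholdRecord,
    calibrate_scheme,
    records_to_frame,
)
from .phantom import (
    GroundTruth,
    ImageVolume,
    PhantomSpec,
    default_iec_spec,
    simulate_phantom,
)
from .regression import (
    AncovaTable,
    DesignError,
    ModelPair,
    SplitModels,
    ThresholdModel,
    ancova,
    fit_split_models,
    shrinkage_cross_validation,
)

logger = logging.getLogger("petthresh")

__all__ = ["RunConfig", "WorkflowError", "WorkflowResult", "run_calibration_workflow", "round_trip"]


class WorkflowError(RuntimeError):
    """A workflow stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one calibration run.

    ``schemes`` lists (EM-equivalent iterations, smoothing FWHM mm) pairs;
    ``tb_ratios`` are the prepared source-to-background ratios, one
    simulated acquisition each.
    """

    out_dir: str | Path
    tb_ratios: tuple[float, ...] = (2.5, 4.2, 8.1, 16.6, 35.0, 70.0)
    schemes: tuple[tuple[int, float], ...] = ((16, 4.0), (16, 6.0), (16, 8.0))
    sphere_diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    noise_sd_fraction: float = 0.05
    seed: int = 0
    settings: SearchSettings = field(default_factory=SearchSettings)
    include_validation: bool = False
    supersampling: int = 8

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("scheme list must be non-empty")
        if not self.tb_ratios:
            raise ValueError("tb_ratios must be non-empty")


@dataclass
class WorkflowResult:
    records: list[ThresholdRecord]
    models: SplitModels
    ancova_table: AncovaTable | None
    shrinkage: dict[str, float]
    failures: list
    paths: dict[str, Path]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-acquisition child seeds (< 2**31) from one master
    seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_calibration_workflow(config: RunConfig) -> WorkflowResult:
    """Run the full simulated calibration and write records.csv,
    models.json and report.json into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_acq = len(config.schemes) * len(config.tb_ratios)
    seeds = derive_seeds(config.seed, n_acq)
    logger.info(
        "calibration run: seed=%d, %d schemes x %d TB ratios, settings=%s",
        config.seed, len(config.schemes), len(config.tb_ratios), config.settings,
    )

    records: list[ThresholdRecord] = []
    failures: list = []
    k = 0
    for iterations, fwhm in config.schemes:
        images: list[tuple[ImageVolume, GroundTruth]] = []
        for tb in config.tb_ratios:
            spec = default_iec_spec(
                tb,
                smoothing_fwhm=fwhm,
                iteration_label=iterations,
                noise_sd_fraction=config.noise_sd_fraction,
                seed=seeds[k],
                sphere_diameters=config.sphere_diameters,
            )
            k += 1
            try:
                images.append(simulate_phantom(spec, supersampling=config.supersampling))
            except Exception as err:
                raise WorkflowError(
                    f"simulate (scheme {iterations}it/{fwhm}mm, TB={tb}): {err}"
                ) from err
        try:
            result = calibrate_scheme(
                images, (iterations, fwhm), config.settings,
                include_validation=config.include_validation,
            )
        except Exception as err:
            raise WorkflowError(f"calibrate (scheme {iterations}it/{fwhm}mm): {err}") from err
        records.extend(result.records)
        failures.extend(result.failures)

    try:
        models = fit_split_models(records)
    except Exception as err:
        raise WorkflowError(f"fit: {err}") from err

    table: AncovaTable | None = None
    n_fwhm = len({s[1] for s in config.schemes})
    n_iter = len({s[0] for s in config.schemes})
    if n_fwhm >= 2 and n_iter >= 2:
        try:
            table = ancova(records)
        except DesignError as err:
            logger.warning("ancova skipped: %s", err)

    shrinkage: dict[str, float] = {}
    validation = [r for r in records if r.role == "validation"]
    if len(validation) >= 3:
        shrinkage["pooled_large"] = shrinkage_cross_validation(models.pooled.large, validation)

    paths = {
        "records": out / "records.csv",
        "models": out / "models.json",
        "report": out / "report.json",
    }
    io.save_records(records, paths["records"])
    io.save_models(models, paths["models"])
    report = {
        "seed": config.seed,
        "settings": dataclasses.asdict(config.settings),
        "n_records": len(records),
        "n_failures": len(failures),
        "pooled_small": models.pooled.small.coefficients,
        "pooled_small_r2_adj": models.pooled.small.r2_adj,
        "pooled_large": models.pooled.large.coefficients,
        "pooled_large_r2_adj": models.pooled.large.r2_adj,
        "shrinkage": shrinkage,
    }
    if table is not None:
        report["ancova"] = table.to_frame().to_dict(orient="records")
    io.atomic_write_text(paths["report"], json.dumps(report, indent=2))
    logger.info("calibration complete: %d records, %d failures", len(records), len(failures))
    return WorkflowResult(records, models, table, shrinkage, failures, paths)


def round_trip(obj, path: str | Path | None = None):
    """Write an object to disk and read it back (volumes as NIfTI, record
    tables as CSV, models/specs as JSON); returns the reloaded object."""
    cleanup = path is None
    if path is None:
        suffix = ".nii" if isinstance(obj, ImageVolume) else ".json"
        if isinstance(obj, (list, CalibrationResult)):
            suffix = ".csv"
        fd = tempfile.NamedTemporaryFile(suffix=suffix, delete=False)
        fd.close()
        path = fd.name
    try:
        if isinstance(obj, ImageVolume):
            io.save_volume(obj, path)
            return io.load_volume(path)
        if isinstance(obj, PhantomSpec):
            io.save_spec(obj, path)
            return io.load_spec(path)
        if isinstance(obj, (ThresholdModel, ModelPair, SplitModels)):
            io.save_models(obj, path)
            return io.load_models(path)
        if isinstance(obj, CalibrationResult):
            io.save_records(obj.records, path)
            return io.load_records(path)
        if isinstance(obj, list) and all(isinstance(r, ThresholdRecord) for r in obj):
            io.save_records(obj, path)
            return io.load_records(path)
        raise TypeError(f"round_trip does not support {type(obj).__name__}")
    finally:
        if cleanup:
            Path(path).unlink(missing_ok=True)
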