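"""End-to-end orchestration: config -> segment -> volumetrics -> field -> dose -> report.

The pipeline consumes a YAML config describing either a pair of real
NIfTI volumes plus seed points, or a synthetic phantom recipe; it runs
the analysis chain and writes masks, a |B| field map, CSV reports and a
run manifest into the output directory.  Identical config + seed yields
byte-identical CSV outputs.

Coordinate convention: the coil center sits at ``coil.center_mm`` in
image coordinates with the coil axis along image +z (pointing into the
volume).  By default the coil is centered in-plane on the pre-treatment
lesion centroid and its plane sits ``standoff_mm`` outside the grid's
z = 0 face, i.e. as close to the head surface as the standoff allows,
with the lesion on the coil axis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .coil import CoilGeometry, field_magnitude_volume, make_rect_coil, warp_coil
from .dosimetry import check_biological_threshold, summarize_dose
from .errors import ConfigError, StageError
from .grids import ImageVolume, LesionMask
from .phantom import HeadModel, PhantomSpec, make_cohort_fixture, make_phantom_pair
from .segmentation import SeedPoint, lesion_volume, per_slice_areas, region_grow
from .volumetrics import (PatientRecord, VISITS, group_summary, summarize_cohort,
                          volumetric_endpoints)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_KNOWN_TOP = {"schema", "phantom", "inputs", "seeds", "segmentation", "coil",
              "dose", "output_dir", "rng_seed", "patient_id", "stim_minutes"}
_KNOWN_SEG = {"rel_threshold", "connectivity", "mode", "band"}
_KNOWN_COIL = {"width_m", "height_m", "current_A", "n_segments",
               "curvature_radius_mm", "standoff_mm", "center_mm"}
_KNOWN_DOSE = {"threshold_mT"}
_KNOWN_SEEDS = {"units", "dwi", "flair"}
_KNOWN_INPUTS = {"dwi", "flair"}
_KNOWN_PHANTOM = {"pre", "post"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    output_dir: Path
    rng_seed: int = 0
    # exactly one input source
    phantom_pre: Optional[PhantomSpec] = None
    phantom_post: Optional[PhantomSpec] = None
    dwi_path: Optional[Path] = None
    flair_path: Optional[Path] = None
    seeds_dwi: tuple = ()
    seeds_flair: tuple = ()
    seed_units: str = "index"
    # segmentation
    rel_threshold: float = 0.20
    connectivity: int = 8
    seg_mode: str = "2d_propagate"
    band: str = "symmetric"
    # coil
    coil_width_m: float = 0.14
    coil_height_m: float = 0.106
    current_A: float = 240.0
    n_segments: int = 4
    curvature_radius_mm: Optional[float] = None
    standoff_mm: float = 2.0
    coil_center_mm: Optional[tuple[float, float, float]] = None
    # dose
    threshold_mT: float = 1.0
    patient_id: int = 1
    stim_minutes: int = 45

    @property
    def is_phantom(self) -> bool:
        return self.phantom_pre is not None


def _reject_unknown(block: dict, known: set, where: str) -> None:
    unknown = sorted(set(block) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")


def validate_config(raw, base_dir: Path | None = None) -> PipelineConfig:
    """Validate a raw config (dict, YAML text, or path) and fill defaults."""
    if isinstance(raw, (str, Path)) and Path(str(raw)).exists():
        base_dir = base_dir or Path(str(raw)).parent
        raw = yaml.safe_load(Path(str(raw)).read_text())
    elif isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()

    _reject_unknown(raw, _KNOWN_TOP, "config")
    schema = raw.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {schema} (expected {SCHEMA_VERSION})")

    phantom_block = raw.get("phantom")
    inputs_block = raw.get("inputs")
    if (phantom_block is None) == (inputs_block is None):
        raise ConfigError("exactly one of 'phantom' and 'inputs' must be present")

    rng_seed = int(raw.get("rng_seed", 0))
    kw: dict = {"output_dir": Path(raw.get("output_dir", "out")), "rng_seed": rng_seed}

    if phantom_block is not None:
        _reject_unknown(phantom_block, _KNOWN_PHANTOM, "phantom")
        pre = dict(phantom_block.get("pre") or {})
        post = dict(phantom_block.get("post") or {})
        pre.setdefault("rng_seed", rng_seed)
        post.setdefault("rng_seed", rng_seed + 1)
        # post inherits the pre grid geometry unless stated
        for key in ("grid_shape", "spacing_mm"):
            if key in pre and key not in post:
                post[key] = pre[key]
        try:
            kw["phantom_pre"] = PhantomSpec(**pre)
            kw["phantom_post"] = PhantomSpec(**post)
        except TypeError as err:
            raise ConfigError(f"bad phantom spec: {err}") from None
    else:
        _reject_unknown(inputs_block, _KNOWN_INPUTS, "inputs")
        for key in _KNOWN_INPUTS:
            if key not in inputs_block:
                raise ConfigError(f"inputs.{key} is required")
            path = (base_dir / inputs_block[key]).resolve()
            if not path.exists():
                raise ConfigError(f"inputs.{key}: path not found: {path}")
            kw[f"{key}_path"] = path
        seeds_block = raw.get("seeds")
        if not seeds_block or not seeds_block.get("dwi") or not seeds_block.get("flair"):
            raise ConfigError("real inputs require seeds for both dwi and flair")

    seeds_block = raw.get("seeds") or {}
    _reject_unknown(seeds_block, _KNOWN_SEEDS, "seeds")
    kw["seed_units"] = seeds_block.get("units", "index")
    if kw["seed_units"] not in ("index", "mm"):
        raise ConfigError("seeds.units must be 'index' or 'mm'")
    kw["seeds_dwi"] = tuple(tuple(s) for s in (seeds_block.get("dwi") or ()))
    kw["seeds_flair"] = tuple(tuple(s) for s in (seeds_block.get("flair") or ()))

    seg = raw.get("segmentation") or {}
    _reject_unknown(seg, _KNOWN_SEG, "segmentation")
    kw["rel_threshold"] = float(seg.get("rel_threshold", 0.20))
    kw["connectivity"] = int(seg.get("connectivity", 8))
    kw["seg_mode"] = seg.get("mode", "2d_propagate")
    kw["band"] = seg.get("band", "symmetric")
    if not 0 < kw["rel_threshold"] < 1:
        raise ConfigError("segmentation.rel_threshold must be in (0, 1)")

    coil = raw.get("coil") or {}
    _reject_unknown(coil, _KNOWN_COIL, "coil")
    kw["coil_width_m"] = float(coil.get("width_m", 0.14))
    kw["coil_height_m"] = float(coil.get("height_m", 0.106))
    kw["current_A"] = float(coil.get("current_A", 240.0))
    kw["n_segments"] = int(coil.get("n_segments", 4))
    radius = coil.get("curvature_radius_mm")
    kw["curvature_radius_mm"] = None if radius is None else float(radius)
    kw["standoff_mm"] = float(coil.get("standoff_mm", 2.0))
    center = coil.get("center_mm")
    kw["coil_center_mm"] = None if center is None else tuple(float(c) for c in center)
    if kw["current_A"] <= 0:
        raise ConfigError("coil.current_A must be positive")
    if kw["coil_width_m"] <= 0 or kw["coil_height_m"] <= 0:
        raise ConfigError("coil dimensions must be positive")
    if kw["standoff_mm"] < 0:
        raise ConfigError("coil.standoff_mm must be >= 0")

    dose = raw.get("dose") or {}
    _reject_unknown(dose, _KNOWN_DOSE, "dose")
    kw["threshold_mT"] = float(dose.get("threshold_mT", 1.0))
    kw["patient_id"] = int(raw.get("patient_id", 1))
    kw["stim_minutes"] = int(raw.get("stim_minutes", 45))
    return PipelineConfig(**kw)


def _seed_indices(seeds, units: str, volume: ImageVolume) -> list[SeedPoint]:
    out = []
    for s in seeds:
        if units == "mm":
            idx = tuple(int(round((c - o) / sp)) for c, o, sp
                        in zip(s, volume.origin_mm, volume.spacing_mm))
        else:
            idx = tuple(int(v) for v in s)
        out.append(SeedPoint(idx))
    return out


def _build_coil(config: PipelineConfig) -> CoilGeometry:
    n_seg = config.n_segments
    if config.curvature_radius_mm is not None and n_seg < 400:
        n_seg = 720  # fine discretization so the warp stays arc-length true
    coil = make_rect_coil(config.coil_width_m, config.coil_height_m,
                          config.current_A, n_seg)
    if config.curvature_radius_mm is not None:
        coil = warp_coil(coil, HeadModel(curvature_radius_mm=config.curvature_radius_mm))
    return coil


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    for key, val in echo.items():
        if isinstance(val, Path):
            echo[key] = str(val)
    if config.phantom_pre is not None:
        echo["phantom_pre"] = asdict(config.phantom_pre)
        echo["phantom_post"] = asdict(config.phantom_post)
    return echo


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the artifact paths.

    Any stage failure raises :class:`StageError` naming the stage, after
    removing the partial outputs written so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict[str, Path] = {}
    stage_log: list[dict] = []

    def _write(name: str, path: Path) -> Path:
        written.append(path)
        artifacts[name] = path
        return path

    def _run_stage(name, func):
        t0 = time.perf_counter()
        try:
            result = func()
        except Exception as err:
            for path in written:
                path.unlink(missing_ok=True)
            raise StageError(name, str(err)) from err
        elapsed = time.perf_counter() - t0
        logger.info("stage=%s elapsed_s=%.3f", name, elapsed)
        stage_log.append({"stage": name, "elapsed_s": round(elapsed, 3)})
        return result

    # --- inputs ---------------------------------------------------------
    def _stage_inputs():
        if config.is_phantom:
            dwi, flair, truth_pre, truth_post = make_phantom_pair(
                config.phantom_pre, config.phantom_post)
            dwi.save(_write("dwi", out / "dwi.nii"))
            flair.save(_write("flair", out / "flair.nii"))
            truth_pre.save(_write("truth_pre", out / "truth_pre_mask.nii"))
            truth_post.save(_write("truth_post", out / "truth_post_mask.nii"))
            seeds_dwi = (_seed_indices(config.seeds_dwi, config.seed_units, dwi)
                         or [SeedPoint(config.phantom_pre.lesion_center_index)])
            seeds_flair = (_seed_indices(config.seeds_flair, config.seed_units, flair)
                           or [SeedPoint(config.phantom_post.lesion_center_index)])
        else:
            dwi = ImageVolume.load(config.dwi_path, modality="dwi")
            flair = ImageVolume.load(config.flair_path, modality="flair")
            seeds_dwi = _seed_indices(config.seeds_dwi, config.seed_units, dwi)
            seeds_flair = _seed_indices(config.seeds_flair, config.seed_units, flair)
        return dwi, flair, seeds_dwi, seeds_flair

    dwi, flair, seeds_dwi, seeds_flair = _run_stage("inputs", _stage_inputs)

    # --- segmentation ---------------------------------------------------
    def _stage_segment():
        masks = {}
        for name, vol, seeds in (("dwi", dwi, seeds_dwi), ("flair", flair, seeds_flair)):
            mask = region_grow(vol, seeds, rel_threshold=config.rel_threshold,
                               connectivity=config.connectivity,
                               mode=config.seg_mode, band=config.band)
            mask.save(_write(f"mask_{name}", out / f"mask_{name}.nii"))
            per_slice_areas(mask).to_csv(
                _write(f"slices_{name}", out / f"slice_areas_{name}.csv"), index=False)
            masks[name] = mask
        return masks

    masks = _run_stage("segment", _stage_segment)

    # --- volumetrics ----------------------------------------------------
    def _stage_volumetrics():
        dwi_cm3 = lesion_volume(masks["dwi"])
        flair_cm3 = lesion_volume(masks["flair"])
        endpoints = volumetric_endpoints(dwi_cm3, flair_cm3)
        import pandas as pd

        pd.DataFrame([asdict(endpoints)]).to_csv(
            _write("volumetrics", out / "volumetrics.csv"), index=False)
        return endpoints

    endpoints = _run_stage("volumetrics", _stage_volumetrics)

    # --- coil field -----------------------------------------------------
    def _stage_field():
        coil = _build_coil(config)
        coil.save_vertices(_write("coil_vertices", out / "coil_vertices.txt"))
        center = config.coil_center_mm
        if center is None:
            centroid = masks["dwi"].voxel_centers_mm().mean(axis=0)
            center = (float(centroid[0]), float(centroid[1]), -config.standoff_mm)
        bmag = field_magnitude_volume(coil, dwi, center)
        img = ImageVolume(bmag, dwi.spacing_mm, dwi.origin_mm, modality=dwi.modality)
        img.save(_write("field", out / "b_magnitude_mT.nii"))
        return coil, center, bmag

    coil, coil_center, bmag = _run_stage("field", _stage_field)

    # --- dosimetry ------------------------------------------------------
    def _stage_dose():
        import pandas as pd

        rows = []
        summaries = {}
        for name, mask in masks.items():
            summary = summarize_dose(mask, coil, coil_center_mm=coil_center,
                                     threshold_mT=config.threshold_mT, bmag_mT=bmag)
            summaries[name] = summary
            rows.append({"lesion": name, "d_min_cm": summary.d_min_cm,
                         "d_max_cm": summary.d_max_cm, "b_min_mT": summary.b_min_mT,
                         "b_max_mT": summary.b_max_mT,
                         "frac_above_threshold": summary.frac_above_threshold,
                         "threshold_mT": summary.threshold_mT,
                         "threshold_pass": check_biological_threshold(summary)})
        pd.DataFrame(rows).to_csv(_write("dose", out / "dose.csv"), index=False)
        return summaries

    summaries = _run_stage("dose", _stage_dose)

    # --- report ---------------------------------------------------------
    def _stage_report():
        record = PatientRecord(
            patient_id=config.patient_id, stim_minutes=config.stim_minutes,
            nihss=(None,) * len(VISITS), bi=(None,) * len(VISITS),
            mrs=(None,) * len(VISITS),
            volumetrics=endpoints, dose=summaries["dwi"])
        summarize_cohort([record]).to_csv(
            _write("report", out / "cohort_report.csv"), index=False)

    _run_stage("report", _stage_report)

    # --- manifest -------------------------------------------------------
    manifest = {
        "package": "elfdose",
        "version": __version__,
        "schema": SCHEMA_VERSION,
        "rng_seed": config.rng_seed,
        "config": _config_echo(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_echo(config), sort_keys=True).encode()).hexdigest(),
        "stages": stage_log,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = out / "manifest.json"
    return artifacts


def write_cohort_report(out_dir) -> dict[str, Path]:
    """Cohort-fixture mode: the published six-patient report tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = make_cohort_fixture()
    report = out / "cohort_report.csv"
    groups = out / "group_summary.csv"
    summarize_cohort(records).to_csv(report, index=False)
    group_summary(records).to_csv(groups, index=False)
    return {"report": report, "groups": groups}
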