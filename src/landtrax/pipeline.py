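"""End-to-end orchestration of the synthetic demonstration pipeline.

Stage order follows the analysis: scene simulation, trajectory construction
and filtering, transition classification and refinement, MMU enforcement,
yield modeling, yield differentials, habitat accounting, and accuracy
propagation. Stages communicate only through declared file artifacts; the run
manifest records every artifact's checksum, per-stage timings and pixel
tallies, and a snapshot of the configuration, so an identical rerun
reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc_mod
from . import differentials as diff_mod
from . import habitat as hab_mod
from .habitat import PairCategory
from .legend import CROP, Legend, default_legend
from .mmu import enforce_mmu, pixel_threshold
from .raster import GridRef, write_raster
from .synthetic import (
    SceneConfig,
    YieldFunction,
    generate_covariates_and_yields,
    generate_scene,
    make_zone_raster,
)
from .trajectory import encode_trajectories, majority_filter, reclassify_binary
from .transitions import (
    RefinementRules,
    TransitionClass,
    apply_refinements,
    attribute_conversion,
    classify_transitions,
)
from .yields import YieldModelSpec, fit_yield_model, predict_surface

log = logging.getLogger("landtrax")

STAGES = ("simulate", "trajectories", "classify", "mmu", "yields",
          "differentials", "habitat", "accuracy")


class ConfigError(ValueError):
    """Pipeline configuration failed validation before any stage ran."""


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    mmu_acres: float = 5.0
    neighborhood_size_m: float = 1500.0  # demo-scale stand-in for the 10 km tiling
    model: YieldModelSpec = field(default_factory=YieldModelSpec)
    zone_grid: tuple[int, int] = (6, 6)
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    legend_path: str | None = None  # optional external legend CSV

    def __post_init__(self):
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if self.legend_path is not None and not Path(self.legend_path).exists():
            raise ConfigError(f"legend file not found: {self.legend_path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        scene = SceneConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.get("scene", {}).items()})
        model = YieldModelSpec(**raw.get("model", {}))
        kwargs = {k: v for k, v in raw.items() if k not in ("scene", "model")}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "zone_grid" in kwargs:
            kwargs["zone_grid"] = tuple(kwargs["zone_grid"])
        return cls(scene=scene, model=model, **kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


DEFAULT_STEM_TABLE = pd.DataFrame(
    # synthetic example densities (stems/acre); editable, not asserted values
    [
        {"cover": "grassland_pasture", "crp": False, "stems_per_acre": 18.0, "se_per_acre": 9.0},
        {"cover": "grassland_pasture", "crp": True, "stems_per_acre": 66.0, "se_per_acre": 30.0},
        {"cover": "other_hay", "crp": False, "stems_per_acre": 10.0, "se_per_acre": 5.0},
        {"cover": "other_hay", "crp": True, "stems_per_acre": 10.0, "se_per_acre": 5.0},
        {"cover": "shrubland", "crp": False, "stems_per_acre": 8.0, "se_per_acre": 4.0},
        {"cover": "shrubland", "crp": True, "stems_per_acre": 8.0, "se_per_acre": 4.0},
        {"cover": "wetlands", "crp": False, "stems_per_acre": 12.0, "se_per_acre": 6.0},
        {"cover": "wetlands", "crp": True, "stems_per_acre": 12.0, "se_per_acre": 6.0},
        {"cover": "forest", "crp": False, "stems_per_acre": 1.0, "se_per_acre": 0.5},
        {"cover": "forest", "crp": True, "stems_per_acre": 1.0, "se_per_acre": 0.5},
        {"cover": "developed", "crp": False, "stems_per_acre": 0.5, "se_per_acre": 0.3},
        {"cover": "developed", "crp": True, "stems_per_acre": 0.5, "se_per_acre": 0.3},
    ]
    # crop covers carry no milkweed; rows exist so noisy pre-cover attributions resolve
    + [
        {"cover": c, "crp": flag, "stems_per_acre": 0.0, "se_per_acre": 0.0}
        for c in ("corn", "soybeans", "wheat", "alfalfa", "fallow_idle")
        for flag in (False, True)
    ]
)

DEFAULT_PAIR_CATEGORIES = {
    1: PairCategory(0, 20),
    2: PairCategory(20, 40),
    3: PairCategory(40, 60),
    4: PairCategory(60, 80),
    5: PairCategory(80, 100),
    6: PairCategory(100, None),  # open top: >100 pairs/sq. mi.
}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the configured stages end-to-end; return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    legend = Legend.from_csv(config.legend_path) if config.legend_path else default_legend()
    ref = GridRef(pixel_size_m=config.scene.pixel_size_m)
    manifest: dict = {"config": config.snapshot(), "seed": config.seed,
                      "stages": {}, "artifacts": {}}
    artifacts: dict[str, Path] = {}

    def record(name: str, path: Path):
        artifacts[name] = path
        manifest["artifacts"][name] = {"path": str(path.relative_to(out)),
                                       "sha256": _sha256(path)}

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            tallies = _STAGE_FUNCS[stage](config, legend, ref, out, state, record)
        except Exception as e:
            manifest["stages"][stage] = {"status": "failed", "error": str(e)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.perf_counter() - t0, 3),
            **(tallies or {}),
        }
        log.info("stage %s complete (%.2fs)", stage, time.perf_counter() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stage_simulate(config, legend, ref, out, state, record):
    series, epochs, truth = generate_scene(config.scene, legend)
    state.update(series=series, epochs=epochs, truth=truth)
    for t, year in enumerate(series.years):
        record(f"landcover_{year}", write_raster(out / f"landcover_{year}.tif",
                                                 series.rasters[t].astype(np.int32), ref))
    for t, year in enumerate(epochs.years):
        record(f"epoch_{year}", write_raster(out / f"epoch_{year}.tif",
                                             epochs.rasters[t].astype(np.int32), ref))
    record("truth_transition", write_raster(out / "truth_transition.tif",
                                            truth.truth_transition, ref))
    record("truth_year", write_raster(out / "truth_year.tif", truth.truth_year, ref))
    legend.to_csv(out / "legend.csv")
    record("legend", out / "legend.csv")
    (out / "scene.yaml").write_text(yaml.safe_dump(config.snapshot()["scene"]))
    record("scene_config", out / "scene.yaml")
    return {"n_fields": len(truth.fields),
            "noisy_pixel_years": int(truth.noise_mask.sum())}


def _stage_trajectories(config, legend, ref, out, state, record):
    series = state["series"]
    binary = reclassify_binary(series)
    epoch_binary = reclassify_binary(state["epochs"])
    traj = majority_filter(encode_trajectories(binary))
    state.update(traj=traj, epoch_binary=epoch_binary)
    record("trajectories", write_raster(out / "trajectories.tif", traj.codes, ref))
    book = pd.DataFrame(
        {"code": list(traj.code_book), "sequence": ["".join(map(str, s)) for s in traj.code_book.values()]}
    )
    book.to_csv(out / "trajectory_codes.csv", index=False)
    record("trajectory_codes", out / "trajectory_codes.csv")
    return {"n_trajectories": len(traj.code_book)}


def _stage_classify(config, legend, ref, out, state, record):
    series, traj = state["series"], state["traj"]
    tmap = classify_transitions(traj, state["epoch_binary"],
                                state["epochs"].years, series.years,
                                pixel_size_m=series.pixel_size_m)
    tmap = attribute_conversion(tmap, series)
    tmap, tallies = apply_refinements(tmap, RefinementRules(), legend)
    state["tmap"] = tmap
    _write_tmap(out / "transitions.tif", tmap, ref, record, "transitions")
    return {"refinement_reassigned": tallies}


def _stage_mmu(config, legend, ref, out, state, record):
    min_px = pixel_threshold(config.mmu_acres, config.scene.pixel_size_m)
    tmap = enforce_mmu(state["tmap"], min_px)
    state["tmap"] = tmap
    _write_tmap(out / "transitions_mmu.tif", tmap, ref, record, "transitions_mmu")
    return {"min_px": min_px}


def _write_tmap(path, tmap, ref, record, name):
    stack = np.stack([tmap.transition.astype(np.int32), tmap.conv_year,
                      tmap.pre_cover, tmap.post_cover])
    import tifffile

    tifffile.imwrite(path, stack)
    Path(str(path) + ".json").write_text(json.dumps(dataclasses.asdict(ref), indent=1))
    record(name, path)


DEMO_YIELD_FN = YieldFunction(
    covariates=("soil_quality", "water_balance", "terrain"),
    coefficients=(60.0, 35.0, -20.0),
    intercept=90.0,
    crop_offsets={"corn": 70.0, "soybeans": -45.0, "wheat": -30.0},
    noise_sd=2.0,
)


def _stage_yields(config, legend, ref, out, state, record):
    series, truth, tmap = state["series"], state["truth"], state["tmap"]
    zones = make_zone_raster(series.shape, *config.zone_grid)
    crops = ("corn", "soybeans", "wheat")
    crop_masks = {
        (crop, year): series.rasters[t] == legend.code(crop)
        for crop in crops
        for t, year in enumerate(series.years)
    }
    grids, table = generate_covariates_and_yields(
        config.scene, zones, DEMO_YIELD_FN, crops=crops, crop_masks=crop_masks
    )
    table.to_csv(out / "yield_training.csv", index=False)
    record("yield_training", out / "yield_training.csv")
    state.update(zones=zones, cov_grids=grids, yield_table=table)
    record("zones", write_raster(out / "zones.tif", zones, ref))

    surfaces = {}
    reports = {}
    for crop in crops:
        records_crop = table[table["crop"] == crop]
        if len(records_crop) < 72:  # need a usable training table for this crop
            continue
        model = fit_yield_model(records_crop.reset_index(drop=True), config.model, crop=crop)
        code = legend.code(crop)
        ever_crop = np.zeros(series.shape, bool)
        for t in range(series.n_years):
            ever_crop |= series.rasters[t] == code
        stable = (tmap.transition == TransitionClass.STABLE_CROP) & ever_crop
        new = (tmap.transition == TransitionClass.TO_CROP) & (tmap.post_cover == code)
        surf = predict_surface(model, grids, stable | new, pixel_size_m=series.pixel_size_m)
        surfaces[crop] = {"surface": surf, "stable": stable, "new": new}
        reports[crop] = {"holdout_rmse": model.report.rmse, "holdout_r2": model.report.r2,
                         "n_train": model.report.n_train, "n_holdout": model.report.n_holdout}
        record(f"yield_surface_{crop}",
               write_raster(out / f"yield_surface_{crop}.tif", surf.values, ref))
    state["yield_surfaces"] = surfaces
    return {"models": reports}


def _stage_differentials(config, legend, ref, out, state, record):
    rows = []
    for crop, bundle in state["yield_surfaces"].items():
        surf, stable, new = bundle["surface"], bundle["stable"], bundle["new"]
        if not new.any() or not stable.any():
            continue
        y_nat = diff_mod.national_reference(surf, stable)
        dn = diff_mod.national_differential(surf, y_nat, new)
        record(f"diff_nat_{crop}", write_raster(out / f"diff_nat_{crop}.tif", dn, ref))
        summary = diff_mod.differential_summary(dn)
        row = {"crop": crop, "y_nat": y_nat,
               "mean_diff_nat": summary["mean"], "sd_diff_nat": summary["sd_spatial"],
               "fraction_below_nat": summary["fraction_below"]}
        try:
            loc = diff_mod.local_differential(surf, stable, new, config.neighborhood_size_m)
            record(f"diff_loc_{crop}", write_raster(out / f"diff_loc_{crop}.tif", loc.diff_loc, ref))
            row["mean_diff_loc"] = loc.weighted_mean
        except ValueError:
            row["mean_diff_loc"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "differentials.csv", index=False)
    record("differentials", out / "differentials.csv")
    return {"crops": list(df["crop"]) if len(df) else []}


def _stage_habitat(config, legend, ref, out, state, record):
    tmap, truth, series = state["tmap"], state["truth"], state["series"]
    rng = np.random.default_rng(config.seed + 9001)
    # CRP status is an input mask; the demo flags a random third of natural land
    natural = np.isin(truth.clean_rasters[0],
                      [legend.code(n) for n in ("grassland_pasture", "other_hay")])
    crp_mask = natural & (rng.random(series.shape) < 0.33)
    hab_mod.attach_current_cover(tmap, truth.clean_rasters[0])
    milkweed = hab_mod.milkweed_loss(tmap, crp_mask, DEFAULT_STEM_TABLE, legend)

    # category raster: smooth accessibility field binned into the table ranges
    field_surface = np.cumsum(rng.random(series.shape), axis=1)
    field_surface = 120 * field_surface / max(field_surface.max(), 1e-9)
    edges = [0, 20, 40, 60, 80, 100, np.inf]
    cat = np.digitize(field_surface, edges[1:-1]) + 1
    ducks = hab_mod.duck_accessibility(tmap, cat, DEFAULT_PAIR_CATEGORIES)

    cultivated = legend.codes_in_group(CROP) + [legend.code("other_hay")]
    lt_mask = hab_mod.longterm_mask(state["epochs"].rasters, tuple(cultivated))
    lt = hab_mod.longterm_conversion_tally(tmap, lt_mask, legend)
    record("longterm_mask", write_raster(out / "longterm_mask.tif",
                                         lt_mask.astype(np.uint8), ref))

    report = {
        "milkweed": {
            "stems_lost": milkweed.stems_lost,
            "stems_lost_se": milkweed.stems_lost_se,
            "converted_mean_density": milkweed.converted_mean_density,
            "existing_mean_density": milkweed.existing_mean_density,
            "density_ratio": milkweed.density_ratio,
            "converted_acres": milkweed.converted_acres,
        },
        "ducks": {
            "mean_converted": ducks.mean_converted,
            "mean_stable_crop": ducks.mean_stable_crop,
            "mean_unconverted": ducks.mean_unconverted,
            "total_opportunities": ducks.total_opportunities,
            "per_pixel_mean": ducks.per_pixel_mean,
            "excluded_pixels": ducks.excluded_pixels,
        },
        "longterm_acres_by_cover": lt.to_dict(orient="records"),
    }
    (out / "habitat_report.json").write_text(json.dumps(report, indent=1))
    record("habitat_report", out / "habitat_report.json")
    return {"stems_lost": milkweed.stems_lost}


def _stage_accuracy(config, legend, ref, out, state, record):
    tmap, zones = state["tmap"], state.get("zones")
    if zones is None:
        zones = make_zone_raster(tmap.shape, *config.zone_grid)
    rng = np.random.default_rng(config.seed + 4242)
    rows = []
    for z in np.unique(zones):
        for code in legend.names:
            base = 0.95 if legend.group(code) == CROP else 0.88
            rows.append({"zone": int(z), "cover_class": int(code), "year": None,
                         "sa": round(float(np.clip(base + rng.normal(0, 0.02), 0.5, 1.0)), 4)})
    table = pd.DataFrame(rows)
    table.to_csv(out / "superclass_accuracy.csv", index=False)
    record("superclass_accuracy", out / "superclass_accuracy.csv")
    acc = acc_mod.expected_accuracy(tmap, table, zones)
    record("expected_accuracy", write_raster(out / "expected_accuracy.tif", acc, ref))
    summary = acc_mod.accuracy_summary(acc, tmap, legend)
    summary.to_csv(out / "expected_accuracy_summary.csv", index=False)
    record("expected_accuracy_summary", out / "expected_accuracy_summary.csv")
    conv = tmap.conversion_mask()
    return {"mean_expected_accuracy": float(np.nanmean(acc[conv])) if conv.any() else None}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "trajectories": _stage_trajectories,
    "classify": _stage_classify,
    "mmu": _stage_mmu,
    "yields": _stage_yields,
    "differentials": _stage_differentials,
    "habitat": _stage_habitat,
    "accuracy": _stage_accuracy,
}
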