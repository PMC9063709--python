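"""End-to-end run: segment → measure → summarize → optional analyses.

One photograph is assumed to hold all of one plant's trimmed inflorescences
(one image = one plant); several frames of the same plant can be merged by
giving them the same ``plant_id`` in the image list.  All randomness used by
any stage flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from ._version import __version__
from .image_io import load_image, load_mask, save_mask
from .segmentation import SegmentationConfig, segment_scene
from .morphometry import measure_labels
from .plant_metrics import summarize_plants, broad_sense_heritability, correlation_matrix
from .yield_model import (
    PUBLISHED_DEFAULT_MODEL,
    PredictionModel,
    apportion_weights,
    predict_idb,
    refit_prediction,
    sampling_simulation,
    top_longest_mean_width,
    yield_threshold_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class ImageEntry:
    """One photograph with its calibration and the plant it belongs to."""

    path: str
    cm_per_pixel: float
    plant_id: str
    remove_mask: str | None = None
    add_mask: str | None = None


@dataclass
class RunConfig:
    """Everything a pipeline run needs; unknown keys are rejected on load."""

    images: list[ImageEntry] = field(default_factory=list)
    meta_csv: str | None = None
    out_dir: str = "inflorascan_out"
    seed: int = 0
    log_level: str = "INFO"
    # segmentation
    min_area_cm2: float = 1.0
    connectivity: int = 8
    object_side: str = "below"
    # measurement
    moment_source: str = "region"
    hull_points: str = "corners"
    # analyses to run after summarizing: subset of
    # {"thresholds", "predict", "h2", "corr", "sample_sim"}
    analyses: list[str] = field(default_factory=list)
    yield_q: list[float] = field(default_factory=lambda: [0.5, 0.75, 0.9])
    k_longest: int = 20
    predict_slope: float = PUBLISHED_DEFAULT_MODEL.slope
    predict_intercept: float = PUBLISHED_DEFAULT_MODEL.intercept
    h2_traits: list[str] = field(default_factory=lambda: ["IW_cm_mean", "TIC_cm2"])
    corr_traits: list[str] = field(default_factory=list)
    sample_sim_m: list[int] = field(default_factory=lambda: [5, 10, 15])
    sample_sim_rounds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        images = [ImageEntry(**e) for e in raw.pop("images", [])]
        return cls(images=images, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {f.name: repr(getattr(self, f.name)) for f in _dc_fields(self)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of output DataFrames.

    Writes, under ``config.out_dir``: per-image ``<id>_mask.png`` and
    ``<id>_labels.png`` (16-bit), ``objects.csv``, ``plants_summary.csv``,
    and one CSV per requested analysis.  Identical config + seed give
    byte-identical CSVs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not config.images:
        raise ValueError("pipeline: no images configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "inflorascan %s, config hash %s, seed %d",
        __version__, config.config_hash(), config.seed,
    )

    obj_tables: list[pd.DataFrame] = []
    for entry in config.images:
        image = load_image(entry.path, entry.cm_per_pixel)
        seg_cfg = SegmentationConfig(
            min_area_cm2=config.min_area_cm2,
            connectivity=config.connectivity,
            object_side=config.object_side,
            remove_mask=load_mask(entry.remove_mask) if entry.remove_mask else None,
            add_mask=load_mask(entry.add_mask) if entry.add_mask else None,
        )
        result = segment_scene(image, seg_cfg)
        logger.info(
            "image %s: T=%d floor=%d px K=%d",
            image.image_id, result.threshold, result.floor_px, result.objects.count,
        )
        save_mask(result.mask, out / f"{image.image_id}_mask.png")
        Image.fromarray(result.objects.label_grid.astype(np.uint16)).save(
            out / f"{image.image_id}_labels.png"
        )
        table = measure_labels(
            result.objects,
            image.cm_per_pixel,
            image_id=image.image_id,
            moment_source=config.moment_source,
            hull_points=config.hull_points,
        )
        table.insert(0, "plant_id", entry.plant_id)
        obj_tables.append(table)

    objects = pd.concat(obj_tables, ignore_index=True)
    objects.to_csv(out / "objects.csv", index=False)

    outputs: dict = {"objects": objects}
    if config.meta_csv is None:
        return outputs
    meta = pd.read_csv(config.meta_csv)
    plants = summarize_plants(objects, meta)
    plants.to_csv(out / "plants_summary.csv", index=False)
    outputs["plants"] = plants

    if any(a in config.analyses for a in ("thresholds", "predict", "sample_sim")):
        if "IDB_g" not in meta.columns and "thresholds" in config.analyses:
            raise ValueError("IDB required for yield analyses")

    if "thresholds" in config.analyses:
        rows = []
        for _, plant in plants.iterrows():
            if plant["IDB_g"] is None or not np.isfinite(plant["IDB_g"]):
                raise ValueError(f"IDB required for plant {plant['plant_id']}")
            recs = objects[objects["plant_id"] == plant["plant_id"]]
            weighted = apportion_weights(plant["IDB_g"], recs, plant["plant_id"])
            for q in config.yield_q:
                rows.append(
                    {
                        "plant_id": plant["plant_id"],
                        "q": q,
                        "percent_required": yield_threshold_fraction(weighted, q),
                    }
                )
        thresholds = pd.DataFrame(rows)
        thresholds.to_csv(out / "yield_thresholds.csv", index=False)
        outputs["thresholds"] = thresholds

    if "predict" in config.analyses:
        model = PredictionModel(
            slope=config.predict_slope,
            intercept=config.predict_intercept,
            k_longest=config.k_longest,
            provenance=(
                "published_default"
                if (config.predict_slope, config.predict_intercept)
                == (PUBLISHED_DEFAULT_MODEL.slope, PUBLISHED_DEFAULT_MODEL.intercept)
                else "refitted"
            ),
        )
        rows = []
        for pid, grp in objects.groupby("plant_id", sort=True):
            mean_iw = top_longest_mean_width(grp, k=config.k_longest)
            rows.append(
                {
                    "plant_id": pid,
                    "mean_IW_cm": mean_iw,
                    "predicted_IDB_g": predict_idb(mean_iw, model),
                }
            )
        pred = pd.DataFrame(rows)
        pred.to_csv(out / "predicted_idb.csv", index=False)
        outputs["predictions"] = pred

    if "h2" in config.analyses:
        rows = []
        for trait in config.h2_traits:
            res = broad_sense_heritability(plants, trait)
            rows.append(
                {"trait": trait, "H2": res.h2, "V_G": res.v_g, "V_W": res.v_w}
            )
        h2 = pd.DataFrame(rows)
        h2.to_csv(out / "heritability.csv", index=False)
        outputs["h2"] = h2

    if "corr" in config.analyses and config.corr_traits:
        r, p = correlation_matrix(plants, config.corr_traits)
        r.to_csv(out / "correlations_r.csv")
        p.to_csv(out / "correlations_p.csv")
        outputs["correlations"] = r

    if "sample_sim" in config.analyses:
        rng_seeds = np.random.SeedSequence(config.seed).generate_state(len(plants))
        rows = []
        for (pid, grp), pseed in zip(objects.groupby("plant_id", sort=True), rng_seeds):
            ranked = grp.sort_values(
                ["IL_cm", "IW_cm", "object_id"],
                ascending=[False, False, True], kind="stable",
            )
            top = ranked["IW_cm"].head(config.k_longest).to_numpy()
            for m in config.sample_sim_m:
                if m > top.size:
                    continue
                res = sampling_simulation(
                    top, m, rounds=config.sample_sim_rounds, seed=int(pseed % (2**31))
                )
                for rnd, mean in enumerate(res.means, start=1):
                    rows.append(
                        {"plant_id": pid, "m": m, "round": rnd, "mean_IW_cm": mean}
                    )
        sim = pd.DataFrame(rows)
        sim.to_csv(out / "sampling_simulation.csv", index=False)
        outputs["sampling"] = sim

    return outputs
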