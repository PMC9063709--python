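"""Ground-truthed synthetic scenes and plant populations.

No study images or plant tables are distributed, so every pipeline stage is
exercised on generated data whose truth is known by construction:

* :func:`generate_scene` renders non-overlapping filled superellipse "buds"
  on a bright background with the blue-channel contrast the segmentation
  stage expects (background blue 200, object blue 60 by default), optional
  Gaussian pixel noise, and optional sub-floor specks that the area opening
  must delete.  The returned truth table records each blob's parameters and
  its analytic moment-equivalent axes.
* :func:`generate_population` draws a clonal population in the image of the
  original study design — 119 genotypes with 4 clonal replicates,
  200–300 inflorescences per plant, right-skewed (log-normal) size
  distributions, and dry biomass proportional to total coverage with a few
  percent of multiplicative noise.

Superellipses (|x/a|^e + |y/b|^e ≤ 1, exponent drawn slightly above 2) make
segmentation and moment estimation non-trivial while keeping the axes
analytically known: the moment-based axis of a superellipse exceeds 2a by the
closed-form factor of :func:`superellipse_axis_factor`, which the truth table
bakes into its expected IL/IW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import beta as _beta

from .image_io import CalibratedImage
from . import plant_metrics
from .yield_model import top_longest_mean_width


def superellipse_axis_factor(exponent: float) -> float:
    """Ratio of the moment-based axis to the true axis for a superellipse.

    For the region |x/a|^e + |y/b|^e ≤ 1 the normalized second moment along
    x is a²·B(3/e, 1/e+1)/B(1/e, 1/e+1), so the moment-based "length"
    (calibrated to be exact for ellipses) is 2a times this factor.  It equals
    1 at e = 2 and grows toward 2/sqrt(3) ≈ 1.155 as the shape squares off.
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    r = _beta(3.0 / exponent, 1.0 / exponent + 1.0) / _beta(
        1.0 / exponent, 1.0 / exponent + 1.0
    )
    return 2.0 * math.sqrt(r)


def superellipse_area(a: float, b: float, exponent: float) -> float:
    """Analytic area of |x/a|^e + |y/b|^e ≤ 1 (π·a·b at e = 2)."""
    e = exponent
    return a * b * (4.0 / e) * _beta(1.0 / e, 1.0 / e + 1.0)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene.

    Defaults give a 40×40 cm frame at 0.05 cm/px (800×800 px) with twelve
    buds of 1.2–2.6 cm semi-major axis — comfortably above the 1 cm² area
    floor — and mild pixel noise.
    """

    n_objects: int = 12
    cm_per_pixel: float = 0.05
    frame_cm: tuple[float, float] = (40.0, 40.0)
    semi_major_range_cm: tuple[float, float] = (1.2, 2.6)
    aspect_range: tuple[float, float] = (0.45, 0.8)
    exponent_range: tuple[float, float] = (2.0, 2.4)
    background_rgb: tuple[int, int, int] = (190, 190, 200)
    object_rgb: tuple[int, int, int] = (80, 110, 60)
    noise_sd: float = 5.0
    n_specks: int = 0
    speck_area_cm2: float = 0.4
    shading: bool = False
    shading_amplitude: float = 15.0
    max_placement_attempts: int = 2000


def _place_centers(
    rng: np.ndarray, radii_px: np.ndarray, shape: tuple[int, int], attempts: int
) -> np.ndarray:
    """Rejection-sample non-overlapping centers; radii are exclusion radii."""
    h, w = shape
    centers: list[tuple[float, float]] = []
    for r in radii_px:
        if 2 * r >= min(h, w):
            raise ValueError("object too large for the frame")
        for _ in range(attempts):
            cx = rng.uniform(r, w - 1 - r)
            cy = rng.uniform(r, h - 1 - r)
            ok = all(
                math.hypot(cx - px, cy - py) > r + pr + 2.0
                for (px, py), pr in zip(centers, radii_px[: len(centers)])
            )
            if ok:
                centers.append((cx, cy))
                break
        else:
            raise ValueError(
                "could not place all objects without overlap; "
                "reduce n_objects or object sizes"
            )
    return np.asarray(centers)


def generate_scene(
    spec: SceneSpec | None = None, seed: int | None = None
) -> tuple[CalibratedImage, pd.DataFrame]:
    """Render a calibrated scene and return it with its ground-truth table.

    The truth table has one row per object (specks excluded) with columns
    ``object_id, center_x_px, center_y_px, a_cm, b_cm, angle_deg, exponent,
    area_cm2, expected_IL_cm, expected_IW_cm``.  Expected axes include the
    analytic superellipse moment factor, so a correct measurement stage
    should land within digitization error of them.  Same spec + seed ⇒
    identical raster.
    """
    spec = spec or SceneSpec()
    if spec.n_objects < 1:
        raise ValueError("need at least one object")
    rng = np.random.default_rng(seed)
    p = spec.cm_per_pixel
    h = int(round(spec.frame_cm[1] / p))
    w = int(round(spec.frame_cm[0] / p))

    a_cm = rng.uniform(*spec.semi_major_range_cm, size=spec.n_objects)
    b_cm = a_cm * rng.uniform(*spec.aspect_range, size=spec.n_objects)
    angles = rng.uniform(0.0, 180.0, size=spec.n_objects)
    exponents = rng.uniform(*spec.exponent_range, size=spec.n_objects)

    speck_r_px = math.sqrt(spec.speck_area_cm2 / math.pi) / p
    radii = np.concatenate(
        [a_cm / p + 3.0, np.full(spec.n_specks, speck_r_px + 3.0)]
    )
    centers = _place_centers(rng, radii, (h, w), spec.max_placement_attempts)

    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.asarray(spec.background_rgb, dtype=np.float64)

    def paint(cx, cy, a_px, b_px, theta_deg, e):
        half = int(math.ceil(max(a_px, b_px))) + 2
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        xs = np.arange(x0, x1, dtype=np.float64) - cx
        ys = np.arange(y0, y1, dtype=np.float64) - cy
        gx, gy = np.meshgrid(xs, ys)
        t = math.radians(theta_deg)
        u = gx * math.cos(t) + gy * math.sin(t)
        v = -gx * math.sin(t) + gy * math.cos(t)
        inside = (np.abs(u / a_px) ** e + np.abs(v / b_px) ** e) <= 1.0
        region = canvas[y0:y1, x0:x1]
        region[inside] = np.asarray(spec.object_rgb, dtype=np.float64)

    for i in range(spec.n_objects):
        paint(centers[i, 0], centers[i, 1], a_cm[i] / p, b_cm[i] / p, angles[i], exponents[i])
    for j in range(spec.n_specks):
        cx, cy = centers[spec.n_objects + j]
        paint(cx, cy, speck_r_px, speck_r_px, 0.0, 2.0)

    if spec.shading:
        ramp = np.linspace(-spec.shading_amplitude, spec.shading_amplitude, w)
        canvas += ramp[None, :, None]
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    factors = np.array([superellipse_axis_factor(e) for e in exponents])
    truth = pd.DataFrame(
        {
            "object_id": np.arange(1, spec.n_objects + 1),
            "center_x_px": centers[: spec.n_objects, 0],
            "center_y_px": centers[: spec.n_objects, 1],
            "a_cm": a_cm,
            "b_cm": b_cm,
            "angle_deg": angles,
            "exponent": exponents,
            "area_cm2": [
                superellipse_area(a, b, e) for a, b, e in zip(a_cm, b_cm, exponents)
            ],
            "expected_IL_cm": 2.0 * a_cm * factors,
            "expected_IW_cm": 2.0 * b_cm * factors,
        }
    )
    image = CalibratedImage(pixels, p, image_id=f"synthetic-scene-{seed}")
    return image, truth


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic clonal population.

    Defaults mirror the original study design: 119 genotypes × 4 clonal
    replicates, about 250 inflorescences per plant, mean object size near
    4.3 cm² with a strongly right-skewed (log-normal) distribution, and dry
    biomass coupled to total coverage through a grams-per-cm² density with
    4% multiplicative noise.  Genotype/plant variance components act on the
    latent log-count, log-size and shape scales.
    """

    n_genotypes: int = 119
    clones_per_genotype: int = 4
    mean_objects_per_plant: float = 250.0
    count_log_vg: float = 0.03
    count_log_ve: float = 0.07
    size_log_mu: float = 1.21  # exp(1.21 + 0.7²/2) ≈ 4.3 cm² mean size
    size_log_sigma_within: float = 0.7
    size_mu_vg: float = 0.004
    size_mu_ve: float = 0.012
    shape_mean: float = 0.62
    shape_sd_within: float = 0.08
    shape_vg: float = 0.0012
    shape_ve: float = 0.002
    density_g_per_cm2: float = 0.12
    idb_noise_sd: float = 0.04
    ph_mean_cm: float = 90.0
    ph_vg: float = 60.0
    ph_ve: float = 55.0
    dtm_mean_d: float = 70.0
    dtm_vg: float = 24.0
    dtm_ve: float = 25.0
    min_objects: int = 25


def generate_population(
    spec: PopulationSpec | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a clonal population; returns ``(plants, objects)`` tables.

    ``objects`` has one row per inflorescence (plant_id, object_id,
    pixel-free morphometrics); ``plants`` is the population table built by
    the real aggregation code (:func:`inflorascan.plant_metrics.summarize_plants`)
    plus ``IDB_g``, ``PH_cm``, ``DTM_d`` and the top-20 mean width
    ``mean_IW_top20_cm``.  Reproducible by seed.
    """
    spec = spec or PopulationSpec()
    if spec.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    rng = np.random.default_rng(seed)

    obj_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    for g in range(spec.n_genotypes):
        gid = f"G{g + 1:03d}"
        g_count = rng.normal(0.0, math.sqrt(spec.count_log_vg))
        g_size = rng.normal(0.0, math.sqrt(spec.size_mu_vg))
        g_shape = rng.normal(0.0, math.sqrt(spec.shape_vg))
        g_ph = rng.normal(0.0, math.sqrt(spec.ph_vg))
        g_dtm = rng.normal(0.0, math.sqrt(spec.dtm_vg))
        for c in range(spec.clones_per_genotype):
            pid = f"{gid}-{c + 1}"
            lam = spec.mean_objects_per_plant * math.exp(
                g_count + rng.normal(0.0, math.sqrt(spec.count_log_ve))
            )
            n_obj = max(int(rng.poisson(lam)), spec.min_objects)
            mu = spec.size_log_mu + g_size + rng.normal(0.0, math.sqrt(spec.size_mu_ve))
            sizes = rng.lognormal(mu, spec.size_log_sigma_within, size=n_obj)
            shape_center = spec.shape_mean + g_shape + rng.normal(
                0.0, math.sqrt(spec.shape_ve)
            )
            ish = np.clip(
                rng.normal(shape_center, spec.shape_sd_within, size=n_obj), 0.2, 0.95
            )
            il = np.sqrt(4.0 * sizes / (math.pi * ish))
            iw = ish * il
            ch_factor = rng.uniform(1.05, 1.18, size=n_obj)
            ch = sizes * ch_factor
            # Ramanujan ellipse perimeter, dilated with the hull so the
            # isoperimetric inequality HP² ≥ 4π·CH stays satisfiable
            x, y = il / 2.0, iw / 2.0
            hp = 1.02 * np.sqrt(ch_factor) * math.pi * (
                3.0 * (x + y) - np.sqrt((3.0 * x + y) * (x + 3.0 * y))
            )
            obj_frames.append(
                pd.DataFrame(
                    {
                        "plant_id": pid,
                        "object_id": np.arange(1, n_obj + 1),
                        "pixel_count": np.rint(sizes / 0.05**2).astype(int),
                        "IS_cm2": sizes,
                        "IL_cm": il,
                        "IW_cm": iw,
                        "CH_cm2": ch,
                        "HP_cm": hp,
                        "ISH": iw / il,
                    }
                )
            )
            tic = float(sizes.sum())
            idb = spec.density_g_per_cm2 * tic * (
                1.0 + rng.normal(0.0, spec.idb_noise_sd)
            )
            meta_rows.append(
                {
                    "plant_id": pid,
                    "genotype_id": gid,
                    "state": "dry",
                    "IDB_g": max(idb, 0.0),
                    "PH_cm": spec.ph_mean_cm + g_ph + rng.normal(0.0, math.sqrt(spec.ph_ve)),
                    "DTM_d": spec.dtm_mean_d + g_dtm + rng.normal(0.0, math.sqrt(spec.dtm_ve)),
                }
            )

    objects = pd.concat(obj_frames, ignore_index=True)
    meta = pd.DataFrame(meta_rows)
    plants = plant_metrics.summarize_plants(objects, meta)
    top_iw = (
        objects.groupby("plant_id", sort=True)
        .apply(lambda grp: top_longest_mean_width(grp, k=20), include_groups=False)
        .rename("mean_IW_top20_cm")
    )
    plants = plants.merge(top_iw, left_on="plant_id", right_index=True)
    return plants, objects


def simulate_clonal_trait(
    n_genotypes: int,
    clones_per_genotype: int,
    v_g: float,
    v_e: float,
    mean: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one trait under the clonal variance-component model.

    value = mean + genotype effect (variance ``v_g``) + plant deviation
    (variance ``v_e``); the true broad-sense heritability is
    v_g / (v_g + v_e).  Returns columns ``genotype_id, plant_id, value``.
    """
    if v_g < 0 or v_e < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0.0, math.sqrt(v_g), size=n_genotypes)
    vals = mean + np.repeat(g_eff, clones_per_genotype) + rng.normal(
        0.0, math.sqrt(v_e), size=n_genotypes * clones_per_genotype
    )
    gids = np.repeat([f"G{i + 1:03d}" for i in range(n_genotypes)], clones_per_genotype)
    pids = [f"{g}-{c + 1}" for g in [f"G{i + 1:03d}" for i in range(n_genotypes)]
            for c in range(clones_per_genotype)]
    return pd.DataFrame({"genotype_id": gids, "plant_id": pids, "value": vals})
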