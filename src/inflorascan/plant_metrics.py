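"""Per-plant aggregation, fresh/dry calibration, heritability and correlations.

A plant's morphometric profile is the mean and standard deviation of each
per-object trait, together with the inflorescence number IN and the total
inflorescence coverage TIC = Σ IS.  Plants imaged fresh are mapped onto the
dry scale (or vice versa) through per-trait linear calibrations fitted on
plants imaged in both states; a calibration is only trusted when its R²
exceeds 0.9.

Broad-sense heritability is estimated from clonal replicates as the
repeatability of a one-way random-effects layout: genotype is the random
group, clones are replicates, and

    V_W = MS_within,   V_G = (MS_between − MS_within) / k1,
    k1 = (N − Σ n_i²/N) / (G − 1),   H² = V_G / (V_G + V_W)

with negative V_G truncated to zero.  No spatial adjustment of the growing
layout is applied, so the estimate is a clonal repeatability on the supplied
values rather than a design-corrected heritability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: per-object traits aggregated into plant means/sds
TRAITS = ("IS_cm2", "IL_cm", "IW_cm", "CH_cm2", "HP_cm", "ISH")


@dataclass(frozen=True)
class PlantSummary:
    """Per-plant aggregate of object records plus metadata."""

    plant_id: str
    genotype_id: str
    state: str  # "fresh" or "dry"
    IN: int
    TIC_cm2: float
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    IDB_g: float | None = None
    PH_cm: float | None = None
    DTM_d: float | None = None

    def to_row(self) -> dict:
        row = {
            "plant_id": self.plant_id,
            "genotype_id": self.genotype_id,
            "state": self.state,
            "IN": self.IN,
            "TIC_cm2": self.TIC_cm2,
        }
        for t in TRAITS:
            row[f"{t}_mean"] = self.means.get(t, float("nan"))
            row[f"{t}_sd"] = self.sds.get(t, float("nan"))
        row["IDB_g"] = self.IDB_g
        row["PH_cm"] = self.PH_cm
        row["DTM_d"] = self.DTM_d
        return row


def summarize_plant(records: pd.DataFrame, meta: dict) -> PlantSummary:
    """Aggregate one plant's object records.

    ``records`` is a measurement table (as produced by
    :func:`inflorascan.morphometry.measure_labels`); ``meta`` supplies
    ``plant_id``, ``genotype_id``, ``state`` and optionally ``IDB_g``,
    ``PH_cm``, ``DTM_d``.  Standard deviations use the n−1 denominator and
    are NaN (flagged undefined) when fewer than two objects contribute.
    Degenerate objects (zero width) are excluded from the ISH mean/sd only.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize a plant with no object records")
    means: dict = {}
    sds: dict = {}
    for t in TRAITS:
        vals = records[t].to_numpy(dtype=float)
        if t == "ISH":
            vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            means[t], sds[t] = float("nan"), float("nan")
            continue
        means[t] = float(np.mean(vals))
        sds[t] = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
    return PlantSummary(
        plant_id=str(meta["plant_id"]),
        genotype_id=str(meta.get("genotype_id", "")),
        state=str(meta.get("state", "dry")),
        IN=int(len(records)),
        TIC_cm2=float(records["IS_cm2"].sum()),
        means=means,
        sds=sds,
        IDB_g=_opt_float(meta.get("IDB_g")),
        PH_cm=_opt_float(meta.get("PH_cm")),
        DTM_d=_opt_float(meta.get("DTM_d")),
    )


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def summarize_plants(objects: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Build the population table: one summary row per plant.

    ``objects`` must carry a ``plant_id`` column (or an ``image_id`` column
    that doubles as the plant id — one frame per plant); ``meta`` is the
    plant metadata table with ``plant_id, genotype_id, state`` and optional
    ``IDB_g, PH_cm, DTM_d``.
    """
    objects = objects.copy()
    if "plant_id" not in objects.columns:
        if "image_id" not in objects.columns:
            raise ValueError("objects table needs a plant_id or image_id column")
        objects["plant_id"] = objects["image_id"]
    meta = meta.set_index(meta["plant_id"].astype(str))
    rows = []
    for pid, grp in objects.groupby(objects["plant_id"].astype(str), sort=True):
        if pid not in meta.index:
            raise ValueError(f"plant {pid!r} missing from metadata table")
        rows.append(summarize_plant(grp, meta.loc[pid].to_dict()).to_row())
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TraitCalibration:
    """Dry-on-fresh linear trendline for one trait."""

    slope: float
    intercept: float
    r2: float
    n_pairs: int
    calibratable: bool  # r2 above the gate and slope non-degenerate


@dataclass(frozen=True)
class CalibrationMap:
    """Per-trait fresh→dry linear transforms with their R² gate."""

    traits: dict  # name -> TraitCalibration
    r2_gate: float = 0.9

    def __getitem__(self, trait: str) -> TraitCalibration:
        return self.traits[trait]


def fit_fresh_dry_calibration(
    fresh: pd.DataFrame,
    dry: pd.DataFrame,
    traits: tuple[str, ...] | None = None,
    r2_gate: float = 0.9,
) -> CalibrationMap:
    """Fit per-trait linear trendlines of dry values on fresh values.

    ``fresh`` and ``dry`` hold the same plants (matched on ``plant_id``)
    imaged in both states, with one column per trait.  Ordinary least squares
    per trait; a trait is marked not-calibratable when its R² does not exceed
    the gate.
    """
    fresh = fresh.set_index(fresh["plant_id"].astype(str))
    dry = dry.set_index(dry["plant_id"].astype(str))
    shared = fresh.index.intersection(dry.index)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 paired plants, got {len(shared)}")
    if traits is None:
        traits = tuple(
            c
            for c in fresh.columns
            if c in dry.columns and pd.api.types.is_numeric_dtype(fresh[c]) and c != "plant_id"
        )
    out: dict = {}
    for t in traits:
        x = fresh.loc[shared, t].to_numpy(dtype=float)
        y = dry.loc[shared, t].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError(f"trait {t!r}: fewer than 3 finite pairs")
        if np.ptp(x) == 0:
            raise ValueError(f"trait {t!r}: zero variance in fresh values")
        res = _stats.linregress(x, y)
        r2 = float(res.rvalue**2)
        out[t] = TraitCalibration(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r2=r2,
            n_pairs=int(x.size),
            calibratable=bool(r2 > r2_gate and res.slope != 0),
        )
    return CalibrationMap(out, r2_gate)


def apply_calibration(
    summary: pd.DataFrame | PlantSummary,
    cal: CalibrationMap,
    direction: str = "fresh_to_dry",
    traits: tuple[str, ...] | None = None,
) -> pd.DataFrame | PlantSummary:
    """Map plant summaries between fresh and dry scales.

    Trait means are transformed affinely (``dry = slope·fresh + intercept``;
    the inverse map for ``dry_to_fresh``); standard deviations scale by
    |slope|, as under any affine map.  By default every trait the map was
    fitted for is transformed; requesting a trait without a trusted
    calibration raises an error naming it.
    """
    if direction not in ("fresh_to_dry", "dry_to_fresh"):
        raise ValueError("direction must be 'fresh_to_dry' or 'dry_to_fresh'")
    if traits is None:
        traits = tuple(cal.traits)

    if isinstance(summary, PlantSummary):
        means, sds = dict(summary.means), dict(summary.sds)
        for t in traits:
            a, b = _affine_for(cal, t, direction)
            means[t] = a * means[t] + b
            sds[t] = abs(a) * sds[t]
        return PlantSummary(
            plant_id=summary.plant_id,
            genotype_id=summary.genotype_id,
            state="dry" if direction == "fresh_to_dry" else "fresh",
            IN=summary.IN,
            TIC_cm2=summary.TIC_cm2,
            means=means,
            sds=sds,
            IDB_g=summary.IDB_g,
            PH_cm=summary.PH_cm,
            DTM_d=summary.DTM_d,
        )

    table = summary.copy()
    for t in traits:
        a, b = _affine_for(cal, t, direction)
        base = t.removesuffix("_mean")
        mean_col = t if t in table.columns else f"{base}_mean"
        if mean_col not in table.columns:
            raise ValueError(f"summary table has no column for trait {t!r}")
        table[mean_col] = a * table[mean_col] + b
        if f"{base}_sd" in table.columns:
            table[f"{base}_sd"] = abs(a) * table[f"{base}_sd"]
    table["state"] = "dry" if direction == "fresh_to_dry" else "fresh"
    return table


def _affine_for(cal: CalibrationMap, trait: str, direction: str) -> tuple[float, float]:
    if trait not in cal.traits:
        raise ValueError(f"no calibration fitted for trait {trait!r}")
    c = cal.traits[trait]
    if not c.calibratable:
        raise ValueError(
            f"trait {trait!r} not calibratable (R²={c.r2:.3f} ≤ gate {cal.r2_gate})"
        )
    if direction == "fresh_to_dry":
        return c.slope, c.intercept
    return 1.0 / c.slope, -c.intercept / c.slope


@dataclass(frozen=True)
class HeritabilityResult:
    """Variance components and broad-sense heritability of one trait."""

    h2: float
    v_g: float
    v_w: float
    ms_between: float
    ms_within: float
    k1: float
    n_genotypes: int
    n_plants: int


def broad_sense_heritability(
    table: pd.DataFrame, trait: str, genotype_col: str = "genotype_id"
) -> HeritabilityResult:
    """Clonal-repeatability estimate of H² = V_G / (V_G + V_W).

    One-way random-effects method of moments over genotype groups; see the
    module docstring for the estimator.  Requires at least two genotypes and
    within-genotype replication somewhere in the table.
    """
    vals = table[[genotype_col, trait]].dropna()
    groups = [g.to_numpy(dtype=float) for _, g in vals.groupby(genotype_col)[trait]]
    g = len(groups)
    n_i = np.array([len(x) for x in groups], dtype=float)
    n = float(n_i.sum())
    if g < 2:
        raise ValueError("heritability needs at least 2 genotypes")
    if np.all(n_i < 2):
        raise ValueError("no within-genotype replication")

    grand = float(np.concatenate(groups).mean())
    means = np.array([x.mean() for x in groups])
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(sum(np.sum((x - m) ** 2) for x, m in zip(groups, means)))
    df_between = g - 1
    df_within = int(n) - g
    if df_within <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    k1 = (n - float(np.sum(n_i**2)) / n) / df_between
    v_g = max((ms_between - ms_within) / k1, 0.0)
    v_w = ms_within
    v_p = v_g + v_w
    h2 = v_g / v_p if v_p > 0 else 0.0
    return HeritabilityResult(
        h2=float(h2),
        v_g=float(v_g),
        v_w=float(v_w),
        ms_between=float(ms_between),
        ms_within=float(ms_within),
        k1=float(k1),
        n_genotypes=g,
        n_plants=int(n),
    )


def correlation_matrix(
    table: pd.DataFrame, traits: list[str], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with significance blanking.

    Returns ``(r, p)`` DataFrames over the requested traits; entries of ``r``
    with p-value above ``alpha`` are blanked to NaN (the diagonal stays 1).
    Pairwise-complete observations; a constant trait yields NaN entries.
    """
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            x = table[traits[i]].to_numpy(dtype=float)
            y = table[traits[j]].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            x, y = x[keep], y[keep]
            if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij = float("nan"), float("nan")
            else:
                res = _stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            if not (pij <= alpha):
                rij_shown = float("nan")
            else:
                rij_shown = rij
            r.iloc[i, j] = r.iloc[j, i] = rij_shown
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p
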