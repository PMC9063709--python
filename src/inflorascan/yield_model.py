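"""Intra-plant yield distribution and the width-based dry-biomass predictor.

Individual inflorescences are not weighed; instead each plant's measured dry
biomass (IDB, grams) is apportioned over its inflorescences proportionally to
their 2-D surface area, via the plant's own grams-per-cm² density
IDB / TIC.  On those per-object weights one can ask what fraction of the
inflorescence count must be picked (largest first) to accumulate a given
share of the yield.

The predictor estimates a plant's IDB from the mean width of its longest
inflorescences (default: the 20 longest), IDB = β₁·IW + β₀.  The published
coefficients (β₁ = 59.14 g/cm, β₀ = −134.97 g, fitted on plants with mean
IW > 2.5 cm) ship as named defaults, but they are environment-specific —
refit on local data whenever any is available.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class WeightedInflorescences:
    """Size-proportional per-object weights for one plant."""

    plant_id: str
    density_g_per_cm2: float
    object_ids: np.ndarray
    weights_g: np.ndarray

    @property
    def total_g(self) -> float:
        return float(self.weights_g.sum())


def apportion_weights(
    idb_g: float, records: pd.DataFrame, plant_id: str = ""
) -> WeightedInflorescences:
    """Distribute a plant's dry biomass over its objects proportionally to area.

    ``records`` needs ``object_id`` and ``IS_cm2`` columns.  The plant's
    density is IDB/TIC and each weight is density·IS, so the weights sum back
    to IDB exactly (to floating-point round-off).
    """
    if idb_g is None or not np.isfinite(idb_g):
        raise ValueError("IDB is required to apportion weights")
    if idb_g <= 0:
        raise ValueError("IDB must be positive")
    if len(records) == 0:
        raise ValueError("no object records")
    sizes = records["IS_cm2"].to_numpy(dtype=float)
    tic = float(sizes.sum())
    if tic <= 0:
        raise ValueError("TIC must be positive to apportion weights")
    density = idb_g / tic
    return WeightedInflorescences(
        plant_id=str(plant_id),
        density_g_per_cm2=density,
        object_ids=records["object_id"].to_numpy(),
        weights_g=density * sizes,
    )


def yield_threshold_fraction(weights: WeightedInflorescences | np.ndarray, q: float) -> float:
    """Percent of inflorescences needed (largest first) to reach a yield share.

    Sorts weights in descending order (ties broken by object id, i.e. input
    order) and returns ``100·k/N`` for the minimal ``k`` whose cumulative
    weight reaches ``q`` of the total.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    w = weights.weights_g if isinstance(weights, WeightedInflorescences) else np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("no weights")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(-w, kind="stable")
    csum = np.cumsum(w[order])
    total = csum[-1]
    k = int(np.searchsorted(csum, q * total - 1e-12 * total) + 1)
    k = min(k, w.size)
    return 100.0 * k / w.size


def top_longest_mean_width(records: pd.DataFrame, k: int = 20) -> float:
    """Mean width of the ``k`` longest inflorescences of a plant.

    Selection is by descending length; ties break toward the larger width,
    then the smaller object id (fully deterministic).  When the plant has
    fewer than ``k`` objects all of them are used, with a warning.
    """
    if len(records) == 0:
        raise ValueError("no object records")
    if k < 1:
        raise ValueError("k must be at least 1")
    if len(records) < k:
        warnings.warn(
            f"only {len(records)} objects available for a top-{k} selection; using all",
            stacklevel=2,
        )
    ranked = records.sort_values(
        ["IL_cm", "IW_cm", "object_id"], ascending=[False, False, True], kind="stable"
    )
    return float(ranked["IW_cm"].head(k).mean())


@dataclass(frozen=True)
class PredictionModel:
    """Linear width→biomass predictor with its fit domain."""

    slope: float  # g per cm of mean width
    intercept: float  # g
    k_longest: int = 20
    min_mean_iw_cm: float = 2.5
    provenance: str = "refitted"

    def __post_init__(self) -> None:
        if self.k_longest < 1:
            raise ValueError("k_longest must be at least 1")


#: Coefficients published for the original cultivation environment
#: (IDB = 59.14·IW − 134.97, mean width of the 20 longest inflorescences,
#: fitted on plants with mean IW > 2.5 cm).  Accuracy outside that
#: environment is not guaranteed — prefer refitting on local data.
PUBLISHED_DEFAULT_MODEL = PredictionModel(
    slope=59.14, intercept=-134.97, k_longest=20, min_mean_iw_cm=2.5,
    provenance="published_default",
)


def predict_idb(mean_iw_cm: float, model: PredictionModel = PUBLISHED_DEFAULT_MODEL) -> float:
    """Predict a plant's inflorescence dry biomass (grams) from its mean width.

    The input should be the *fresh-equivalent* mean width of the plant's
    ``model.k_longest`` longest inflorescences.  Widths at or below the
    model's fit domain (default 2.5 cm) trigger a warning, not an error: the
    line was fitted above that domain and extrapolates poorly below it.
    """
    if not (mean_iw_cm > 0 and np.isfinite(mean_iw_cm)):
        raise ValueError("mean width must be a positive finite number")
    if mean_iw_cm <= model.min_mean_iw_cm:
        warnings.warn(
            f"mean IW {mean_iw_cm:.2f} cm is at or below the model's fit domain "
            f"(> {model.min_mean_iw_cm} cm); prediction is an extrapolation",
            stacklevel=2,
        )
    return model.intercept + model.slope * mean_iw_cm


@dataclass(frozen=True)
class RefitResult:
    """OLS refit of the width→biomass line on a local population."""

    model: PredictionModel
    r2: float
    f_stat: float
    df: tuple[int, int]
    n: int
    p_value: float


def refit_prediction(
    table: pd.DataFrame,
    min_mean_iw_cm: float = 2.5,
    k_longest: int = 20,
    iw_col: str = "mean_IW_cm",
    idb_col: str = "IDB_g",
) -> RefitResult:
    """Refit the IDB-on-width line by ordinary least squares.

    ``table`` holds one row per plant with its top-k mean width and measured
    IDB; rows at or below ``min_mean_iw_cm`` are excluded before fitting,
    mirroring the predictor's fit domain.  Reports R² and the regression
    F-statistic with (1, n−2) degrees of freedom.
    """
    data = table[[iw_col, idb_col]].dropna()
    data = data[data[iw_col] > min_mean_iw_cm]
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 plants above the width filter, got {n}")
    x = data[iw_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mean width")
    y = data[idb_col].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    model = PredictionModel(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        k_longest=k_longest,
        min_mean_iw_cm=min_mean_iw_cm,
        provenance="refitted",
    )
    return RefitResult(
        model=model,
        r2=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        df=(1, n - 2),
        n=n,
        p_value=float(fit.f_pvalue),
    )


@dataclass(frozen=True)
class SamplingResult:
    """Subsample means of the top-width set and their dispersal."""

    m: int
    rounds: int
    means: np.ndarray
    full_mean: float

    @property
    def min(self) -> float:
        return float(self.means.min())

    @property
    def max(self) -> float:
        return float(self.means.max())

    @property
    def max_rel_deviation(self) -> float:
        """Largest |subsample mean − full mean| / full mean over the rounds."""
        if self.full_mean == 0:
            return float("nan")
        return float(np.max(np.abs(self.means - self.full_mean)) / abs(self.full_mean))


def sampling_simulation(
    top_widths: np.ndarray, m: int, rounds: int = 10, seed: int | None = None
) -> SamplingResult:
    """How stable is the mean width when only ``m`` of the top-k are measured?

    Draws ``rounds`` subsamples of size ``m`` without replacement from the
    plant's top-k width set and reports each subsample mean plus its dispersal
    around the full-set mean.  With ``m`` equal to the set size every round
    reproduces the full mean exactly.
    """
    w = np.asarray(top_widths, dtype=float)
    k = w.size
    if k == 0:
        raise ValueError("empty width set")
    if not 1 <= m <= k:
        raise ValueError(f"subsample size m={m} must lie in 1..{k}")
    if rounds < 1:
        raise ValueError("rounds must be at least 1")
    rng = np.random.default_rng(seed)
    means = np.array([rng.choice(w, size=m, replace=False).mean() for _ in range(rounds)])
    return SamplingResult(m=m, rounds=rounds, means=means, full_mean=float(w.mean()))
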