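"""Day-level proportions, the sigmoid recovery model and the recovery score.

Ground-truth class proportions come from rough color annotations: broad
pen strokes in the class palette over each training slide, with white for
unannotated or non-tissue regions.  Per day j, the palette pixels of all
that day's annotations are pooled and normalized to a proportion vector
p_j on the K-simplex.

A slide's recovery over days is modeled by the sigmoid
sigma(x) = 1 / (1 + exp(-a (x - d))) with gain a (speed of recovery) and
inflection day d (switch to recovery); the defaults a = 0.65, d = 6 match
the cardiotoxin-injury time course.  Class weights omega in [0, 1]^K are
fitted by ordinary least squares so that p_j . omega tracks sigma(j), and
the recovery score of any slide is the weighted proportion

    RecoveryScore = p_hat . omega = sum_k p_hat_k * omega_k  in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .scheme import ClassScheme, DEFAULT_SCHEME, NO_DETECTION


@dataclass(frozen=True)
class SigmoidModel:
    """Recovery-over-days sigmoid: gain ``a`` > 0, inflection day ``d``."""

    a: float = 0.65
    d: float = 6.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("sigmoid gain a must be > 0")


def sigmoid(x, model: SigmoidModel = SigmoidModel()) -> np.ndarray | float:
    """sigma(x) = 1 / (1 + exp(-a (x - d))), strictly increasing in x."""
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-model.a * (x - model.d)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# proportions from annotations and class maps

@dataclass
class DayProportionTable:
    """Per-day class proportions p_j plus the raw per-class pixel counts."""

    proportions: dict[int, np.ndarray]
    pixel_counts: dict[int, np.ndarray]
    scheme: ClassScheme = DEFAULT_SCHEME

    @property
    def days(self) -> list[int]:
        return sorted(self.proportions)

    def __getitem__(self, day: int) -> np.ndarray:
        return self.proportions[day]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for day in self.days:
            row = {"day": day}
            for k, name in enumerate(self.scheme.names):
                row[f"p_{name}"] = self.proportions[day][k]
                row[f"px_{name}"] = int(self.pixel_counts[day][k])
            rows.append(row)
        return pd.DataFrame(rows)


def _count_palette_pixels(
    raster: np.ndarray, scheme: ClassScheme, snap_tolerance: float | None
) -> np.ndarray:
    """Per-class pixel counts of one annotation raster (white ignored)."""
    raster = np.asarray(raster)
    flat = raster.reshape(-1, 3).astype(np.int64)
    counts = np.zeros(scheme.K, dtype=np.int64)
    if snap_tolerance is None:
        for k, color in enumerate(scheme.colors):
            counts[k] = np.all(flat == np.asarray(color), axis=1).sum()
    else:
        palette = np.asarray(scheme.colors + (scheme.sentinel_color,), dtype=np.int64)
        d2 = ((flat[:, None, :] - palette[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        ok = d2[np.arange(len(flat)), nearest] <= snap_tolerance**2
        for k in range(scheme.K):
            counts[k] = ((nearest == k) & ok).sum()
    return counts


def proportions_from_annotations(
    annotations_by_day: dict[int, list[np.ndarray]],
    scheme: ClassScheme = DEFAULT_SCHEME,
    snap_tolerance: float | None = None,
) -> DayProportionTable:
    """Pool rough-annotation pixel counts per day into proportions p_j.

    Palette colors are matched exactly by default; ``snap_tolerance``
    (Euclidean RGB distance) enables nearest-palette snapping for
    annotations that went through lossy encoding.  White (and anything
    off-palette) is ignored.  Splitting a day's annotation into several
    rasters does not change the result (pure pixel pooling).
    """
    proportions, counts = {}, {}
    for day, rasters in annotations_by_day.items():
        total = np.zeros(scheme.K, dtype=np.int64)
        for raster in rasters:
            total += _count_palette_pixels(raster, scheme, snap_tolerance)
        if total.sum() == 0:
            raise ValueError(f"day {day}: no annotated (palette) pixels; "
                             "proportion undefined")
        counts[int(day)] = total
        proportions[int(day)] = total / total.sum()
    return DayProportionTable(proportions, counts, scheme)


def classmap_proportions(
    class_raster: np.ndarray,
    cell_mask: np.ndarray,
    K: int | None = None,
    scheme: ClassScheme = DEFAULT_SCHEME,
    sentinel: int = NO_DETECTION,
) -> np.ndarray:
    """Class proportions of a slide's class map, relative to the cell area.

    ``class_raster`` holds integer class codes (sentinel = no detection);
    only pixels inside ``cell_mask`` are counted.
    """
    K = K or scheme.K
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask: proportions undefined")
    vals = np.asarray(class_raster)[cell_mask]
    counts = np.array([(vals == k).sum() for k in range(K)], dtype=np.float64)
    if counts.sum() == 0:
        raise ValueError("cell mask contains no classified pixels")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# recovery weights and score

@dataclass(frozen=True)
class RecoveryWeights:
    """Per-class weights omega in [0, 1]^K plus the pre-clip LS residual."""

    omega: np.ndarray
    fit_residual: float
    omega_raw: np.ndarray | None = None


def fit_weights(P, days, model: SigmoidModel = SigmoidModel()) -> RecoveryWeights:
    """Least-squares fit of omega so that P @ omega tracks sigma(days).

    ``P`` is an (M, K) matrix of per-slide (or per-day) true proportions
    and ``days`` the matching day labels.  Solved with
    ``numpy.linalg.lstsq`` (minimum-norm solution when P is
    rank-deficient, with a warning); the solution is then clipped to
    [0, 1] and the pre-clip residual reported so active clipping is
    detectable.
    """
    P = np.asarray(P, dtype=np.float64)
    days = np.asarray(days, dtype=np.float64)
    if P.ndim != 2 or len(days) != P.shape[0]:
        raise ValueError("P must be (M, K) with one day per row")
    targets = sigmoid(days, model)
    omega_raw, _, rank, _ = np.linalg.lstsq(P, np.atleast_1d(targets), rcond=None)
    if rank < P.shape[1]:
        warnings.warn(
            f"proportion design is rank-deficient (rank {rank} < K={P.shape[1]}); "
            "minimum-norm weights returned", RuntimeWarning, stacklevel=2)
    residual = float(np.linalg.norm(P @ omega_raw - targets))
    return RecoveryWeights(np.clip(omega_raw, 0.0, 1.0), residual, omega_raw)


def recovery_score(p_hat, weights: RecoveryWeights | np.ndarray) -> float:
    """RecoveryScore = sum_k p_hat_k * omega_k (in [0, 1])."""
    omega = weights.omega if isinstance(weights, RecoveryWeights) else np.asarray(weights)
    p_hat = np.asarray(p_hat, dtype=np.float64)
    if p_hat.shape != omega.shape:
        raise ValueError("proportion and weight vectors differ in length")
    return float(p_hat @ omega)


@dataclass
class RecoverySummary:
    """Per-slide summary: score, cell-area rate and class proportions."""

    slide_id: str
    recovery_score: float
    cell_area_rate: float
    color_proportions: np.ndarray
    day: int | None = None


# ---------------------------------------------------------------------------
# model-style wrapper

class RecoveryScoreModel:
    """Recovery-score weight model, statsmodels-style.

    Built from a proportion design (per-slide rows P and day labels) and a
    :class:`SigmoidModel`; :meth:`fit` returns a
    :class:`RecoveryScoreResults` whose :meth:`~RecoveryScoreResults.score`
    maps any proportion vector to its recovery score.
    """

    def __init__(self, P, days, sigmoid_model: SigmoidModel = SigmoidModel(),
                 scheme: ClassScheme = DEFAULT_SCHEME) -> None:
        self.P = np.asarray(P, dtype=np.float64)
        self.days = np.asarray(days)
        self.sigmoid_model = sigmoid_model
        self.scheme = scheme

    @classmethod
    def from_table(cls, table: DayProportionTable,
                   sigmoid_model: SigmoidModel = SigmoidModel()) -> "RecoveryScoreModel":
        days = table.days
        P = np.vstack([table[j] for j in days])
        return cls(P, days, sigmoid_model, table.scheme)

    def fit(self) -> "RecoveryScoreResults":
        return RecoveryScoreResults(self, fit_weights(self.P, self.days, self.sigmoid_model))


class RecoveryScoreResults:
    def __init__(self, model: RecoveryScoreModel, weights: RecoveryWeights) -> None:
        self.model = model
        self.weights = weights

    @property
    def omega(self) -> np.ndarray:
        return self.weights.omega

    @property
    def fit_residual(self) -> float:
        return self.weights.fit_residual

    def score(self, p_hat) -> float:
        return recovery_score(p_hat, self.weights)

    def fitted_scores(self) -> np.ndarray:
        """Score of each design row (the fitted sigma(day) approximations)."""
        return self.model.P @ self.weights.omega

    def summary(self) -> str:
        m = self.model
        lines = [
            "Recovery-score weights (least squares against sigmoid recovery)",
            "=" * 64,
            f"sigmoid: a = {m.sigmoid_model.a}, d = {m.sigmoid_model.d} [day]",
            f"design: {m.P.shape[0]} rows x {m.P.shape[1]} classes",
            "omega (clipped to [0,1]): "
            + "  ".join(f"{name}={w:.4f}" for name, w in zip(m.scheme.names, self.omega)),
            f"pre-clip residual ||P w - sigma||: {self.fit_residual:.6f}",
        ]
        if self.weights.omega_raw is not None and np.any(
            (self.weights.omega_raw < 0) | (self.weights.omega_raw > 1)
        ):
            lines.append("note: clipping active (raw weights outside [0,1])")
        return "\n".join(lines)
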