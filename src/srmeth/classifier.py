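"""Pattern-score classifier for DRM2-like vs CMT2-like CHH methylation.

Regions methylated by the two plant CHH methyltransferases differ in how
methylation varies across reads and sites: DRM2 targets show a bimodal
read population (fully methylated vs nearly unmethylated reads → high
read-methylation SD, low stochasticity) while CMT2 targets look like
independent per-site noise (high stochasticity, read-methylation SD near
the binomial null). A linear probability model — ordinary least squares of
a 0/1 class label on the four region features — captures this separation;
the raw linear predictor is affinely rescaled by its training min/max so
that the resulting *pattern score* lies in [0, 1], with 0 = DRM2-like and
1 = CMT2-like. Scores of unseen data falling outside the training range
are clipped.

Genome-level analysis asks how many methylation "pattern signals" a sample
contains by counting peaks of a Gaussian KDE (Scott's-rule bandwidth) of
element pattern scores: one peak = a single dominant enzyme activity, two
peaks = both activities present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.signal import find_peaks
from sklearn.metrics import roc_curve

from .features import FEATURE_NAMES, ElementSummary, RegionFeatures

__all__ = [
    "PatternModel",
    "RocResult",
    "KdePeaks",
    "fit_pattern_model",
    "pattern_score",
    "pattern_score_array",
    "score_elements",
    "roc",
    "kde_peaks",
]


@dataclass(frozen=True)
class PatternModel:
    """Fitted linear classifier plus the affine [0, 1] scaling."""

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    scale_low: float
    scale_high: float
    per_feature_r2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_low >= self.scale_high:
            raise ValueError("scale_low must be < scale_high")
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")

    def raw_score(self, x: np.ndarray) -> np.ndarray:
        """Unscaled linear predictor for rows of feature values."""
        return self.intercept + np.asarray(x, dtype=float) @ np.asarray(
            self.coefficients
        )

    def save(self, path: str | Path) -> None:
        """Plain-text key = value serialization."""
        with open(path, "w") as handle:
            handle.write(f"features = {','.join(self.feature_names)}\n")
            for name, coef in zip(self.feature_names, self.coefficients):
                handle.write(f"coef.{name} = {coef!r}\n")
            handle.write(f"intercept = {self.intercept!r}\n")
            handle.write(f"scale_low = {self.scale_low!r}\n")
            handle.write(f"scale_high = {self.scale_high!r}\n")
            for name, r2 in self.per_feature_r2.items():
                handle.write(f"r2.{name} = {r2!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PatternModel":
        values: dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                if "=" in line:
                    key, _, val = line.partition("=")
                    values[key.strip()] = val.strip()
        names = tuple(values["features"].split(","))
        return cls(
            feature_names=names,
            coefficients=tuple(float(values[f"coef.{n}"]) for n in names),
            intercept=float(values["intercept"]),
            scale_low=float(values["scale_low"]),
            scale_high=float(values["scale_high"]),
            per_feature_r2={
                n: float(values[f"r2.{n}"]) for n in names if f"r2.{n}" in values
            },
        )


def _design_matrix(
    features: Sequence[RegionFeatures | ElementSummary],
    names: Sequence[str],
) -> np.ndarray:
    rows = []
    for f in features:
        try:
            rows.append([getattr(f, n) for n in names])
        except AttributeError as err:
            raise KeyError(f"feature missing from input: {err}") from err
    return np.asarray(rows, dtype=float)


def fit_pattern_model(
    regions_0: Sequence[RegionFeatures],
    regions_1: Sequence[RegionFeatures],
    feature_names: Sequence[str] = FEATURE_NAMES,
    min_meth: float = 0.10,
) -> PatternModel:
    """Fit the linear probability model on two labeled region sets.

    ``regions_0`` carries label 0 (DRM2-like reference sample) and
    ``regions_1`` label 1 (CMT2-like). Regions below ``min_meth`` mean
    methylation are excluded before fitting. Constant features are dropped
    with a warning (singular design otherwise). The scaling bounds are the
    min/max raw predictor over the training data, so training scores span
    exactly [0, 1]; marginal r² of each feature against the label is
    recorded.
    """
    keep0 = [f for f in regions_0 if f.mean_read_meth >= min_meth]
    keep1 = [f for f in regions_1 if f.mean_read_meth >= min_meth]
    if not keep0 or not keep1:
        raise ValueError("both classes must be non-empty after the methylation filter")

    names = list(feature_names)
    X = _design_matrix(keep0 + keep1, names)
    y = np.concatenate([np.zeros(len(keep0)), np.ones(len(keep1))])

    constant = [n for n, col in zip(names, X.T) if np.ptp(col) == 0]
    if constant:
        warnings.warn(f"dropping constant feature(s): {', '.join(constant)}")
        keep_cols = [i for i, n in enumerate(names) if n not in constant]
        names = [names[i] for i in keep_cols]
        X = X[:, keep_cols]
    if not names:
        raise ValueError("all features constant; cannot fit")

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    intercept = float(fit.params[0])
    coefficients = tuple(float(c) for c in fit.params[1:])

    raw = intercept + X @ np.asarray(coefficients)
    per_feature_r2 = {}
    for name, col in zip(names, X.T):
        res = sps.linregress(col, y)
        per_feature_r2[name] = float(res.rvalue**2)

    return PatternModel(
        feature_names=tuple(names),
        coefficients=coefficients,
        intercept=intercept,
        scale_low=float(raw.min()),
        scale_high=float(raw.max()),
        per_feature_r2=per_feature_r2,
    )


def pattern_score_array(model: PatternModel, X: np.ndarray) -> np.ndarray:
    """Scaled, clipped pattern scores for rows of feature values."""
    raw = model.raw_score(X)
    scaled = (raw - model.scale_low) / (model.scale_high - model.scale_low)
    return np.clip(scaled, 0.0, 1.0)


def pattern_score(model: PatternModel, features: RegionFeatures | ElementSummary) -> float:
    """Pattern score in [0, 1] of one region or element."""
    x = _design_matrix([features], model.feature_names)
    return float(pattern_score_array(model, x)[0])


def score_elements(
    model: PatternModel, element_summaries: Iterable[ElementSummary]
) -> list[ElementSummary]:
    """Attach pattern scores to element summaries (element-mean features)."""
    return [
        replace(summary, pattern_score=pattern_score(model, summary))
        for summary in element_summaries
    ]


@dataclass(frozen=True)
class RocResult:
    """ROC curve points plus the trapezoidal area under the curve."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def roc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC by threshold sweep over the unique scores; trapezoidal AUC.

    Requires both labels present. Degenerate all-equal scores give the
    chance diagonal (AUC 0.5).
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=tuple(fpr), tpr=tuple(tpr), auc=auc)


@dataclass(frozen=True)
class KdePeaks:
    """Gaussian-KDE density of pattern scores and its detected peaks."""

    grid: tuple[float, ...]
    density: tuple[float, ...]
    peak_positions: tuple[float, ...]

    @property
    def n_peaks(self) -> int:
        return len(self.peak_positions)


def kde_peaks(
    values: Sequence[float],
    grid_size: int = 512,
    prominence_frac: float = 0.05,
) -> KdePeaks:
    """Count pattern-signal peaks in a sample's score distribution.

    Gaussian KDE with Scott's-rule bandwidth (σ̂·n^(−1/5)), evaluated on a
    fixed grid over [0, 1]; peaks are local maxima with prominence above
    ``prominence_frac`` of the global maximum. The density is padded below
    its minimum before peak finding so a maximum at a grid boundary still
    counts (clipped scores can concentrate at 0 or 1). Requires ≥ 10
    values; a zero-variance sample degenerates to a single peak at the
    common value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("kde_peaks requires at least 10 values")
    grid = np.linspace(0.0, 1.0, grid_size)
    if np.ptp(values) == 0:
        density = np.zeros(grid_size)
        idx = int(np.argmin(np.abs(grid - values[0])))
        density[idx] = 1.0
        return KdePeaks(tuple(grid), tuple(density), (float(grid[idx]),))
    kde = sps.gaussian_kde(values, bw_method="scott")
    density = kde(grid)
    padded = np.concatenate([[density.min() - 1.0], density, [density.min() - 1.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * density.max())
    peaks = peaks - 1
    return KdePeaks(
        grid=tuple(grid),
        density=tuple(density),
        peak_positions=tuple(float(grid[i]) for i in peaks),
    )
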