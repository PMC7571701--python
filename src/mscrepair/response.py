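"""Dose-response curves and defect-severity surfaces.

Given a trained ensemble, sweep one descriptor (e.g. implantation cell
number) or two (defect area and depth percentage) over a grid while all
other descriptors are held at a reference vector, impute the outcome at
every grid point, and normalize the predicted repair score against the full
range of scores in the database.  Each grid point carries the ensemble
standard deviation, and points outside the training range of the varied
descriptor are flagged as extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, PropertyVector
from .ensemble import Ensemble
from .imputation import ImputeConfig, impute_ensemble_members

__all__ = [
    "ResponseGrid",
    "normalize_to_db_range",
    "build_reference",
    "response_curve",
    "response_surface",
    "detect_thresholds",
]


def normalize_to_db_range(score: float | np.ndarray, data: Dataset) -> np.ndarray | float:
    """Rescale a predicted score against the observed outcome range.

    0 maps to the worst and 1 to the best outcome present in the database;
    extrapolated predictions may fall outside [0, 1] and are returned as-is.
    """
    outcomes = data.values[data.mask[:, -1], -1]
    if outcomes.size == 0:
        raise ValueError("no observed outcomes in the database")
    lo, hi = float(outcomes.min()), float(outcomes.max())
    if lo == hi:
        raise ValueError("degenerate outcome range in the database")
    return (score - lo) / (hi - lo)


def build_reference(data: Dataset) -> PropertyVector:
    """Default fixed-condition vector: per-slot mean of observed values.

    Indicator slots get their rounded frequency (the modal level); the
    outcome slot is left missing so prediction always goes through the
    fixed-point imputation.
    """
    means = data.column_means()
    values = means.copy()
    for j in range(data.width - 1):
        observed = data.values[data.mask[:, j], j]
        if observed.size and set(np.unique(observed)) <= {0.0, 1.0}:
            values[j] = float(round(means[j]))
    mask = np.isfinite(values)
    values[-1] = np.nan
    mask[-1] = False
    return PropertyVector(values, mask)


@dataclass
class ResponseGrid:
    """Predicted (normalized) repair score over a 1-D or 2-D descriptor grid."""

    properties: list[str]
    grids: list[np.ndarray]
    score: np.ndarray          # normalized to the database score range
    raw_score: np.ndarray      # unnormalized predicted outcome
    std: np.ndarray            # ensemble standard deviation per grid point
    extrapolated: np.ndarray   # outside the training range of the varied axes
    reference: PropertyVector = field(repr=False, default=None)

    @property
    def ndim(self) -> int:
        return len(self.grids)


def _predict_point(ens: Ensemble, x: PropertyVector, data: Dataset,
                   cfg: ImputeConfig) -> tuple[float, float]:
    completed = impute_ensemble_members(ens, x, data, cfg)
    outs = completed[:, -1]
    return float(outs.mean()), float(outs.std(ddof=0))


def _training_range(data: Dataset, col: int) -> tuple[float, float]:
    observed = data.values[data.mask[:, col], col]
    if observed.size == 0:
        return float("inf"), float("-inf")
    return float(observed.min()), float(observed.max())


def response_curve(ens: Ensemble, prop: str, grid: np.ndarray,
                   data: Dataset, reference: PropertyVector | None = None,
                   impute_cfg: ImputeConfig | None = None) -> ResponseGrid:
    """Predicted repair score as one descriptor sweeps a grid.

    ``reference`` defaults to :func:`build_reference`; the outcome slot of
    every assembled vector is masked and recovered by per-member imputation,
    so each point's uncertainty is the member spread.
    """
    columns = ens.columns or data.columns
    if prop not in columns[:-1]:
        raise ValueError(f"{prop!r} is not a model descriptor")
    impute_cfg = impute_cfg or ImputeConfig()
    reference = reference or build_reference(data)
    j = columns.index(prop)
    grid = np.asarray(grid, dtype=float)
    score = np.empty(grid.shape)
    std = np.empty(grid.shape)
    for g, val in enumerate(grid):
        x = reference.copy()
        x.values[j] = val
        x.mask[j] = True
        x.values[-1] = np.nan
        x.mask[-1] = False
        score[g], std[g] = _predict_point(ens, x, data, impute_cfg)
    lo, hi = _training_range(data, j)
    extrapolated = (grid < lo) | (grid > hi)
    return ResponseGrid([prop], [grid], np.asarray(normalize_to_db_range(score, data)),
                        score, std, extrapolated, reference)


def response_surface(ens: Ensemble, prop1: str, prop2: str,
                     grid1: np.ndarray, grid2: np.ndarray, data: Dataset,
                     reference: PropertyVector | None = None,
                     impute_cfg: ImputeConfig | None = None) -> ResponseGrid:
    """Predicted repair score over the Cartesian grid of two descriptors.

    ``score[a, b]`` corresponds to ``grid1[a], grid2[b]``; swapping the two
    descriptors transposes the surface.  A point is flagged as extrapolated
    when either coordinate leaves its training range.
    """
    columns = ens.columns or data.columns
    for p in (prop1, prop2):
        if p not in columns[:-1]:
            raise ValueError(f"{p!r} is not a model descriptor")
    impute_cfg = impute_cfg or ImputeConfig()
    reference = reference or build_reference(data)
    j1, j2 = columns.index(prop1), columns.index(prop2)
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    score = np.empty((grid1.size, grid2.size))
    std = np.empty_like(score)
    for a, v1 in enumerate(grid1):
        for b, v2 in enumerate(grid2):
            x = reference.copy()
            x.values[j1], x.values[j2] = v1, v2
            x.mask[j1] = x.mask[j2] = True
            x.values[-1] = np.nan
            x.mask[-1] = False
            score[a, b], std[a, b] = _predict_point(ens, x, data, impute_cfg)
    lo1, hi1 = _training_range(data, j1)
    lo2, hi2 = _training_range(data, j2)
    extrapolated = ((grid1 < lo1) | (grid1 > hi1))[:, None] | \
                   ((grid2 < lo2) | (grid2 > hi2))[None, :]
    return ResponseGrid([prop1, prop2], [grid1, grid2],
                        np.asarray(normalize_to_db_range(score, data)),
                        score, std, extrapolated, reference)


def detect_thresholds(curve: ResponseGrid,
                      slope_threshold: float | None = None) -> list[tuple[float, float]]:
    """Candidate critical-size intervals on a 1-D response curve.

    Flags grid intervals whose finite-difference slope of the normalized
    score is negative and strictly below a threshold; the default threshold
    is the steepest quartile of all interval slopes.  Heuristic and
    exploratory: returned breakpoints are readouts of the fitted model, not
    constants of the method.
    """
    if curve.ndim != 1:
        raise ValueError("threshold detection expects a 1-D curve")
    grid = curve.grids[0]
    if grid.size < 5:
        raise ValueError("need at least 5 grid points")
    slopes = np.diff(curve.score) / np.diff(grid)
    thr = float(np.quantile(slopes, 0.25)) if slope_threshold is None else slope_threshold
    flagged = np.nonzero((slopes < thr) & (slopes < 0))[0]
    return [(float(grid[i]), float(grid[i + 1])) for i in flagged]
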