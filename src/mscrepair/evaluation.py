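"""Validation, screening, and anomaly detection.

Everything here scores the pipeline the way a small meta-analysis must be
scored: leave-one-out cross-validation (each entry predicted by an ensemble
trained on all the others, with its outcome hidden and read back from the
converged imputation), the coefficient of determination

    R^2 = 1 - sum_i (y_pred_i - y_actl_i)^2 / sum_i (y_actl_i - mean)^2 ,

confidence filtering (recompute R^2 on the fraction of entries with the
smallest ensemble uncertainty), standard-deviations-out anomaly flagging,
single-property screening with forward selection, correlation screening,
R^2-drop property influence, and two deliberately naive baselines (k-nearest
neighbours and the training-fold mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .ensemble import train_ensemble
from .imputation import ImputeConfig, impute_ensemble_members
from .network import TrainConfig

__all__ = [
    "CVResult",
    "ScreenResult",
    "SelectionResult",
    "r_squared",
    "loocv",
    "standard_deviations_out",
    "flag_anomalies",
    "confidence_filtered_r2",
    "single_property_screen",
    "correlation_screen",
    "forward_selection",
    "property_influence",
    "knn_baseline",
    "mean_baseline",
    "hidden_sweep",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def r_squared(pred: np.ndarray, actual: np.ndarray) -> float:
    """Coefficient of determination against the identity line.

    1 is a perfect fit; 0 matches predicting the mean of ``actual``
    everywhere; arbitrarily negative values are possible.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError("pred and actual must be equal-length 1-D arrays")
    if len(actual) < 2:
        raise ValueError("need at least two points")
    denom = float(((actual - actual.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("R^2 undefined: actual values are constant")
    return 1.0 - float(((pred - actual) ** 2).sum()) / denom


def standard_deviations_out(y_pred: float, y_actl: float, std: float) -> float:
    """Signed prediction error in units of the reported uncertainty.

    Positive means the model overpredicts the repair score (predicted better
    than observed); negative means underprediction.
    """
    if std < 0:
        raise ValueError("std must be >= 0")
    if std == 0.0:
        if y_pred == y_actl:
            return 0.0
        raise ValueError("infinite standard-deviations-out: std is zero")
    return (y_pred - y_actl) / std


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-entry LOOCV predictions plus the aggregate fit.

    ``table`` has one row per entry with a known outcome: the original row
    index, actual and predicted outcome, ensemble standard deviation, and
    standard-deviations-out.  ``member_outcomes`` (N, M) keeps each
    member's converged outcome so downstream code can resample members.
    """

    table: pd.DataFrame
    r2: float
    n: int
    member_outcomes: np.ndarray | None = field(default=None, repr=False)

    def member_r2(self) -> np.ndarray:
        """R^2 computed from each member's predictions alone."""
        if self.member_outcomes is None:
            raise ValueError("member outcomes were not recorded")
        actual = self.table["actual"].to_numpy()
        return np.array([
            r_squared(self.member_outcomes[:, m], actual)
            for m in range(self.member_outcomes.shape[1])
        ])


def _fold_seed(base_seed: int, data: Dataset, idx: int) -> int:
    # Content-derived, so predictions do not depend on storage order.
    return (int(base_seed) + data.row_digest(idx)) % (2**31)


def loocv(data: Dataset, train_cfg: TrainConfig | None = None,
          impute_cfg: ImputeConfig | None = None, n_members: int = 20,
          base_seed: int = 0) -> CVResult:
    """Leave-one-out cross-validation of the full pipeline.

    For every entry with a known outcome: train an ensemble on the remaining
    entries (training rows are put in a canonical order first, so fold
    results are invariant to how the dataset happens to be sorted), hide the
    held-out outcome, impute it through each member's fixed-point iteration,
    and record the member mean and population standard deviation.
    """
    train_cfg = train_cfg or TrainConfig()
    impute_cfg = impute_cfg or ImputeConfig()
    known = np.nonzero(data.mask[:, -1])[0]
    if len(known) < 3:
        raise ValueError("need at least 3 entries with a known outcome")
    rows = []
    member_outcomes = np.empty((len(known), n_members))
    for r, idx in enumerate(known):
        fold = data.drop_row(int(idx))
        fold = fold.subset_rows(fold.canonical_order())
        seed = _fold_seed(base_seed, data, int(idx))
        try:
            ens = train_ensemble(fold, train_cfg, n_members, base_seed=seed)
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"LOOCV training failed on fold {idx}") from exc
        x = data.entry(int(idx))
        actual = float(x.values[-1])
        x.values[-1] = np.nan
        x.mask[-1] = False
        completed = impute_ensemble_members(ens, x, fold, impute_cfg)
        outs = completed[:, -1]
        member_outcomes[r] = outs
        pred = float(outs.mean())
        std = float(outs.std(ddof=0))
        z = standard_deviations_out(pred, actual, std) if std > 0 else (
            0.0 if pred == actual else math.inf
        )
        rows.append({"entry": int(idx), "actual": actual, "pred": pred,
                     "std": std, "z": z})
    table = pd.DataFrame(rows)
    r2 = r_squared(table["pred"].to_numpy(), table["actual"].to_numpy())
    return CVResult(table, r2, len(known), member_outcomes)


# ---------------------------------------------------------------------------
# anomaly flagging and confidence filtering
# ---------------------------------------------------------------------------

def flag_anomalies(cv: CVResult, threshold: float = 1.0) -> pd.DataFrame:
    """Entries whose |standard-deviations-out| exceeds the threshold.

    Overpredicted entries (z > 0) come first in descending z, then
    underpredicted ones (z < 0) in ascending z — most extreme first on each
    side.
    """
    t = cv.table
    over = t[t["z"] > threshold].sort_values("z", ascending=False, kind="stable")
    under = t[t["z"] < -threshold].sort_values("z", ascending=True, kind="stable")
    over = over.assign(direction="overpredicted")
    under = under.assign(direction="underpredicted")
    return pd.concat([over, under], ignore_index=True)


def confidence_filtered_r2(cv: CVResult, fraction: float,
                           use_full_mean: bool = False) -> float:
    """R^2 over the ``fraction`` of entries with the smallest uncertainty.

    Entries are ranked by ensemble standard deviation (ties broken by
    original order); the retained subset's own outcome mean enters the
    denominator by default (``use_full_mean=True`` keeps the full-set mean).
    ``fraction=1`` reproduces the overall LOOCV R^2 exactly.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    t = cv.table
    keep = int(math.ceil(fraction * len(t)))
    order = np.argsort(t["std"].to_numpy(), kind="stable")
    retained = np.sort(order[:keep])  # restore original order
    sub = t.iloc[retained]
    actual = sub["actual"].to_numpy()
    pred = sub["pred"].to_numpy()
    if len(sub) < 2 or np.ptp(actual) == 0.0:
        raise ValueError(f"retained subset at fraction {fraction} is degenerate")
    if use_full_mean:
        denom = float(((actual - t["actual"].mean()) ** 2).sum())
        return 1.0 - float(((pred - actual) ** 2).sum()) / denom
    return r_squared(pred, actual)


# ---------------------------------------------------------------------------
# descriptor screening and selection
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Single-property screening: per-property R^2 and the induced ranking."""

    table: pd.DataFrame          # property, r2, r2_std
    ranking: list[str]


@dataclass
class SelectionResult:
    """Outcome of forward selection over the screened ranking."""

    chosen: list[str]
    prefix_trace: list[float]    # combined LOOCV R^2 at each prefix length k
    declined_after: int | None   # k beyond which the trace falls (overfitting)
    dataset: Dataset             # input restricted to chosen (consolidated) columns


def single_property_screen(data: Dataset, properties: list[str] | None = None,
                           train_cfg: TrainConfig | None = None,
                           impute_cfg: ImputeConfig | None = None,
                           n_members: int = 20, base_seed: int = 0) -> ScreenResult:
    """LOOCV R^2 of a model given one condition property at a time.

    The per-property uncertainty is the standard deviation of R^2 across
    member-wise predictions.  Properties are ranked by R^2 descending.
    """
    properties = properties or list(data.columns[:-1])
    rows = []
    for prop in properties:
        sub = data.select_columns([prop])
        if int(sub.mask[:, 0].sum()) < 3:
            raise ValueError(f"property {prop!r} has fewer than 3 known values")
        cv = loocv(sub, train_cfg, impute_cfg, n_members, base_seed)
        rows.append({"property": prop, "r2": cv.r2,
                     "r2_std": float(cv.member_r2().std(ddof=0))})
    table = pd.DataFrame(rows).sort_values(
        "r2", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return ScreenResult(table, table["property"].tolist())


def correlation_screen(data: Dataset, properties: list[str] | None = None):
    """Pairwise Pearson and Spearman matrices on pairwise-complete rows.

    Pairs with fewer than three complete observations are left NaN and
    excluded from the reported maximum absolute off-diagonal value.
    Returns ``(pearson, spearman, max_abs_offdiag)``.
    """
    properties = properties or list(data.columns[:-1])
    k = len(properties)
    idx = [data.columns.index(p) for p in properties]
    pear = np.full((k, k), np.nan)
    spear = np.full((k, k), np.nan)
    for a in range(k):
        pear[a, a] = spear[a, a] = 1.0
        for b in range(a + 1, k):
            both = data.mask[:, idx[a]] & data.mask[:, idx[b]]
            if both.sum() < 3:
                continue
            xa = data.values[both, idx[a]]
            xb = data.values[both, idx[b]]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            pear[a, b] = pear[b, a] = float(stats.pearsonr(xa, xb).statistic)
            spear[a, b] = spear[b, a] = float(stats.spearmanr(xa, xb).statistic)
    off = ~np.eye(k, dtype=bool)
    finite = off & np.isfinite(pear)
    finite_s = off & np.isfinite(spear)
    candidates = np.concatenate([np.abs(pear[finite]), np.abs(spear[finite_s])])
    max_off = float(candidates.max()) if candidates.size else math.nan
    pear_df = pd.DataFrame(pear, index=properties, columns=properties)
    spear_df = pd.DataFrame(spear, index=properties, columns=properties)
    return pear_df, spear_df, max_off


def forward_selection(screen: ScreenResult, data: Dataset,
                      train_cfg: TrainConfig | None = None,
                      impute_cfg: ImputeConfig | None = None,
                      n_members: int = 20, base_seed: int = 0,
                      with_trace: bool = True) -> SelectionResult:
    """Keep the screened properties with individually positive R^2.

    Also reports the combined LOOCV R^2 of every top-k prefix of the
    screened ranking (the overfitting diagnostic: the prefix trace falling
    past some k signals that further descriptors only fit noise;
    ``with_trace=False`` skips this costly diagnostic) and applies the
    bone-marrow/adipose tissue-source consolidation to the final set when
    both indicators survive selection.
    """
    by_prop = dict(zip(screen.table["property"], screen.table["r2"]))
    positives = [p for p in screen.ranking if by_prop[p] > 0]
    if not positives:
        raise ValueError("no screened property has a positive R^2")
    trace: list[float] = []
    declined_after: int | None = None
    if with_trace:
        for k in range(1, len(screen.ranking) + 1):
            sub = data.select_columns(screen.ranking[:k])
            trace.append(loocv(sub, train_cfg, impute_cfg, n_members, base_seed).r2)
        best_k = int(np.argmax(trace)) + 1
        if best_k < len(trace):
            declined_after = best_k
    chosen_data = data.select_columns(positives)
    chosen = list(positives)
    bm_ad = [c for c in chosen if c in ("tissue_source_BM", "tissue_source_AD")]
    if len(bm_ad) == 2:
        chosen_data = chosen_data.consolidate_columns(bm_ad, "tissue_BM_or_AD")
        chosen = [c for c in chosen_data.columns[:-1]]
    return SelectionResult(chosen, trace, declined_after, chosen_data)


def property_influence(data: Dataset, chosen: list[str],
                       train_cfg: TrainConfig | None = None,
                       impute_cfg: ImputeConfig | None = None,
                       n_members: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Importance as the drop in LOOCV R^2 when a property is removed."""
    if len(chosen) < 2:
        raise ValueError("need at least two chosen properties")
    full = loocv(data.select_columns(chosen), train_cfg, impute_cfg,
                 n_members, base_seed).r2
    rows = []
    for prop in chosen:
        rest = [p for p in chosen if p != prop]
        r2 = loocv(data.select_columns(rest), train_cfg, impute_cfg,
                   n_members, base_seed).r2
        rows.append({"property": prop, "delta_r2": full - r2})
    return (pd.DataFrame(rows)
            .sort_values("delta_r2", ascending=False, kind="stable")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def knn_baseline(data: Dataset, k: int = 3) -> CVResult:
    """LOOCV k-nearest-neighbour regression on mean-filled vectors.

    Euclidean distance over the condition slots; the prediction is the
    unweighted mean of the k nearest training outcomes.  Ties in distance
    are broken by original row order.
    """
    known = np.nonzero(data.mask[:, -1])[0]
    if k >= len(known):
        raise ValueError(f"k={k} needs more than k entries with known outcome")
    filled = data.filled()
    rows = []
    for idx in known:
        train_rows = known[known != idx]
        diffs = filled.values[train_rows, :-1] - filled.values[idx, :-1]
        dist = np.sqrt((diffs**2).sum(axis=1))
        nearest = train_rows[np.argsort(dist, kind="stable")[:k]]
        pred = float(data.values[nearest, -1].mean())
        rows.append({"entry": int(idx), "actual": float(data.values[idx, -1]),
                     "pred": pred, "std": math.nan, "z": math.nan})
    table = pd.DataFrame(rows)
    return CVResult(table, r_squared(table["pred"].to_numpy(),
                                     table["actual"].to_numpy()), len(known))


def mean_baseline(data: Dataset) -> CVResult:
    """LOOCV prediction by the training-fold outcome mean."""
    known = np.nonzero(data.mask[:, -1])[0]
    if len(known) < 3:
        raise ValueError("need at least 3 entries with a known outcome")
    rows = []
    for idx in known:
        others = known[known != idx]
        pred = float(data.values[others, -1].mean())
        rows.append({"entry": int(idx), "actual": float(data.values[idx, -1]),
                     "pred": pred, "std": math.nan, "z": math.nan})
    table = pd.DataFrame(rows)
    return CVResult(table, r_squared(table["pred"].to_numpy(),
                                     table["actual"].to_numpy()), len(known))


# ---------------------------------------------------------------------------
# hyperparameter sweep
# ---------------------------------------------------------------------------

def hidden_sweep(data: Dataset, hiddens: list[int] | None = None,
                 train_cfg: TrainConfig | None = None,
                 impute_cfg: ImputeConfig | None = None,
                 n_members: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """LOOCV R^2 as a function of the hidden-node count."""
    train_cfg = train_cfg or TrainConfig()
    hiddens = hiddens or list(range(1, 11))
    rows = []
    for h in hiddens:
        cfg = TrainConfig(**{**vars(train_cfg), "hidden": h})
        rows.append({"hidden": h,
                     "r2": loocv(data, cfg, impute_cfg, n_members, base_seed).r2})
    return pd.DataFrame(rows)
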