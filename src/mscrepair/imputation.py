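"""Fixed-point imputation of missing slots.

Missing values start at the training-set column means and are then relaxed
toward self-consistency with the trained model by the softened fixed-point
iteration

    x[n+1] = gamma * x[n] + (1 - gamma) * f(x[n]),

applied to the missing slots only; observed slots are clamped (a config
switch restores the literal whole-vector update for comparison).  ``f`` is
held fixed across iterations.  The softening parameter ``gamma`` in [0, 1]
damps oscillations — at the fixed point the update is a no-op for any gamma,
so gamma shapes the path, not the limit.  The converged vector itself (not
``f`` of it) is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset, PropertyVector
from .ensemble import Ensemble
from .network import NetworkParams, forward

__all__ = [
    "ImputeConfig",
    "ImputeResult",
    "initial_fill",
    "impute",
    "impute_dataset",
    "impute_ensemble_members",
]


@dataclass
class ImputeConfig:
    """Iteration controls.

    gamma:
        Softening weight on the previous iterate, in [0, 1]; 0.5 by default.
        gamma = 1 freezes the iterate (the initial fill is returned);
        gamma = 0 is the raw fixed-point map.
    tol:
        Convergence threshold on the max absolute change over missing slots.
    max_iter:
        Iteration cap; hitting it returns the best iterate with
        ``converged=False`` and a warning rather than an exception.
    update_known:
        If True, apply the update to every slot (the literal whole-vector
        reading); default clamps observed slots.
    """

    gamma: float = 0.5
    tol: float = 1e-4
    max_iter: int = 100
    update_known: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ImputeResult:
    vector: PropertyVector
    iterations: int
    converged: bool


def initial_fill(x: PropertyVector, data: Dataset) -> PropertyVector:
    """Replace missing slots by the training set's per-slot means.

    Indicator slots receive the mean indicator frequency.  The mask is left
    untouched: filled slots stay flagged as imputed, not observed.
    """
    if not (~x.mask).any():
        return x.copy()
    means = data.column_means()
    needed = ~x.mask
    if not np.isfinite(means[needed]).all():
        bad = [data.columns[j] for j in np.nonzero(needed & ~np.isfinite(means))[0]]
        raise ValueError(f"no observed training values to fill slots: {bad}")
    out = x.copy()
    out.values[needed] = means[needed]
    return out


def _model_fn(model: Ensemble | NetworkParams):
    if isinstance(model, Ensemble):
        return lambda v: model.member_predictions(v).mean(axis=0)
    return lambda v: forward(model, v)


def impute(model: Ensemble | NetworkParams, x: PropertyVector, data: Dataset,
           cfg: ImputeConfig | None = None) -> ImputeResult:
    """Iterate the softened fixed-point map until self-consistency.

    Starts from :func:`initial_fill`.  If the change metric grows for five
    consecutive iterations, gamma is pushed toward 1 by halving ``1 - gamma``
    (oscillation guard).  A fully observed vector is returned unchanged with
    zero iterations.
    """
    cfg = cfg or ImputeConfig()
    width = model.width if isinstance(model, (Ensemble, NetworkParams)) else None
    if width is not None and x.width != width:
        raise ValueError(f"model width {width} != vector width {x.width}")
    free = ~x.mask if not cfg.update_known else np.ones(x.width, dtype=bool)
    if not (~x.mask).any():
        return ImputeResult(x.copy(), 0, True)

    f = _model_fn(model)
    cur = initial_fill(x, data)
    gamma = cfg.gamma
    prev_change = np.inf
    growing = 0
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        y = f(cur)
        new_vals = gamma * cur.values + (1.0 - gamma) * y
        nxt = cur.values.copy()
        nxt[free] = new_vals[free]
        change = float(np.max(np.abs(nxt - cur.values))) if free.any() else 0.0
        cur.values = nxt
        if change <= cfg.tol:
            converged = True
            break
        if change > prev_change:
            growing += 1
            if growing >= 5:
                gamma = 1.0 - (1.0 - gamma) / 2.0
                growing = 0
                warnings.warn(
                    f"impute: oscillation guard raised gamma to {gamma:.4f}",
                    stacklevel=2,
                )
        else:
            growing = 0
        prev_change = change
    if not converged:
        warnings.warn(
            f"impute did not converge within {cfg.max_iter} iterations "
            f"(last change {prev_change:.3g})",
            stacklevel=2,
        )
    return ImputeResult(cur, iterations, converged)


def impute_dataset(model: Ensemble | NetworkParams, data: Dataset,
                   cfg: ImputeConfig | None = None) -> Dataset:
    """Impute every entry independently (``f`` fixed, so order is irrelevant).

    The returned dataset has all values finite; its mask still distinguishes
    observed from imputed cells.
    """
    out = data.copy()
    for i in range(data.n_entries):
        res = impute(model, data.entry(i), data, cfg)
        out.values[i] = res.vector.values
    return out


def impute_ensemble_members(ens: Ensemble, x: PropertyVector, data: Dataset,
                            cfg: ImputeConfig | None = None) -> np.ndarray:
    """Converged vectors per member, shape ``(M, I)``.

    Running the fixed-point iteration separately through each member (rather
    than through the ensemble mean) lets the member spread propagate into
    the imputed slots, which is what the reported uncertainty is built from.
    """
    return np.stack([impute(m, x, data, cfg).vector.values for m in ens.members])
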