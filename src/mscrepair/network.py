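"""The self-consistent imputing network and its trainer.

The model maps a length-``I`` property vector ``x`` to a prediction ``y`` of
the *same* vector, one hidden tanh layer per predicted slot:

    y_j = sum_h C[h, j] * tanh(sum_i A[i, h, j] * x_i + B[h, j]) + D[j]

with the structural self-weight constraint ``A[j, h, j] = 0``: slot ``j`` is
predicted without any knowledge of its own observed value.  That constraint
is what turns a fixed-point solution of ``f(x) = x`` into an imputation
device rather than the identity map.

The training objective is the mean summed squared error over observed slots,

    sigma = (1/N) * sum_{x in X} sum_j mask_j * (f_j(x) - x_j)^2 .

Note the convention: no square root is applied even though the quantity is
conventionally referred to as an RMSE-style cost; human-facing error reports
should use ``sqrt(sigma)``.

Training is a greedy random walk (Gaussian parameter proposals with a
geometrically decaying step size, accepted only when the cost improves)
optionally followed by an analytic-gradient Adam refinement.  The best
parameters seen anywhere along the run are returned, so the final cost never
exceeds the initial one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import Dataset, PropertyVector

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "init_params",
    "forward",
    "forward_batch",
    "rmse_cost",
    "train",
    "train_with_trace",
]


@dataclass
class NetworkParams:
    """Variational parameters of one network.

    ``A`` has shape ``(I, H, I)`` (input slot, hidden node, output slot),
    ``B`` and ``C`` shape ``(H, I)``, ``D`` shape ``(I,)``.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        I, H = self.D.shape[0], self.B.shape[0]
        if self.A.shape != (I, H, I) or self.C.shape != (H, I) or self.B.shape != (H, I):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.A, self.B, self.C, self.D):
            if not np.isfinite(arr).all():
                raise ValueError("network parameters must be finite")

    @property
    def width(self) -> int:
        return self.D.shape[0]

    @property
    def hidden(self) -> int:
        return self.B.shape[0]

    def apply_self_mask(self) -> "NetworkParams":
        """Force A[j, h, j] = 0 in place; safe to call after any update."""
        idx = np.arange(self.width)
        self.A[idx, :, idx] = 0.0
        return self

    def self_mask_holds(self) -> bool:
        idx = np.arange(self.width)
        return bool((self.A[idx, :, idx] == 0.0).all())

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.A.copy(), self.B.copy(), self.C.copy(), self.D.copy())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "hidden": self.hidden,
            "A": self.A.ravel().tolist(),
            "B": self.B.ravel().tolist(),
            "C": self.C.ravel().tolist(),
            "D": self.D.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        I, H = int(d["width"]), int(d["hidden"])
        return cls(
            np.asarray(d["A"], dtype=float).reshape(I, H, I),
            np.asarray(d["B"], dtype=float).reshape(H, I),
            np.asarray(d["C"], dtype=float).reshape(H, I),
            np.asarray(d["D"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainConfig:
    """Training schedule.

    hidden:
        Hidden tanh nodes per predicted slot.  Four is a deliberately small
        default for databases of a few dozen entries; use the hidden-size
        sweep in :mod:`mscrepair.evaluation` to revisit it.
    walk_steps / walk_step_size / walk_grow / walk_shrink:
        Greedy random-walk phase: Gaussian proposals, accepted only on cost
        improvement.  The proposal scale is adapted per member — multiplied
        by ``walk_grow`` after an accepted step and by ``walk_shrink`` after
        a rejected one — so each member settles at the scale its local cost
        basin supports.
    descent_steps / learning_rate:
        Adam refinement on the analytic gradient; set ``use_descent=False``
        for the pure random-walk reading of the optimizer.
    sample_steps / sample_step_size:
        Residual-tempered scatter phase after fitting: a Metropolis walk
        around the optimum whose temperature per output block is the
        estimated residual variance of that output, so ensemble members end
        up spread exactly as far apart as the noise in the data supports.
        On noise-free data the temperature collapses and members stay at
        the optimum.  Set ``sample_steps=0`` to disable.
    seed:
        Seeds both initialization and the proposal stream.
    """

    hidden: int = 4
    walk_steps: int = 200
    walk_step_size: float = 0.15
    walk_grow: float = 1.05
    walk_shrink: float = 0.97
    descent_steps: int = 300
    learning_rate: float = 0.05
    use_descent: bool = True
    sample_steps: int = 400
    sample_step_size: float = 0.05
    sample_temper: float = 2.0
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.walk_steps < 0 or self.descent_steps < 0 or self.sample_steps < 0:
            raise ValueError("step counts must be >= 0")
        if self.walk_step_size <= 0 or self.learning_rate <= 0:
            raise ValueError("step sizes must be > 0")
        if not (self.walk_grow >= 1.0 > self.walk_shrink > 0.0):
            raise ValueError("need walk_grow >= 1 > walk_shrink > 0")


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------

def forward(params: NetworkParams, x: PropertyVector | np.ndarray) -> np.ndarray:
    """Evaluate the network on one (pre-filled) property vector."""
    values = x.values if isinstance(x, PropertyVector) else np.asarray(x, dtype=float)
    if values.shape != (params.width,):
        raise ValueError(f"expected a length-{params.width} vector, got {values.shape}")
    if not np.isfinite(values).all():
        raise ValueError("forward requires finite inputs; fill missing slots first")
    eta = np.tanh(np.einsum("i,ihj->hj", values, params.A) + params.B)
    return np.einsum("hj,hj->j", params.C, eta) + params.D


def forward_batch(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Evaluate the network on an ``(N, I)`` matrix of pre-filled entries."""
    X = np.asarray(X, dtype=float)
    eta = np.tanh(np.einsum("ni,ihj->nhj", X, params.A) + params.B[None])
    return np.einsum("nhj,hj->nj", eta, params.C) + params.D[None]


def rmse_cost(params: NetworkParams, data: Dataset) -> float:
    """Mean summed squared error over observed slots (no square root).

    Entries must be pre-filled: missing slots act as inputs through their
    current imputations but never contribute to the error sum.
    """
    if data.n_entries < 1:
        raise ValueError("empty dataset")
    X = data.values
    if not np.isfinite(X).all():
        X = data.filled().values
    Y = forward_batch(params, X)
    resid = np.where(data.mask, Y - np.where(data.mask, data.values, 0.0), 0.0)
    return float((resid**2).sum() / data.n_entries)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_params(I: int, H: int, seed: int, data: Dataset | None = None,
                scale: float = 0.5) -> NetworkParams:
    """Random small-scale initialization with the self-weight mask enforced.

    ``A`` and ``B`` are uniform on ``(-scale, scale)`` so tanh units start in
    their linear regime for unit-interval inputs; ``C`` starts small and
    ``D`` at the per-slot mean of observed values (zero without data), so the
    initial prediction is already the column-mean baseline.
    """
    if I < 2 or H < 1:
        raise ValueError("need I >= 2 and H >= 1")
    rng = np.random.default_rng(seed)
    A = rng.uniform(-scale, scale, size=(I, H, I))
    B = rng.uniform(-scale, scale, size=(H, I))
    C = rng.uniform(-0.1, 0.1, size=(H, I))
    if data is not None:
        means = data.column_means()
        D = np.where(np.isfinite(means), means, 0.0)
    else:
        D = np.zeros(I)
    return NetworkParams(A, B, C, D.copy()).apply_self_mask()


# ---------------------------------------------------------------------------
# batched trainer (shared by single-network and ensemble training)
# ---------------------------------------------------------------------------

def _batched_cost(Ab, Bb, Cb, Db, X, W, N):
    eta = np.tanh(np.einsum("ni,mihj->mnhj", X, Ab) + Bb[:, None])
    Y = np.einsum("mnhj,mhj->mnj", eta, Cb) + Db[:, None]
    R = W * (Y - X[None])
    return (R**2).sum(axis=(1, 2)) / N, eta, Y


def _zero_self(Ab):
    idx = np.arange(Ab.shape[1])
    Ab[:, idx, :, idx] = 0.0
    return Ab


def train_members(data: Dataset, cfg: TrainConfig, seeds: list[int],
                  record_trace: bool = False):
    """Train ``len(seeds)`` independent networks on the same data.

    Members are mathematically independent (per-member RNG stream, per-member
    greedy acceptance); evaluation is merely batched for speed.  Returns the
    list of trained :class:`NetworkParams` and, if requested, the per-member
    trace of accepted random-walk costs.
    """
    if data.n_entries < 1:
        raise ValueError("cannot train on an empty dataset")
    if not data.mask.any():
        raise ValueError("cannot train: no observed values in the dataset")
    filled = data.filled() if not np.isfinite(data.values).all() else data
    X = filled.values
    W = data.mask.astype(float)[None]  # (1, N, I), broadcast over members
    N, I = X.shape
    M, H = len(seeds), cfg.hidden

    inits = [init_params(I, H, s, data=data, scale=cfg.init_scale) for s in seeds]
    Ab = np.stack([p.A for p in inits])
    Bb = np.stack([p.B for p in inits])
    Cb = np.stack([p.C for p in inits])
    Db = np.stack([p.D for p in inits])

    cost, _, _ = _batched_cost(Ab, Bb, Cb, Db, X, W, N)
    init_cost = cost.copy()
    traces = [[float(c)] for c in cost]

    # --- greedy random walk ------------------------------------------------
    if cfg.walk_steps > 0:
        rngs = [np.random.default_rng(int(s) + 0x5F5E1) for s in seeds]
        nA = np.stack([r.standard_normal((cfg.walk_steps, I, H, I)) for r in rngs])
        nB = np.stack([r.standard_normal((cfg.walk_steps, H, I)) for r in rngs])
        nC = np.stack([r.standard_normal((cfg.walk_steps, H, I)) for r in rngs])
        nD = np.stack([r.standard_normal((cfg.walk_steps, I)) for r in rngs])
        step = np.full(M, cfg.walk_step_size)
        for t in range(cfg.walk_steps):
            s4 = step[:, None, None, None]
            s3 = step[:, None, None]
            cA = _zero_self(Ab + s4 * nA[:, t])
            cB = Bb + s3 * nB[:, t]
            cC = Cb + s3 * nC[:, t]
            cD = Db + step[:, None] * nD[:, t]
            c_new, _, _ = _batched_cost(cA, cB, cC, cD, X, W, N)
            acc = c_new < cost
            if acc.any():
                Ab[acc], Bb[acc], Cb[acc], Db[acc] = cA[acc], cB[acc], cC[acc], cD[acc]
                cost = np.where(acc, c_new, cost)
                for m in np.nonzero(acc)[0]:
                    traces[m].append(float(c_new[m]))
            step = np.clip(np.where(acc, step * cfg.walk_grow, step * cfg.walk_shrink),
                           1e-4, 1.0)

    best = (cost.copy(), Ab.copy(), Bb.copy(), Cb.copy(), Db.copy())

    # --- Adam refinement ----------------------------------------------------
    if cfg.use_descent and cfg.descent_steps > 0:
        b1, b2, eps = 0.9, 0.999, 1e-8
        mom = [np.zeros_like(a) for a in (Ab, Bb, Cb, Db)]
        vel = [np.zeros_like(a) for a in (Ab, Bb, Cb, Db)]
        for t in range(1, cfg.descent_steps + 1):
            c_now, eta, Y = _batched_cost(Ab, Bb, Cb, Db, X, W, N)
            improved = c_now < best[0]
            if improved.any():
                best[0][improved] = c_now[improved]
                best[1][improved] = Ab[improved]
                best[2][improved] = Bb[improved]
                best[3][improved] = Cb[improved]
                best[4][improved] = Db[improved]
            R = 2.0 * W * (Y - X[None]) / N  # (M, N, I)
            gD = R.sum(axis=1)
            gC = np.einsum("mnj,mnhj->mhj", R, eta)
            S = R[:, :, None, :] * Cb[:, None] * (1.0 - eta**2)  # (M, N, H, I)
            gB = S.sum(axis=1)
            gA = _zero_self(np.einsum("mnhj,ni->mihj", S, X))
            grads = (gA, gB, gC, gD)
            params = [Ab, Bb, Cb, Db]
            for k in range(4):
                mom[k] = b1 * mom[k] + (1 - b1) * grads[k]
                vel[k] = b2 * vel[k] + (1 - b2) * grads[k] ** 2
                mhat = mom[k] / (1 - b1**t)
                vhat = vel[k] / (1 - b2**t)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            Ab, Bb, Cb, Db = params
            _zero_self(Ab)
        c_now, _, _ = _batched_cost(Ab, Bb, Cb, Db, X, W, N)
        improved = c_now < best[0]
        if improved.any():
            best[0][improved] = c_now[improved]
            best[1][improved] = Ab[improved]
            best[2][improved] = Bb[improved]
            best[3][improved] = Cb[improved]
            best[4][improved] = Db[improved]

    # --- residual-tempered scatter ------------------------------------------
    # Parameters of different output slots are disjoint, so the Metropolis
    # acceptance factorizes per output block.  The temperature of block j is
    # the estimated residual variance of slot j at the fit, with a small
    # degrees-of-freedom guard; on noise-free data it collapses to ~0 and the
    # phase leaves members at their optimum.
    if cfg.sample_steps > 0:
        Ab, Bb, Cb, Db = (best[k].copy() for k in (1, 2, 3, 4))
        _, _, Y = _batched_cost(Ab, Bb, Cb, Db, X, W, N)
        rss = ((W * (Y - X[None])) ** 2).sum(axis=1)  # (M, I)
        n_obs = data.mask.sum(axis=0).astype(float)   # per-slot observations
        p_j = H * (I + 1) + 1                         # params per output block
        dof = np.maximum(n_obs - p_j, 3.0)
        # Predictive tempering: a posterior-matched temperature alone yields
        # member spread ~ leverage * sigma (epistemic only).  Inflating by
        # (1 + n/p) targets the full predictive scale (epistemic +
        # observation noise) in the linear-leverage limit; sample_temper
        # compensates for the effective dimension of a tanh block being
        # smaller than its parameter count and for finite chain length.
        inflate = cfg.sample_temper * (1.0 + n_obs / p_j)
        sigma2 = np.maximum((rss / dof[None]) * inflate[None], 1e-10)  # (M, I)
        active = n_obs > 0
        srngs = [np.random.default_rng(int(s) + 0xA11CE) for s in seeds]
        sA = np.stack([r.standard_normal((cfg.sample_steps, I, H, I)) for r in srngs])
        sB = np.stack([r.standard_normal((cfg.sample_steps, H, I)) for r in srngs])
        sC = np.stack([r.standard_normal((cfg.sample_steps, H, I)) for r in srngs])
        sD = np.stack([r.standard_normal((cfg.sample_steps, I)) for r in srngs])
        sU = np.stack([r.random((cfg.sample_steps, I)) for r in srngs])
        scale = np.full((M, I), cfg.sample_step_size)
        for t in range(cfg.sample_steps):
            cA = _zero_self(Ab + scale[:, None, None, :] * sA[:, t])
            cB = Bb + scale[:, None, :] * sB[:, t]
            cC = Cb + scale[:, None, :] * sC[:, t]
            cD = Db + scale * sD[:, t]
            _, _, Yc = _batched_cost(cA, cB, cC, cD, X, W, N)
            rss_new = ((W * (Yc - X[None])) ** 2).sum(axis=1)
            with np.errstate(over="ignore"):
                acc = (sU[:, t] < np.exp(-np.clip(
                    (rss_new - rss) / (2.0 * sigma2), -50, 50
                ))) & active[None, :]
            Ab = np.where(acc[:, None, None, :], cA, Ab)
            Bb = np.where(acc[:, None, :], cB, Bb)
            Cb = np.where(acc[:, None, :], cC, Cb)
            Db = np.where(acc, cD, Db)
            rss = np.where(acc, rss_new, rss)
            # target a healthy acceptance rate block by block
            scale = np.clip(np.where(acc, scale * 1.1, scale * 0.95), 1e-4, 0.5)
        # safety clamp: a sampled member never ends worse than it started
        c_s, _, _ = _batched_cost(Ab, Bb, Cb, Db, X, W, N)
        bad = c_s > init_cost
        best = (
            np.where(bad, best[0], c_s),
            np.where(bad[:, None, None, None], best[1], Ab),
            np.where(bad[:, None, None], best[2], Bb),
            np.where(bad[:, None, None], best[3], Cb),
            np.where(bad[:, None], best[4], Db),
        )

    members = [
        NetworkParams(best[1][m], best[2][m], best[3][m], best[4][m]).apply_self_mask()
        for m in range(M)
    ]
    if record_trace:
        return members, traces
    return members


def train(data: Dataset, cfg: TrainConfig) -> NetworkParams:
    """Train a single network; deterministic given ``(data, cfg)``."""
    return train_members(data, cfg, [cfg.seed])[0]


def train_with_trace(data: Dataset, cfg: TrainConfig):
    """As :func:`train`, also returning the accepted-cost trace of the walk."""
    members, traces = train_members(data, cfg, [cfg.seed], record_trace=True)
    return members[0], traces[0]
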