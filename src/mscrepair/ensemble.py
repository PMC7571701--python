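"""Ensemble training and uncertainty quantification.

Many networks are trained independently on the same data from different
random seeds; the ensemble mean is the prediction and the population
standard deviation across members is its uncertainty.  The spread captures
both the noise in the underlying records and the instability of
extrapolation — members agree where the data pin the function down and
disagree where they do not.  No bootstrap resampling is involved: every
member sees the full training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import Dataset, PropertyVector
from .network import NetworkParams, TrainConfig, forward, train_members

__all__ = ["Ensemble", "EnsemblePrediction", "train_ensemble", "predict_with_uncertainty"]

DEFAULT_MEMBERS = 100


@dataclass
class EnsemblePrediction:
    """Per-slot ensemble mean and (population) standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have matching shapes")

    @property
    def outcome(self) -> float:
        return float(self.mean[-1])

    @property
    def outcome_std(self) -> float:
        return float(self.std[-1])


@dataclass
class Ensemble:
    """A trained committee of networks sharing one descriptor order."""

    members: list[NetworkParams]
    seeds: list[int]
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")
        widths = {p.width for p in self.members}
        hiddens = {p.hidden for p in self.members}
        if len(widths) != 1 or len(hiddens) != 1:
            raise ValueError("members must share I and H")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def width(self) -> int:
        return self.members[0].width

    def member_predictions(self, x: PropertyVector | np.ndarray) -> np.ndarray:
        """(M, I) matrix of each member's forward output on ``x``."""
        return np.stack([forward(p, x) for p in self.members])

    # -- serialization: directory of member files + manifest ----------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, member in enumerate(self.members):
            member.save(directory / f"member_{k:04d}.json")
        manifest = {
            "n_members": self.n_members,
            "seeds": list(map(int, self.seeds)),
            "columns": self.columns,
            "width": self.width,
            "hidden": self.members[0].hidden,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        members = [
            NetworkParams.load(directory / f"member_{k:04d}.json")
            for k in range(manifest["n_members"])
        ]
        return cls(members, manifest["seeds"], manifest.get("columns"))


def member_seeds(base_seed: int, n_members: int) -> list[int]:
    """Derived per-member seeds, kept within 31 bits."""
    return [(int(base_seed) + k) % (2**31) for k in range(n_members)]


def train_ensemble(data: Dataset, cfg: TrainConfig, n_members: int = DEFAULT_MEMBERS,
                   base_seed: int | None = None) -> Ensemble:
    """Train ``n_members`` networks from derived seeds ``base_seed + k``.

    Deterministic given ``(data, cfg, n_members, base_seed)``.  Members are
    trained on identical data and never share state; results are identical
    to training each member on its own.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if base_seed is None:
        base_seed = cfg.seed
    seeds = member_seeds(base_seed, n_members)
    members = train_members(data, cfg, seeds)
    return Ensemble(members, seeds, columns=list(data.columns))


def predict_with_uncertainty(ens: Ensemble, x: PropertyVector | np.ndarray) -> EnsemblePrediction:
    """Ensemble mean and population standard deviation of ``f(x)``.

    ``x`` must be pre-filled (route incomplete vectors through the impute
    module first).
    """
    preds = ens.member_predictions(x)
    return EnsemblePrediction(preds.mean(axis=0), preds.std(axis=0, ddof=0))
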