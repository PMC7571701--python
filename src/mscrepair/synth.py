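"""Synthetic therapy databases with known ground truth.

The generator emulates the statistical shape of a small cell-therapy
meta-analysis table: a few dozen entries, mixed continuous and categorical
predictors on wildly different natural scales, one bounded outcome driven by
a nonlinear function of the predictors, additive Gaussian noise, and
per-column missingness.  Two planted outcome families are provided:

``tanh``
    A single-hidden-node network of exactly the model's functional form, so
    the estimator can represent the truth exactly — the plant used for
    parameter-recovery checks.

``composite``
    A clinically shaped surface: the repair score falls with defect
    severity (area/depth percentage) and responds to the implanted cell
    dose through a bell on the log-dose axis — the plant used for
    dose-curve and threshold analyses.

Every draw is deterministic given the seed, and a :class:`SynthTruth`
records the noiseless outcomes, the planted function, and (after masking)
every hidden cell's true value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import Dataset
from .schema import CSV_COLUMNS, EncodingConfig

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate",
    "generate_table",
    "mask_missing",
    "planted_outcome",
]

#: Encoded-axis position of a 2e7-cell dose on the 1e5..1e9 log-uniform range.
DOSE_OPTIMUM_CELLS = 2e7
_CELL_LO, _CELL_HI = 1e5, 1e9


@dataclass
class SynthConfig:
    """Generation settings.

    Defaults mirror the scale of the study database: 44 entries, predictors
    spanning their literature ranges (body weight 0.02-70 kg and cell number
    1e5-1e9 log-uniform; defect percentages uniform on their typical
    sub-ranges), outcome noise of 0.05 on the unit score, and no
    missingness until :func:`mask_missing` is applied.
    """

    n: int = 44
    outcome: str = "composite"           # "composite" | "tanh" | "additive"
    n_continuous: int = 4                # tanh plant: number of condition slots
    n_informative: int | None = None     # tanh plant: slots the outcome uses
                                         # (None = all; the rest are pure noise)
    hidden: int = 1                      # tanh plant: hidden nodes
    noise_sd: float = 0.05
    heteroscedastic: bool = False        # noise grows along x1, which is
                                         # sampled sparsely where it is noisy
    plant_overrides: Mapping[str, float] | None = None  # composite-plant tweaks
    seed: int = 0
    tissue_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"BM": 0.5, "AD": 0.25, "SF": 0.1, "WJ": 0.05,
                                 "ST": 0.05, "UCB": 0.05}
    )
    damage_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"osteochondral_defect": 0.66, "osteoarthritis": 0.34}
    )
    area_pct_range: tuple[float, float] = (1.0, 60.0)
    depth_pct_range: tuple[float, float] = (10.0, 100.0)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for freqs in (self.tissue_freqs, self.damage_freqs):
            if any(not 0 <= p <= 1 for p in freqs.values()):
                raise ValueError("categorical frequencies must lie in [0, 1]")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError("categorical frequencies must sum to 1")
        if self.outcome not in ("composite", "tanh", "additive"):
            raise ValueError(f"unknown outcome family {self.outcome!r}")
        for lo, hi in (self.area_pct_range, self.depth_pct_range):
            if not (0 <= lo < hi <= 100):
                raise ValueError("percentage ranges must satisfy 0 <= lo < hi <= 100")


@dataclass
class SynthTruth:
    """Ground truth accompanying one generated dataset."""

    noiseless: np.ndarray                       # noiseless outcome per entry
    plant: dict                                 # planted-function parameters
    hidden_cells: dict[tuple[int, int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# planted outcome functions (operate on encoded [0, 1] coordinates)
# ---------------------------------------------------------------------------

def _tanh_plant_params(k: int, hidden: int, rng: np.random.Generator) -> dict:
    """A single-output tanh network over k condition slots, scaled to keep
    outcomes comfortably inside the unit interval with a healthy dynamic
    range (sd ~ 0.2 on uniform inputs).

    Inputs enter centered; weights are bounded away from zero (every
    nominally informative slot actually drives the outcome) and scaled by
    1/sqrt(k) so the pre-activation stays in the responsive part of tanh.
    """
    signs = rng.choice([-1.0, 1.0], size=(k, hidden))
    scale = 2.0 / np.sqrt(k)
    return {
        "family": "tanh",
        "A": (signs * rng.uniform(0.7, 1.5, size=(k, hidden)) * scale).tolist(),
        "B": rng.uniform(-0.3, 0.3, size=hidden).tolist(),
        "C": (rng.uniform(0.3, 0.45, size=hidden) / hidden).tolist(),
        "D": 0.5,
    }


def _additive_plant_params(k: int, rng: np.random.Generator) -> dict:
    """One private tanh node per condition slot (y = D + sum_i C_i tanh(a_i (x_i - 1/2))).

    Every informative slot contributes its own additive nonlinear component,
    so "informative" is marginally detectable — the right ground truth for
    screening experiments (a single shared node can hide a driver behind its
    co-drivers, which no marginal screen can see).
    """
    signs = rng.choice([-1.0, 1.0], size=k)
    # amplitudes sized so each driver's marginal effect is unambiguous at
    # study scale (a few dozen entries); occasional clipping at the unit
    # bounds is part of the generative model
    return {
        "family": "additive",
        "a": (signs * rng.uniform(1.5, 3.0, size=k)).tolist(),
        "C": (rng.uniform(0.3, 0.45, size=k) * 1.2 / max(k, 1)).tolist(),
        "D": 0.5,
    }


def _composite_plant_params() -> dict:
    # dose axis encoded as (log10(cells) - 5) / 4 on the 1e5..1e9 range
    d_opt = (np.log10(DOSE_OPTIMUM_CELLS) - np.log10(_CELL_LO)) / (
        np.log10(_CELL_HI) - np.log10(_CELL_LO)
    )
    return {
        "family": "composite",
        "base": 0.15,
        "severity_gain": 0.40,       # score lost at maximal severity
        "area_weight": 0.4,
        "depth_weight": 0.6,
        "dose_gain": 0.30,
        "dose_optimum": float(d_opt),
        "dose_width": 0.25,
        "weight_gain": 0.10,         # heavier species fare slightly better
    }


def planted_outcome(plant: dict, x: np.ndarray) -> np.ndarray:
    """Noiseless outcome of the planted function on encoded condition rows.

    For the tanh family ``x`` holds the k condition slots; for the composite
    family the column order is (area_pct, depth_pct, log-dose, log-weight),
    all on [0, 1].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if plant["family"] == "tanh":
        A = np.asarray(plant["A"])
        eta = np.tanh((x - 0.5) @ A + np.asarray(plant["B"]))
        return eta @ np.asarray(plant["C"]) + plant["D"]
    if plant["family"] == "additive":
        a = np.asarray(plant["a"])
        C = np.asarray(plant["C"])
        return np.tanh((x - 0.5) * a) @ C + plant["D"]
    if plant["family"] == "composite":
        area, depth, dose, weight = (x[:, i] for i in range(4))
        severity = plant["area_weight"] * area + plant["depth_weight"] * depth
        bell = np.exp(-((dose - plant["dose_optimum"]) ** 2)
                      / (2.0 * plant["dose_width"] ** 2))
        return (plant["base"]
                + plant["severity_gain"] * (1.0 - severity)
                + plant["dose_gain"] * bell
                + plant["weight_gain"] * weight)
    raise ValueError(f"unknown plant family {plant['family']!r}")


# ---------------------------------------------------------------------------
# encoded-dataset generation
# ---------------------------------------------------------------------------

def generate(cfg: SynthConfig) -> tuple[Dataset, SynthTruth]:
    """Generate an encoded dataset with no missing cells yet.

    The tanh family yields columns ``x1..xk`` plus the outcome; the
    composite family yields the four encoded clinical axes plus two
    indicator columns (tissue BM-or-AD, damage type) that do not enter the
    planted function — realistic nuisance structure.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.outcome in ("tanh", "additive"):
        k = cfg.n_continuous
        X = rng.uniform(0.0, 1.0, size=(cfg.n, k))
        if cfg.heteroscedastic:
            # few entries at high x1, where the outcome is also noisiest —
            # the typical shape of pooled animal-study conditions
            X[:, 0] = rng.beta(1.0, 2.2, size=cfg.n)
        k_inf = cfg.n_informative if cfg.n_informative is not None else k
        if cfg.outcome == "tanh":
            plant = _tanh_plant_params(k_inf, cfg.hidden, rng)
        else:
            plant = _additive_plant_params(k_inf, rng)
        columns = [f"x{i + 1}" for i in range(k)]
    else:
        plant = _composite_plant_params()
        if cfg.plant_overrides:
            plant.update(cfg.plant_overrides)
        # correlated clinical axes, as in pooled study data: lesion area and
        # depth share a severity latent, and implanted dose scales with body
        # size (pairwise correlations ~0.5) — the cross-property structure
        # imputation feeds on
        sev = rng.uniform(0.0, 1.0, size=cfg.n)
        u1, u2, u3 = rng.uniform(0.0, 1.0, size=(3, cfg.n))
        lo_a, hi_a = _unit(cfg.area_pct_range)
        lo_d, hi_d = _unit(cfg.depth_pct_range)
        area = lo_a + (0.5 * sev + 0.5 * u1) * (hi_a - lo_a)
        depth = lo_d + (0.5 * sev + 0.5 * u2) * (hi_d - lo_d)
        weight = rng.uniform(0.0, 1.0, size=cfg.n)
        dose = 0.5 * weight + 0.5 * u3
        tissues = rng.choice(list(cfg.tissue_freqs), p=list(cfg.tissue_freqs.values()),
                             size=cfg.n)
        damages = rng.choice(list(cfg.damage_freqs), p=list(cfg.damage_freqs.values()),
                             size=cfg.n)
        X = np.column_stack([
            area, depth, dose, weight,
            np.isin(tissues, ("BM", "AD")).astype(float),
            (damages == "osteoarthritis").astype(float),
        ])
        columns = ["defect_area_pct", "defect_depth_pct", "cell_number",
                   "body_weight_kg", "tissue_BM_or_AD", "damage_osteoarthritis"]
    if cfg.outcome in ("tanh", "additive"):
        g = planted_outcome(plant, X[:, :k_inf])
    else:
        g = planted_outcome(plant, X[:, :4])
    if cfg.noise_sd > 0:
        sd = cfg.noise_sd
        if cfg.heteroscedastic:
            sd = cfg.noise_sd * (0.2 + 2.0 * X[:, 0])
        noise = rng.normal(0.0, 1.0, size=cfg.n) * sd
    else:
        noise = 0.0
    y = np.clip(g + noise, 0.0, 1.0)
    values = np.column_stack([X, y])
    mask = np.ones_like(values, dtype=bool)
    ds = Dataset(values, mask, columns + ["repair_score"])
    return ds, SynthTruth(noiseless=np.asarray(g), plant=plant)


def _unit(pct_range: tuple[float, float]) -> tuple[float, float]:
    return pct_range[0] / 100.0, pct_range[1] / 100.0


def mask_missing(data: Dataset, truth: SynthTruth,
                 rates: Mapping[str, float] | float, seed: int,
                 mask_outcome: bool = False) -> Dataset:
    """Hide cells completely at random, column by column.

    ``rates`` is either one rate for every condition column or a mapping
    ``column -> rate``; the outcome column is only eligible when
    ``mask_outcome`` is true.  Hidden true values are recorded in
    ``truth.hidden_cells``.
    """
    if isinstance(rates, (int, float)):
        rates = {c: float(rates) for c in data.columns[:-1]}
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} outside [0, 1]")
        if col not in data.columns:
            raise KeyError(f"unknown column {col!r}")
        if col == data.outcome_column and not mask_outcome:
            raise ValueError("outcome masking requires mask_outcome=True")
    rng = np.random.default_rng(seed)
    out = data.copy()
    for col, rate in rates.items():
        j = data.columns.index(col)
        hide = rng.random(data.n_entries) < rate
        for i in np.nonzero(hide)[0]:
            truth.hidden_cells[(int(i), int(j))] = float(out.values[i, j])
        out.values[hide, j] = np.nan
        out.mask[hide, j] = False
    return out


# ---------------------------------------------------------------------------
# schema-level generation (raw CSV units)
# ---------------------------------------------------------------------------

def generate_table(cfg: SynthConfig) -> tuple[pd.DataFrame, SynthTruth, EncodingConfig]:
    """Generate a raw schema table (natural units) plus its fitted encoding.

    Continuous axes are decoded from the same draws :func:`generate` uses:
    body weight log-uniform on 0.02-70 kg, cell number log-uniform on
    1e5-1e9, defect percentages on their configured sub-ranges.  Useful for
    exercising the CSV reader and encoder against ground truth.
    """
    cfg2 = SynthConfig(**{**vars(cfg), "outcome": "composite"})
    ds, truth = generate(cfg2)
    area = ds.values[:, 0] * 100.0
    depth = ds.values[:, 1] * 100.0
    cells = 10.0 ** (5.0 + 4.0 * ds.values[:, 2])
    weight = 10.0 ** (np.log10(0.02) + ds.values[:, 3]
                      * (np.log10(70.0) - np.log10(0.02)))
    rng = np.random.default_rng(cfg.seed + 1)
    tissue = np.where(ds.values[:, 4] > 0.5,
                      rng.choice(["BM", "AD"], size=cfg.n),
                      rng.choice(["SF", "WJ", "ST", "UCB"], size=cfg.n))
    damage = np.where(ds.values[:, 5] > 0.5, "osteoarthritis", "osteochondral_defect")
    species = np.where(weight > 20, "human",
                       np.where(weight > 1.5, "rabbit", "rat"))
    df = pd.DataFrame({
        "species": species,
        "body_weight_kg": weight,
        "tissue_source": tissue,
        "cell_number": cells,
        "cell_concentration_per_ml": cells / rng.uniform(0.5, 5.0, size=cfg.n),
        "defect_area_mm2": np.nan,
        "defect_depth_mm": np.nan,
        "defect_area_pct": area,
        "defect_depth_pct": depth,
        "damage_type": damage,
        "score_name": "unit",
        "score_raw": ds.values[:, -1],
        "repair_score": ds.values[:, -1],
    }, columns=CSV_COLUMNS)
    enc = EncodingConfig.fit(
        df, ["defect_area_pct", "defect_depth_pct", "cell_number", "body_weight_kg",
             "tissue_source", "damage_type"],
        consolidate_bm_ad=True,
    )
    return df, truth, enc
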