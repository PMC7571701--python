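"""Therapy-record schema, score normalization, encoding, and CSV I/O.

One row of the database is one study condition: a species and its body
weight, the MSC tissue source, how many cells were implanted and at what
concentration, the cartilage defect geometry (absolute and as a percentage
of the knee cartilage), the type of damage, and a repair outcome reported on
one of ten clinical or histological instruments.  Instrument scores are
linearly rescaled to the unit interval with 1 = healthy tissue, so that
outcomes from ICRS gradings and pain scales live on one axis.

Records are encoded into numeric property vectors for the model: continuous
properties min-max scaled to [0, 1] with bounds fitted on training rows
only, categorical properties as indicator columns, and the repair score in
the final slot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .data import Dataset, PropertyVector

__all__ = [
    "ScoreScale",
    "DEFAULT_SCALES",
    "normalize_score",
    "TherapyRecord",
    "SpeciesGeometry",
    "derive_properties",
    "EncodingConfig",
    "CSV_COLUMNS",
    "read_table",
    "write_table",
    "read_dataset",
    "write_dataset",
]

HIGHER_IS_HEALTHIER = "higher_is_healthier"
HIGHER_IS_WORSE = "higher_is_worse"

TISSUE_SOURCES = ("BM", "AD", "SF", "WJ", "ST", "UCB")
DAMAGE_TYPES = ("osteochondral_defect", "osteoarthritis")

CSV_COLUMNS = [
    "species",
    "body_weight_kg",
    "tissue_source",
    "cell_number",
    "cell_concentration_per_ml",
    "defect_area_mm2",
    "defect_depth_mm",
    "defect_area_pct",
    "defect_depth_pct",
    "damage_type",
    "score_name",
    "score_raw",
    "repair_score",
]


# ---------------------------------------------------------------------------
# score scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreScale:
    """Bounds and polarity of one scoring instrument."""

    name: str
    lo: float
    hi: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_IS_HEALTHIER, HIGHER_IS_WORSE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.lo < self.hi:
            raise ValueError(f"scale {self.name!r} is degenerate: lo must be < hi")


#: Default instrument registry.  Bounds and polarities are conventional for
#: the common variants of each instrument; override per study via config —
#: a silently flipped polarity inverts the outcome, so the registry is
#: explicit rather than guessed at read time.
DEFAULT_SCALES: dict[str, ScoreScale] = {
    s.name: s
    for s in [
        ScoreScale("ICRS", 0, 12, HIGHER_IS_HEALTHIER),
        ScoreScale("ODriscoll", 0, 24, HIGHER_IS_HEALTHIER),
        ScoreScale("Pineda", 0, 14, HIGHER_IS_WORSE),
        ScoreScale("Mankin", 0, 14, HIGHER_IS_WORSE),
        ScoreScale("OARSI", 0, 24, HIGHER_IS_WORSE),
        ScoreScale("IKDC", 0, 100, HIGHER_IS_HEALTHIER),
        ScoreScale("VAS", 0, 10, HIGHER_IS_WORSE),
        ScoreScale("KOOS", 0, 100, HIGHER_IS_HEALTHIER),
        ScoreScale("WOMAC", 0, 96, HIGHER_IS_WORSE),
        ScoreScale("Lysholm", 0, 100, HIGHER_IS_HEALTHIER),
        ScoreScale("unit", 0, 1, HIGHER_IS_HEALTHIER),
    ]
}


def load_scales(path: str | Path) -> dict[str, ScoreScale]:
    """Read a ScoreScale registry from YAML ({name: {lo, hi, direction}})."""
    raw = yaml.safe_load(Path(path).read_text())
    return {
        name: ScoreScale(name, float(d["lo"]), float(d["hi"]), d["direction"])
        for name, d in raw.items()
    }


def save_scales(scales: Mapping[str, ScoreScale], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({
        s.name: {"lo": s.lo, "hi": s.hi, "direction": s.direction}
        for s in scales.values()
    }))


def normalize_score(raw: float | None, scale: ScoreScale) -> float:
    """Linearly map an instrument score to [0, 1], 1 = healthy tissue.

    Pain-type instruments (``higher_is_worse``) are inverted so that 0 is
    always the worst damage or pain.  Missing input propagates to missing
    output.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    if scale.lo == scale.hi:  # defensive; ScoreScale already rejects this
        raise ValueError(f"degenerate scale {scale.name!r}")
    if not scale.lo <= raw <= scale.hi:
        raise ValueError(
            f"score {raw} outside [{scale.lo}, {scale.hi}] for scale {scale.name!r}"
        )
    unit = (raw - scale.lo) / (scale.hi - scale.lo)
    return unit if scale.direction == HIGHER_IS_HEALTHIER else 1.0 - unit


# ---------------------------------------------------------------------------
# records and derived properties
# ---------------------------------------------------------------------------

@dataclass
class TherapyRecord:
    """One study condition; any field may be missing (None)."""

    species: str | None = None
    body_weight_kg: float | None = None
    tissue_source: str | None = None
    cell_number: float | None = None
    cell_concentration_per_ml: float | None = None
    delivery_volume_ml: float | None = None
    defect_area_mm2: float | None = None
    defect_depth_mm: float | None = None
    defect_volume_mm3: float | None = None
    defect_area_pct: float | None = None
    defect_depth_pct: float | None = None
    damage_type: str | None = None
    score_name: str | None = None
    score_raw: float | None = None
    repair_score: float | None = None

    _POSITIVE = (
        "body_weight_kg", "cell_number", "cell_concentration_per_ml",
        "delivery_volume_ml", "defect_area_mm2", "defect_depth_mm",
        "defect_volume_mm3",
    )

    def validate(self) -> "TherapyRecord":
        if self.repair_score is not None and not 0.0 <= self.repair_score <= 1.0:
            raise ValueError(f"repair_score {self.repair_score} outside [0, 1]")
        for name in ("defect_area_pct", "defect_depth_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} {v} outside [0, 100]")
        for name in self._POSITIVE:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.tissue_source is not None and self.tissue_source not in TISSUE_SOURCES:
            raise ValueError(f"unknown tissue_source {self.tissue_source!r}")
        if self.damage_type is not None and self.damage_type not in DAMAGE_TYPES:
            raise ValueError(f"unknown damage_type {self.damage_type!r}")
        return self


@dataclass(frozen=True)
class SpeciesGeometry:
    """Reference knee-cartilage geometry for one species, used to express a
    defect as a percentage of the joint surface / cartilage thickness."""

    cartilage_area_mm2: float
    cartilage_depth_mm: float

    def __post_init__(self) -> None:
        if self.cartilage_area_mm2 <= 0 or self.cartilage_depth_mm <= 0:
            raise ValueError("reference geometry must be strictly positive")


def derive_properties(record: TherapyRecord,
                      refs: Mapping[str, SpeciesGeometry] | None = None) -> TherapyRecord:
    """Fill derivable missing fields; present fields are never overwritten.

    Derivations: defect volume = area x depth; implantation cell number =
    concentration x delivery volume; defect area/depth percentages from a
    per-species reference geometry when one is configured.  The operation is
    idempotent and a no-op where the inputs are themselves missing.
    """
    record.validate()
    out = TherapyRecord(**vars(record))
    if out.defect_volume_mm3 is None and None not in (out.defect_area_mm2, out.defect_depth_mm):
        out.defect_volume_mm3 = out.defect_area_mm2 * out.defect_depth_mm
    if out.cell_number is None and None not in (
        out.cell_concentration_per_ml, out.delivery_volume_ml
    ):
        out.cell_number = out.cell_concentration_per_ml * out.delivery_volume_ml
    if refs is not None and out.species in refs:
        geo = refs[out.species]
        if out.defect_area_pct is None and out.defect_area_mm2 is not None:
            out.defect_area_pct = 100.0 * out.defect_area_mm2 / geo.cartilage_area_mm2
        if out.defect_depth_pct is None and out.defect_depth_mm is not None:
            out.defect_depth_pct = min(
                100.0, 100.0 * out.defect_depth_mm / geo.cartilage_depth_mm
            )
    return out.validate()


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass
class ColumnSpec:
    """One slot of the encoded vector."""

    slot: str                      # encoded column name
    source: str                    # TherapyRecord / CSV field it comes from
    kind: str                      # "continuous" | "indicator"
    lo: float | None = None        # continuous bounds (fitted on training rows)
    hi: float | None = None
    level: str | None = None       # indicator level
    log10: bool = False            # scale on log10 axis (cell counts span decades)


@dataclass
class EncodingConfig:
    """Descriptor list and per-property encoding rules.

    Continuous properties are min-max scaled to [0, 1] with bounds fitted
    from training data only; encode-time values outside the fitted bounds
    are clipped to the boundary (tanh units saturate on raw magnitudes — the
    clip is reported via a warning flag on :meth:`encode_frame`).
    Categorical properties become one indicator slot per observed level.
    The outcome always occupies the final slot.
    """

    specs: list[ColumnSpec]
    outcome: str = "repair_score"
    consolidate_bm_ad: bool = False
    unseen_category_error: bool = True

    CONTINUOUS = {
        "body_weight_kg": True,     # value = log10 axis
        "cell_number": True,
        "cell_concentration_per_ml": True,
        "defect_area_mm2": False,
        "defect_depth_mm": False,
        "defect_volume_mm3": False,
        "defect_area_pct": False,
        "defect_depth_pct": False,
    }
    CATEGORICAL = {"tissue_source": TISSUE_SOURCES, "damage_type": DAMAGE_TYPES}

    @property
    def columns(self) -> list[str]:
        return [s.slot for s in self.specs] + [self.outcome]

    @property
    def width(self) -> int:
        return len(self.specs) + 1

    @classmethod
    def fit(cls, df: pd.DataFrame, descriptors: Iterable[str] | None = None,
            consolidate_bm_ad: bool = False) -> "EncodingConfig":
        """Fit encoding rules from a training table.

        ``descriptors`` selects and orders the condition properties; the
        default is every known property present in the table.
        """
        if descriptors is None:
            descriptors = [
                c for c in df.columns
                if (c in cls.CONTINUOUS or c in cls.CATEGORICAL)
                and df[c].notna().any()
            ]
        specs: list[ColumnSpec] = []
        for name in descriptors:
            if name in cls.CONTINUOUS:
                log10 = cls.CONTINUOUS[name]
                vals = pd.to_numeric(df[name], errors="coerce").dropna().to_numpy(float)
                if len(vals) == 0:
                    raise ValueError(f"no observed values to fit bounds for {name!r}")
                if log10:
                    vals = np.log10(vals)
                lo, hi = float(vals.min()), float(vals.max())
                if lo == hi:
                    hi = lo + 1.0  # constant column: encode as 0
                specs.append(ColumnSpec(name, name, "continuous", lo, hi, log10=log10))
            elif name in cls.CATEGORICAL:
                if name == "tissue_source" and consolidate_bm_ad:
                    specs.append(ColumnSpec("tissue_BM_or_AD", name, "indicator",
                                            level="BM|AD"))
                    levels = [l for l in cls.CATEGORICAL[name]
                              if l in set(df[name].dropna()) and l not in ("BM", "AD")]
                else:
                    levels = [l for l in cls.CATEGORICAL[name]
                              if l in set(df[name].dropna())]
                for level in levels:
                    specs.append(ColumnSpec(f"{name}_{level}", name, "indicator",
                                            level=level))
            else:
                raise KeyError(f"unknown descriptor {name!r}")
        return cls(specs, consolidate_bm_ad=consolidate_bm_ad)

    # -- encode ------------------------------------------------------------
    def _encode_cell(self, spec: ColumnSpec, value) -> tuple[float, bool]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return math.nan, False
        if spec.kind == "continuous":
            v = float(value)
            if spec.log10:
                if v <= 0:
                    raise ValueError(f"{spec.source} must be > 0 for log scaling")
                v = math.log10(v)
            unit = (v - spec.lo) / (spec.hi - spec.lo)
            return float(np.clip(unit, 0.0, 1.0)), True
        # indicator
        levels = spec.level.split("|")
        value = str(value)
        known = set(self.CATEGORICAL[spec.source])
        if value not in known:
            if self.unseen_category_error:
                raise ValueError(f"unseen {spec.source} level {value!r}")
            return 0.0, True
        return (1.0 if value in levels else 0.0), True

    def encode_frame(self, df: pd.DataFrame) -> Dataset:
        """Encode a schema table into a Dataset (outcome in the last slot)."""
        n = len(df)
        values = np.full((n, self.width), np.nan)
        mask = np.zeros((n, self.width), dtype=bool)
        for r in range(n):
            row = df.iloc[r]
            for c, spec in enumerate(self.specs):
                values[r, c], mask[r, c] = self._encode_cell(spec, row.get(spec.source))
            out = row.get(self.outcome)
            if out is not None and not (isinstance(out, float) and math.isnan(out)):
                values[r, -1], mask[r, -1] = float(out), True
        meta_cols = [c for c in ("species", "score_name") if c in df.columns]
        meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
        return Dataset(values, mask, self.columns, meta)

    def encode_record(self, record: TherapyRecord) -> PropertyVector:
        df = pd.DataFrame([{k: (np.nan if v is None else v) for k, v in vars(record).items()}])
        ds = self.encode_frame(df)
        return ds.entry(0)

    # -- decode ------------------------------------------------------------
    def decode_frame(self, ds: Dataset) -> pd.DataFrame:
        """Invert the encoding on known (or filled) slots; rounding aside,
        ``decode(encode(df)) == df`` on observed fields."""
        rows = []
        for r in range(ds.n_entries):
            rec: dict = {}
            cat_hits: dict[str, list[tuple[str, float]]] = {}
            for c, spec in enumerate(self.specs):
                v = ds.values[r, c]
                if not np.isfinite(v):
                    continue
                if spec.kind == "continuous":
                    raw = spec.lo + v * (spec.hi - spec.lo)
                    rec[spec.source] = 10.0**raw if spec.log10 else raw
                else:
                    cat_hits.setdefault(spec.source, []).append((spec.level, v))
            for source, hits in cat_hits.items():
                level, top = max(hits, key=lambda kv: kv[1])
                if top > 0.5:
                    rec[source] = level.split("|")[0]
            if np.isfinite(ds.values[r, -1]):
                rec[self.outcome] = ds.values[r, -1]
            rows.append(rec)
        df = pd.DataFrame(rows)
        if ds.meta is not None:
            for c in ds.meta.columns:
                if c not in df.columns:
                    df[c] = ds.meta[c].to_numpy()
        return df

    # -- config round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "consolidate_bm_ad": self.consolidate_bm_ad,
            "unseen_category_error": self.unseen_category_error,
            "specs": [vars(s) for s in self.specs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingConfig":
        return cls(
            [ColumnSpec(**s) for s in d["specs"]],
            outcome=d.get("outcome", "repair_score"),
            consolidate_bm_ad=d.get("consolidate_bm_ad", False),
            unseen_category_error=d.get("unseen_category_error", True),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EncodingConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# CSV database I/O
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA", "NaN"]


def read_table(path: str | Path, scales: Mapping[str, ScoreScale] | None = None,
               normalize: bool = True) -> pd.DataFrame:
    """Read the CSV database into a schema table.

    Empty cells denote missing (``NA``/``NaN`` are accepted on read, never
    written).  When ``normalize`` is true and ``repair_score`` is absent for
    a row but ``score_name``/``score_raw`` are present, the unit-interval
    score is computed from the (default or supplied) scale registry.
    """
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in {path}: {unknown}")
    numeric = [c for c in CSV_COLUMNS
               if c not in ("species", "tissue_source", "damage_type", "score_name")]
    for c in numeric:
        if c in df.columns:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[c], errors="coerce")
                rows = df.index[bad.isna() & df[c].notna()].tolist()
                raise ValueError(f"non-numeric value in column {c!r}, rows {rows}") from exc
    for c in ("species", "tissue_source", "damage_type", "score_name"):
        if c in df.columns:
            df[c] = df[c].where(df[c].notna(), None)
    if normalize and "score_raw" in df.columns and "score_name" in df.columns:
        registry = dict(DEFAULT_SCALES)
        if scales:
            registry.update(scales)
        if "repair_score" not in df.columns:
            df["repair_score"] = np.nan
        for i in df.index:
            if pd.isna(df.at[i, "repair_score"]) and df.at[i, "score_name"] is not None \
                    and not pd.isna(df.at[i, "score_raw"]):
                name = df.at[i, "score_name"]
                if name not in registry:
                    raise KeyError(f"no ScoreScale registered for {name!r} (row {i})")
                df.at[i, "repair_score"] = normalize_score(
                    float(df.at[i, "score_raw"]), registry[name]
                )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a schema table; missing cells become empty strings."""
    df.to_csv(path, index=False, na_rep="")


def read_dataset(path: str | Path, cfg: EncodingConfig | None = None,
                 **read_kwargs) -> tuple[Dataset, EncodingConfig]:
    """Read and encode the CSV database.

    With ``cfg=None`` the encoding is fitted from the file itself (all
    recognized properties, file order); pass a fitted config to encode new
    rows against training-time bounds.
    """
    df = read_table(path, **read_kwargs)
    if cfg is None:
        cfg = EncodingConfig.fit(df)
    return cfg.encode_frame(df), cfg


def write_dataset(ds: Dataset, cfg: EncodingConfig, path: str | Path) -> None:
    write_table(cfg.decode_frame(ds), path)
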