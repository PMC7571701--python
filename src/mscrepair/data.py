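"""Numeric containers for encoded therapy records.

A therapy record is encoded as a length-``I`` property vector: slots
``1..I-1`` hold the (scaled) treatment conditions and slot ``I`` holds the
therapeutic outcome, the cartilage repair score on the unit interval.  A
boolean mask runs alongside the values: ``True`` marks a slot that was
observed in the source study, ``False`` a slot that is missing and may only
ever be filled by imputation.  Missing slots hold ``NaN`` until filled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PropertyVector", "Dataset"]


@dataclass
class PropertyVector:
    """One encoded entry: values plus a known/missing mask.

    ``values[i]`` is ``NaN`` whenever ``mask[i]`` is ``False`` and the slot
    has not yet been filled; the model cost function never reads an
    unobserved slot as a target.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValueError(
                f"values {self.values.shape} and mask {self.mask.shape} must be "
                "equal-length 1-D arrays"
            )

    @property
    def width(self) -> int:
        return self.values.shape[0]

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    def copy(self) -> "PropertyVector":
        return PropertyVector(self.values.copy(), self.mask.copy())


@dataclass
class Dataset:
    """An ordered collection of encoded entries sharing one descriptor order.

    ``values`` is the ``(N, I)`` matrix of encoded entries, ``mask`` the
    matching observation indicator (``True`` = observed).  ``columns`` names
    the ``I`` slots; by convention the last column is the outcome.  ``meta``
    optionally carries row-aligned provenance (study label, species, ...).
    """

    values: np.ndarray
    mask: np.ndarray
    columns: list[str]
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.columns = list(self.columns)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be matching (N, I) arrays")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{len(self.columns)} column names for {self.values.shape[1]} slots"
            )
        if self.values.shape[0] < 1:
            raise ValueError("a dataset needs at least one entry")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_entries(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def outcome_column(self) -> str:
        return self.columns[-1]

    def entry(self, idx: int) -> PropertyVector:
        return PropertyVector(self.values[idx].copy(), self.mask[idx].copy())

    def copy(self) -> "Dataset":
        return Dataset(
            self.values.copy(),
            self.mask.copy(),
            list(self.columns),
            None if self.meta is None else self.meta.copy(),
        )

    # -- slicing -----------------------------------------------------------
    def subset_rows(self, rows: Sequence[int] | np.ndarray) -> "Dataset":
        rows = np.asarray(rows, dtype=int)
        meta = self.meta.iloc[rows].reset_index(drop=True) if self.meta is not None else None
        return Dataset(self.values[rows].copy(), self.mask[rows].copy(), list(self.columns), meta)

    def drop_row(self, idx: int) -> "Dataset":
        keep = [i for i in range(self.n_entries) if i != idx]
        return self.subset_rows(keep)

    def select_columns(self, condition_columns: Iterable[str]) -> "Dataset":
        """Restrict to a subset of condition columns; the outcome is kept."""
        names = list(condition_columns)
        unknown = [c for c in names if c not in self.columns[:-1]]
        if unknown:
            raise KeyError(f"unknown condition columns: {unknown}")
        idx = [self.columns.index(c) for c in names] + [self.width - 1]
        return Dataset(
            self.values[:, idx].copy(), self.mask[:, idx].copy(),
            names + [self.outcome_column], self.meta,
        )

    def consolidate_columns(self, sources: Sequence[str], new_name: str) -> "Dataset":
        """Merge indicator columns into a single any-of indicator.

        The merged slot is observed only when every source slot is observed;
        its value is the maximum of the sources (1 if any level applies).
        """
        idx = [self.columns.index(c) for c in sources]
        keep = [i for i in range(self.width) if i not in idx]
        merged_vals = np.nanmax(self.values[:, idx], axis=1)
        merged_mask = self.mask[:, idx].all(axis=1)
        merged_vals = np.where(merged_mask, merged_vals, np.nan)
        insert_at = min(idx)
        # rebuild preserving original column order, merged slot at the first source position
        new_cols: list[str] = []
        cols_vals: list[np.ndarray] = []
        cols_mask: list[np.ndarray] = []
        for i in range(self.width):
            if i == insert_at:
                new_cols.append(new_name)
                cols_vals.append(merged_vals)
                cols_mask.append(merged_mask)
            if i in idx:
                continue
            new_cols.append(self.columns[i])
            cols_vals.append(self.values[:, i])
            cols_mask.append(self.mask[:, i])
        return Dataset(
            np.column_stack(cols_vals), np.column_stack(cols_mask), new_cols, self.meta
        )

    # -- filling -----------------------------------------------------------
    def column_means(self) -> np.ndarray:
        """Per-slot mean of observed values; NaN for a slot never observed."""
        with np.errstate(invalid="ignore"):
            sums = np.where(self.mask, self.values, 0.0).sum(axis=0)
            counts = self.mask.sum(axis=0)
        out = np.full(self.width, np.nan)
        nz = counts > 0
        out[nz] = sums[nz] / counts[nz]
        return out

    def filled(self, fill: np.ndarray | None = None) -> "Dataset":
        """Return a copy with missing slots replaced (default: column means).

        The mask is untouched: filled slots remain flagged as unobserved.
        """
        if fill is None:
            fill = self.column_means()
        fill = np.asarray(fill, dtype=float)
        if not np.isfinite(fill[(~self.mask).any(axis=0)]).all():
            bad = [
                self.columns[j]
                for j in range(self.width)
                if (~self.mask[:, j]).any() and not np.isfinite(fill[j])
            ]
            raise ValueError(f"no observed values to fill columns: {bad}")
        values = np.where(self.mask, self.values, fill[None, :])
        return Dataset(values, self.mask.copy(), list(self.columns), self.meta)

    def has_missing(self) -> bool:
        return bool((~self.mask).any())

    # -- canonical ordering and hashing -------------------------------------
    def canonical_order(self) -> np.ndarray:
        """Row permutation sorting entries lexicographically.

        Used by cross-validation so that fold results do not depend on the
        order entries happen to be stored in.
        """
        keys = np.nan_to_num(self.values, nan=-1e30)
        cols = [self.mask[:, j] for j in range(self.width - 1, -1, -1)]
        cols = [keys[:, j] for j in range(self.width - 1, -1, -1)] + cols
        return np.lexsort(cols)

    def row_digest(self, idx: int) -> int:
        """Stable 31-bit digest of one entry's content (order-independent id)."""
        payload = np.ascontiguousarray(
            np.concatenate([np.nan_to_num(self.values[idx], nan=-1e30), self.mask[idx]])
        ).tobytes()
        return zlib.crc32(payload) & 0x7FFFFFFF
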