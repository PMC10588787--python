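"""Core in-memory containers shared by every pipeline stage.

An :class:`AnalyteMatrix` holds one omics block (plasma proteins,
eicosanoids or targeted metabolites) as a samples × analytes table plus two
disjoint boolean masks: values missing for technical reasons (proteomics
missing values) and values censored below the detection limit (eicosanoids).
:class:`SampleMeta` carries the per-sample group label and the two measured
confounders, age and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("healthy", "remission", "active")
BLOCKS = ("protein", "eicosanoid", "metabolite")

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"


class TriomicsError(ValueError):
    """Base error for invalid inputs to the pipeline."""


def _empty_mask(values: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(False, index=values.index, columns=values.columns)


@dataclass
class AnalyteMatrix:
    """One omics block: samples in rows, analytes in columns.

    ``values`` may contain NaN exactly where one of the masks is set.
    ``scale`` tracks whether intensities are raw (positive, pre-log) or
    log2-transformed. ``imputed_mask`` records provenance of cells filled in
    by an imputation step; those cells are no longer flagged in
    ``missing_mask`` / ``below_lod_mask``.
    """

    values: pd.DataFrame
    block_label: str
    scale: str = SCALE_LOG2
    missing_mask: pd.DataFrame = None  # type: ignore[assignment]
    below_lod_mask: pd.DataFrame = None  # type: ignore[assignment]
    imputed_mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.block_label not in BLOCKS:
            raise TriomicsError(
                f"unknown block label {self.block_label!r}; expected one of {BLOCKS}"
            )
        if self.scale not in (SCALE_RAW, SCALE_LOG2):
            raise TriomicsError(f"unknown scale {self.scale!r}")
        if self.missing_mask is None:
            self.missing_mask = _empty_mask(self.values)
        if self.below_lod_mask is None:
            self.below_lod_mask = _empty_mask(self.values)
        if self.imputed_mask is None:
            self.imputed_mask = _empty_mask(self.values)
        for name in ("missing_mask", "below_lod_mask", "imputed_mask"):
            mask = getattr(self, name)
            if mask.shape != self.values.shape:
                raise TriomicsError(f"{name} shape {mask.shape} != values shape")
        if (
            self.missing_mask.to_numpy(dtype=bool)
            & self.below_lod_mask.to_numpy(dtype=bool)
        ).any():
            raise TriomicsError("missing_mask and below_lod_mask must be disjoint")
        if self.values.columns.duplicated().any():
            raise TriomicsError("analyte ids must be unique")
        if self.values.index.duplicated().any():
            raise TriomicsError("sample ids must be unique")

    # -- convenience accessors -------------------------------------------

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def observed_mask(self) -> pd.DataFrame:
        """True where a cell carries a measured (non-masked) value."""
        return ~(self.missing_mask | self.below_lod_mask)

    def copy(self) -> "AnalyteMatrix":
        return replace(
            self,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            below_lod_mask=self.below_lod_mask.copy(),
            imputed_mask=self.imputed_mask.copy(),
        )

    def select_analytes(self, keep) -> "AnalyteMatrix":
        """Sub-matrix restricted to ``keep`` analytes, order preserved."""
        keep = list(keep)
        return replace(
            self,
            values=self.values[keep].astype(float),
            missing_mask=self.missing_mask[keep].astype(bool),
            below_lod_mask=self.below_lod_mask[keep].astype(bool),
            imputed_mask=self.imputed_mask[keep].astype(bool),
        )

    def require_complete(self, context: str = "") -> None:
        if self.values.isna().to_numpy().any():
            raise TriomicsError(
                f"matrix for block {self.block_label!r} still contains missing "
                f"values{'; ' + context if context else ''}"
            )


@dataclass
class SampleMeta:
    """Per-sample metadata: group in {healthy, remission, active}, age, sex.

    Sex is coded 0/1 and enters every model as a numeric column.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"group", "age", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise TriomicsError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise TriomicsError(f"unknown group labels: {sorted(bad)}")
        if self.table.index.duplicated().any():
            raise TriomicsError("sample ids must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    @property
    def age(self) -> pd.Series:
        return self.table["age"].astype(float)

    @property
    def sex(self) -> pd.Series:
        return self.table["sex"].astype(float)

    def group_members(self, group: str) -> pd.Index:
        if group not in GROUPS:
            raise TriomicsError(f"unknown group {group!r}")
        return self.table.index[self.table["group"] == group]

    def check_alignment(self, matrix: AnalyteMatrix) -> None:
        if not matrix.sample_ids.equals(self.sample_ids):
            raise TriomicsError(
                f"sample ordering of block {matrix.block_label!r} does not "
                "match the metadata"
            )


def warn(message: str) -> None:
    """Single funnel for data-quality warnings (filterable by category)."""
    warnings.warn(message, UserWarning, stacklevel=3)
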