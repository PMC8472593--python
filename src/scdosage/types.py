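"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are internal BED convention: 0-based, half-open
[start, end). Conversions from 1-based closed inputs happen at read time and
nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    DuplicateIdError,
    MetadataError,
    NaNValueError,
    NegativeValueError,
    OverlappingSegmentsError,
    UnknownStateError,
)

# copy-number states
GAIN = "GAIN"
NEUTRAL = "NEUTRAL"
LOSS = "LOSS"
UNKNOWN = "UNKNOWN"
CNV_STATES = (GAIN, NEUTRAL, LOSS)

# regulation directions
UP = "UP"
DOWN = "DOWN"
NONE = "NONE"


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()[:5]
        raise DuplicateIdError(f"duplicate {kind} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values in TPM.

    ``values[i, j]`` is the TPM of ``gene_ids[i]`` in ``cell_ids[j]``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MetadataError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(self.values).all():
            raise NaNValueError("expression matrix contains NaN or infinite values")
        if (self.values < 0).any():
            raise NegativeValueError("expression matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.cell_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellMetadata:
    """cell_id -> patient_id assignment."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def patient_of(self, cell_id: str) -> str:
        try:
            return self.mapping[cell_id]
        except KeyError:
            raise MetadataError(f"cell {cell_id!r} has no patient assignment") from None

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [c for c in expr.cell_ids if c not in self.mapping]
        if missing:
            raise MetadataError(
                f"{len(missing)} expression cells missing from metadata, e.g. {missing[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": list(self.mapping), "patient_id": list(self.mapping.values())}
        )


@dataclass
class GeneAnnotation:
    """Genomic location of each gene: one record per gene_id, BED semantics."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        req = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise MetadataError(f"gene annotation missing columns {missing}")
        t = self.table.loc[:, req].copy()
        t["gene_id"] = t["gene_id"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        _check_unique(t["gene_id"], "gene annotation")
        if (t["start"] < 0).any():
            raise CoordinateError("gene annotation has negative start coordinate")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "gene_id"].tolist()[:5]
            raise CoordinateError(f"gene annotation has empty/inverted intervals: {bad}")
        if not t["strand"].isin(["+", "-", "."]).all():
            raise CoordinateError("strand must be one of '+', '-', '.'")
        self.table = t.reset_index(drop=True)

    @property
    def chromosomes(self) -> set[str]:
        return set(self.table["chrom"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CNVSegmentSet:
    """Per-patient copy-number segments (bulk calls), internal coordinates.

    Either ``copy_number`` (non-negative real, NaN when unknown) or a
    pre-called ``state`` in {GAIN, NEUTRAL, LOSS} must be present per record.
    """

    table: pd.DataFrame  # columns: patient_id, chrom, start, end, copy_number, state

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("patient_id", "chrom"):
            if col not in t.columns:
                raise MetadataError(f"CNV segments missing column {col!r}")
            t[col] = t[col].astype(str)
        for col in ("start", "end"):
            if col not in t.columns:
                raise MetadataError(f"CNV segments missing column {col!r}")
            t[col] = t[col].astype(np.int64)
        if "copy_number" not in t.columns:
            t["copy_number"] = np.nan
        t["copy_number"] = t["copy_number"].astype(float)
        if "state" not in t.columns:
            t["state"] = np.nan
        t["state"] = t["state"].astype(object).where(t["state"].notna(), np.nan)
        if (t["start"] < 0).any():
            raise CoordinateError("CNV segment with negative start coordinate")
        if (t["start"] >= t["end"]).any():
            raise CoordinateError("CNV segment with start >= end after normalization")
        neg_cn = t["copy_number"].notna() & (t["copy_number"] < 0)
        if neg_cn.any():
            raise NegativeValueError("CNV segment with negative copy number")
        bad_state = t["state"].notna() & ~t["state"].isin(CNV_STATES)
        if bad_state.any():
            tok = t.loc[bad_state, "state"].unique().tolist()[:5]
            raise UnknownStateError(f"unknown copy-number state tokens: {tok}")
        self._check_no_self_overlap(t)
        self.table = t.reset_index(drop=True)

    @staticmethod
    def _check_no_self_overlap(t: pd.DataFrame) -> None:
        for (pat, chrom), grp in t.groupby(["patient_id", "chrom"], sort=False):
            g = grp.sort_values("start")
            prev_end = g["end"].shift(1)
            clash = g["start"] < prev_end.fillna(-1)
            if clash.any():
                raise OverlappingSegmentsError(
                    f"patient {pat!r} has overlapping CNV segments on {chrom!r}"
                )

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.table["patient_id"]))

    @property
    def chromosomes(self) -> set[str]:
        return set(self.table["chrom"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set_name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, members) in self.sets.items():
            members = tuple(dict.fromkeys(str(m) for m in members))
            if not members:
                raise MetadataError(f"gene set {name!r} is empty")
            clean[str(name)] = (str(desc), members)
        self.sets = clean

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)
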