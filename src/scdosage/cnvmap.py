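"""Assign each gene a per-patient copy-number state by genomic overlap.

CNV calls come from bulk DNA sequencing, so a patient's copy-number state is
broadcast to all of that patient's cells downstream. Overlap uses half-open
interval arithmetic: gene [gs, ge) and segment [ss, se) overlap iff
max(gs, ss) < min(ge, se), and the overlap must span at least
``min_overlap_bp`` bases (default 1, i.e. any overlap counts). A gene
spanning several segments of one patient takes the segment with the larger
overlap; ties go to the segment whose copy number deviates more from
diploid, then to the leftmost segment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .types import GAIN, LOSS, NEUTRAL, UNKNOWN, CNVSegmentSet, GeneAnnotation

ASSIGNMENT_COLUMNS = [
    "patient_id", "gene_id", "chrom", "copy_number", "state", "overlap_bp",
]


@dataclass(frozen=True)
class CNVStateRule:
    """Numeric copy-number -> state thresholds.

    GAIN iff cn >= gain_min_cn; LOSS iff cn <= loss_max_cn; else NEUTRAL.
    ``precalled_state`` mode passes through states already present on the
    segments instead.
    """

    gain_min_cn: float = 3.0
    loss_max_cn: float = 1.0
    mode: str = "absolute_cn"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute_cn", "precalled_state"):
            raise ValidationError(f"unknown CNV state mode {self.mode!r}")
        if not self.loss_max_cn < self.gain_min_cn:
            raise ValidationError("loss_max_cn must be below gain_min_cn")


def overlap_genes(
    annotation: GeneAnnotation,
    segments: CNVSegmentSet,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Map every (patient, gene) pair to its best-overlapping CNV segment.

    Returns a table with one row per patient x gene; pairs with no
    qualifying segment get state UNKNOWN, overlap_bp 0 and NaN copy number.
    """
    if len(annotation) == 0:
        raise ValidationError("empty gene annotation")
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    ann_chroms = annotation.chromosomes
    seg_chroms = segments.chromosomes
    if len(segments) and ann_chroms.isdisjoint(seg_chroms):
        raise ValidationError(
            "gene annotation and CNV segments share no chromosome names "
            f"(genes: {sorted(ann_chroms)[:3]}..., segments: {sorted(seg_chroms)[:3]}...)"
        )
    only_seg = seg_chroms - ann_chroms
    if only_seg:
        warnings.warn(f"CNV chromosomes absent from annotation: {sorted(only_seg)[:5]}")

    # one interval tree per (patient, chromosome)
    trees: dict[tuple[str, str], IntervalTree] = {}
    seg_t = segments.table
    for idx, row in enumerate(seg_t.itertuples(index=False)):
        trees.setdefault((row.patient_id, row.chrom), IntervalTree()).addi(
            row.start, row.end, idx
        )

    patients = segments.patients
    rows: list[tuple] = []
    for gene in annotation.table.itertuples(index=False):
        for pat in patients:
            tree = trees.get((pat, gene.chrom))
            best = None  # (overlap_bp, |cn - 2|, -start, idx)
            if tree is not None:
                for iv in tree.overlap(gene.start, gene.end):
                    ov = min(gene.end, iv.end) - max(gene.start, iv.begin)
                    if ov < min_overlap_bp:
                        continue
                    cn = seg_t.at[iv.data, "copy_number"]
                    dev = abs(cn - 2.0) if np.isfinite(cn) else -1.0
                    key = (ov, dev, -iv.begin, iv.data)
                    if best is None or key > best:
                        best = key
            if best is None:
                rows.append((pat, gene.gene_id, gene.chrom, np.nan, UNKNOWN, 0))
            else:
                idx = best[3]
                rows.append(
                    (
                        pat,
                        gene.gene_id,
                        gene.chrom,
                        seg_t.at[idx, "copy_number"],
                        seg_t.at[idx, "state"],
                        int(best[0]),
                    )
                )
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    out["overlap_bp"] = out["overlap_bp"].astype(np.int64)
    return out


def classify_cnv_state(assignment: pd.DataFrame, rule: CNVStateRule | None = None) -> pd.DataFrame:
    """Fill the ``state`` column from numeric copy number (or validate
    pre-called states). UNKNOWN rows stay UNKNOWN."""
    rule = rule or CNVStateRule()
    out = assignment.copy()
    assigned = out["state"] != UNKNOWN
    if rule.mode == "precalled_state":
        if out.loc[assigned, "state"].isna().any():
            raise ValidationError("precalled_state mode but segments carry no state")
        return out
    cn = out["copy_number"]
    if cn[assigned].isna().any():
        raise ValidationError("absolute_cn mode but copy_number missing on assigned rows")
    state = np.where(cn >= rule.gain_min_cn, GAIN, np.where(cn <= rule.loss_max_cn, LOSS, NEUTRAL))
    out["state"] = np.where(assigned, state, UNKNOWN)
    return out
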