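"""Concordant CNV-expression event calling and recurrence ranking.

An *event* is a (gene, cell) pair where the gene sits in a non-neutral CNV
segment of the cell's patient and the cell's Z-score survives the dropout
mask. An event is *informative* when |z| exceeds the significance threshold,
and *concordant* when the directions agree: copy-number gain with
up-regulation (CNG-UP) or loss with down-regulation (CNL-DOWN). Genes are
then ranked by how many distinct cells show a concordant event; a hard
cell-count cutoff (e.g. 100 cells in a ~1500-cell dataset, 6 in a ~130-cell
one) keeps only recurrent dosage effects.
"""
from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .dosage import DEFAULT_Z_THRESHOLD, ZScoreMatrix
from .errors import ValidationError
from .types import DOWN, GAIN, LOSS, NONE, UP, CellMetadata

EVENT_COLUMNS = [
    "gene_id", "cell_id", "patient_id", "z", "cnv_state", "direction", "informative",
]

CONCORDANCE_MODES = ("CNG_UP", "CNL_DOWN", "BOTH")


class EventCensus(NamedTuple):
    total: int
    informative: int
    non_informative: int
    n_cells: int
    n_genes: int


class CrossValidation(NamedTuple):
    genes_a: frozenset
    genes_b: frozenset
    intersection: frozenset
    union: frozenset


def call_events(
    z: ZScoreMatrix,
    assignment: pd.DataFrame,
    meta: CellMetadata,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Enumerate unique (gene, cell) CNV-expression events.

    ``assignment`` is the per-(patient, gene) state table from
    :func:`scdosage.cnvmap.overlap_genes` / ``classify_cnv_state``.
    """
    if not z_threshold > 0:
        raise ValidationError("z threshold must be positive")
    gene_pos = z.gene_index()
    patients_of_cells = np.array([meta.patient_of(c) for c in z.cell_ids])
    cell_ids = np.asarray(z.cell_ids)

    hot = assignment[assignment["state"].isin([GAIN, LOSS])]
    rows: list[pd.DataFrame] = []
    for pat, grp in hot.groupby("patient_id", sort=True):
        cols = np.flatnonzero(patients_of_cells == pat)
        if cols.size == 0:
            continue
        genes = [g for g in grp["gene_id"] if g in gene_pos]
        if not genes:
            continue
        gidx = np.array([gene_pos[g] for g in genes])
        states = grp.set_index("gene_id").loc[genes, "state"].to_numpy()
        sub_z = z.z[np.ix_(gidx, cols)]
        sub_ok = ~z.masked[np.ix_(gidx, cols)]
        gi, ci = np.nonzero(sub_ok)
        if gi.size == 0:
            continue
        zv = sub_z[gi, ci]
        direction = np.where(zv > z_threshold, UP, np.where(zv < -z_threshold, DOWN, NONE))
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": np.asarray(genes, dtype=object)[gi],
                    "cell_id": cell_ids[cols][ci],
                    "patient_id": pat,
                    "z": zv,
                    "cnv_state": states[gi],
                    "direction": direction,
                    "informative": np.abs(zv) > z_threshold,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    events = pd.concat(rows, ignore_index=True)
    # uniqueness per (gene, cell) holds by construction; assert the contract
    if events.duplicated(["gene_id", "cell_id"]).any():
        raise AssertionError("duplicate (gene, cell) events")
    return events.sort_values(["gene_id", "cell_id"], kind="mergesort").reset_index(drop=True)


def event_census(events: pd.DataFrame) -> EventCensus:
    """Totals used in run reports: every event is informative or not."""
    total = len(events)
    informative = int(events["informative"].sum()) if total else 0
    return EventCensus(
        total=total,
        informative=informative,
        non_informative=total - informative,
        n_cells=int(events["cell_id"].nunique()) if total else 0,
        n_genes=int(events["gene_id"].nunique()) if total else 0,
    )


def filter_concordant(events: pd.DataFrame, mode: str = "CNG_UP") -> pd.DataFrame:
    """Keep informative events whose CNV state and regulation agree."""
    if mode not in CONCORDANCE_MODES:
        raise ValidationError(f"unknown concordance mode {mode!r}")
    if len(events) == 0:
        return events.copy()
    up = (events["cnv_state"] == GAIN) & (events["direction"] == UP)
    down = (events["cnv_state"] == LOSS) & (events["direction"] == DOWN)
    keep = {"CNG_UP": up, "CNL_DOWN": down, "BOTH": up | down}[mode]
    return events[keep & events["informative"]].reset_index(drop=True)


def recurrence_table(events: pd.DataFrame, min_cells: int = 100) -> pd.DataFrame:
    """Rank genes by the number of distinct cells with a concordant event.

    Only genes seen in ``min_cells`` or more cells are retained. Ordering is
    deterministic: n_cells desc, mean_z desc, gene_id asc.
    """
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    if len(events) == 0:
        return pd.DataFrame(columns=["gene_id", "n_cells", "n_events", "patients_hit", "mean_z"])
    grouped = events.groupby("gene_id", sort=False)
    table = pd.DataFrame(
        {
            "n_cells": grouped["cell_id"].nunique(),
            "n_events": grouped.size(),
            "patients_hit": grouped["patient_id"].agg(lambda s: frozenset(s)),
            "mean_z": grouped["z"].mean(),
        }
    ).reset_index()
    table = table[table["n_cells"] >= min_cells]
    table = table.sort_values(
        ["n_cells", "mean_z", "gene_id"], ascending=[False, False, True], kind="mergesort"
    )
    return table.reset_index(drop=True)


def _gene_set(table) -> frozenset:
    if isinstance(table, pd.DataFrame):
        return frozenset(table["gene_id"])
    return frozenset(table)


def cross_validate(table_a, table_b) -> CrossValidation:
    """Set algebra over the retained genes of two analyses (e.g. a primary
    and an independent validation dataset)."""
    a, b = _gene_set(table_a), _gene_set(table_b)
    return CrossValidation(a, b, a & b, a | b)
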