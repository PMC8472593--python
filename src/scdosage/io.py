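"""Readers and writers for every external format the pipeline touches.

Formats supported:

* expression — dense TSV (header row of cell ids, first column gene ids) or
  MatrixMarket triplet with sidecar row/column name files (one id per line);
* cell metadata — TSV with ``cell_id`` and ``patient_id`` columns;
* gene annotation — BED4+ (chrom, start, end, gene id[, score, strand]);
* CNV segments — SEG-like TSV with a ``coordinate_origin`` flag;
* gene sets — GMT;
* interaction network — two-column TSV edge list or SIF;
* all stage outputs — TSV with a header row.

Coordinates are normalized to 0-based half-open at read time; every
downstream module assumes that convention.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    MalformedHeaderError,
    MetadataError,
    NaNValueError,
    NegativeValueError,
    ValidationError,
)
from .types import (
    CellMetadata,
    CNVSegmentSet,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetCollection,
)

EXPRESSION_FORMATS = ("dense_tsv", "mtx_triplet")
COORDINATE_ORIGINS = ("zero_half_open", "one_closed")


# ---------------------------------------------------------------------------
# expression

def read_expression_matrix(
    path: str,
    format: str = "dense_tsv",
    row_names: str | None = None,
    col_names: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x cell TPM matrix.

    For ``mtx_triplet``, ``row_names`` and ``col_names`` point to sidecar
    files with one gene / cell identifier per line; they default to
    ``<path>.rows`` and ``<path>.cols``.
    """
    if format not in EXPRESSION_FORMATS:
        raise ValidationError(f"unknown expression format {format!r}")
    if format == "dense_tsv":
        return _read_dense_tsv(path)
    return _read_mtx_triplet(path, row_names, col_names)


def _read_dense_tsv(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise MalformedHeaderError(f"{path}: expected a header with >= 2 columns")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[1] != len(header) - 1:
        raise MalformedHeaderError(f"{path}: header width inconsistent with data rows")
    values = df.to_numpy(dtype=float)  # raises on non-numeric tokens
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def _read_name_file(path: str, kind: str) -> list[str]:
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip()]
    if not names:
        raise MalformedHeaderError(f"{path}: empty {kind} name file")
    return names


def _read_mtx_triplet(path: str, row_names: str | None, col_names: str | None) -> ExpressionMatrix:
    row_names = row_names or path + ".rows"
    col_names = col_names or path + ".cols"
    genes = _read_name_file(row_names, "gene")
    cells = _read_name_file(col_names, "cell")
    mat = scipy.io.mmread(path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise MetadataError(
            f"{path}: matrix shape {dense.shape} != names ({len(genes)}, {len(cells)})"
        )
    return ExpressionMatrix(genes, cells, dense)


def write_expression_matrix(expr: ExpressionMatrix, path: str) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def tpm_from_counts(
    counts: np.ndarray,
    gene_lengths: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
) -> ExpressionMatrix:
    """Convert a gene x cell count matrix to TPM.

    Per cell: rate_g = count_g / length_g, then scaled so the cell column
    sums to 1e6. Constant column sums make expression proportions comparable
    across cells regardless of sequencing depth.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise MetadataError("gene_lengths must match the number of count rows")
    if not np.isfinite(counts).all():
        raise NaNValueError("count matrix contains NaN or infinite values")
    if (counts < 0).any():
        raise NegativeValueError("count matrix contains negative values")
    if (lengths <= 0).any():
        raise ValidationError("every gene length must be positive")
    rate = counts / lengths[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        raise ValidationError("all-zero cell: TPM undefined")
    tpm = rate / colsum[None, :] * 1e6
    return ExpressionMatrix(list(gene_ids), list(cell_ids), tpm)


# ---------------------------------------------------------------------------
# metadata / annotation / segments

def read_cell_metadata(path: str) -> CellMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "patient_id"):
        if col not in df.columns:
            raise MalformedHeaderError(f"{path}: missing column {col!r}")
    if df["cell_id"].duplicated().any():
        raise MetadataError(f"{path}: duplicate cell ids in metadata")
    return CellMetadata(dict(zip(df["cell_id"], df["patient_id"])))


def write_cell_metadata(meta: CellMetadata, path: str) -> None:
    meta.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str) -> GeneAnnotation:
    """BED4+: chrom, start, end, gene_id and optionally score, strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise MalformedHeaderError(f"{path}: BED file needs >= 4 columns")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3],
            "chrom": df.iloc[:, 0],
            "start": df.iloc[:, 1].astype(np.int64),
            "end": df.iloc[:, 2].astype(np.int64),
            "strand": df.iloc[:, 5] if df.shape[1] >= 6 else ".",
        }
    )
    return GeneAnnotation(out)


def write_gene_annotation(ann: GeneAnnotation, path: str) -> None:
    t = ann.table
    bed = pd.DataFrame(
        {
            0: t["chrom"],
            1: t["start"],
            2: t["end"],
            3: t["gene_id"],
            4: 0,
            5: t["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


_CNV_COLUMN_ALIASES = {
    "patient": "patient_id",
    "sample": "patient_id",
    "sample_id": "patient_id",
    "chromosome": "chrom",
    "chr": "chrom",
    "cn": "copy_number",
    "copynumber": "copy_number",
}


def read_cnv_segments(path: str, coordinate_origin: str = "zero_half_open") -> CNVSegmentSet:
    """Read SEG-like per-patient CNV segments.

    ``one_closed`` inputs (SEG convention) are converted to the internal
    0-based half-open coordinates by decrementing ``start`` by one.
    """
    if coordinate_origin not in COORDINATE_ORIGINS:
        raise ValidationError(f"unknown coordinate origin {coordinate_origin!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [_CNV_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    for col in ("patient_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise MalformedHeaderError(f"{path}: missing column {col!r}")
    if "copy_number" not in df.columns and "state" not in df.columns:
        raise MalformedHeaderError(f"{path}: need a copy_number or state column")
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
        }
    )
    if coordinate_origin == "one_closed":
        out["start"] = out["start"] - 1
    if "copy_number" in df.columns:
        out["copy_number"] = pd.to_numeric(df["copy_number"], errors="raise")
    if "state" in df.columns:
        out["state"] = df["state"].str.upper()
    return CNVSegmentSet(out)


def write_cnv_segments(segments: CNVSegmentSet, path: str) -> None:
    segments.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets / network

def read_gene_sets(path: str) -> GeneSetCollection:
    """GMT: one set per line — name, description, then member gene ids."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedHeaderError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, desc, *members = fields
            if name in sets:
                raise MetadataError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = (desc, tuple(m for m in members if m))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_network(path: str, format: str | None = None):
    """Read an undirected simple interaction network.

    ``format`` is ``tsv`` (two columns per edge) or ``sif`` (node, relation,
    partners); inferred from the extension when omitted. Self-loops are
    rejected; duplicate edges collapse.
    """
    import networkx as nx

    if format is None:
        format = "sif" if path.lower().endswith(".sif") else "tsv"
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "sif":
                if len(fields) < 3:
                    if len(fields) == 1:  # isolated node
                        graph.add_node(fields[0])
                        continue
                    raise MalformedHeaderError(f"{path}:{lineno}: malformed SIF line")
                src, _rel, *targets = fields
                pairs = [(src, t) for t in targets]
            else:
                if len(fields) < 2:
                    raise MalformedHeaderError(f"{path}:{lineno}: edge line needs 2 columns")
                pairs = [(fields[0], fields[1])]
            for a, b in pairs:
                if a == b:
                    raise ValidationError(f"{path}:{lineno}: self-loop on {a!r} rejected")
                graph.add_edge(a, b)
    return graph


def write_network(graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# stage outputs

def write_event_table(events: pd.DataFrame, path: str) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_event_table(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "cell_id": str, "patient_id": str},
    )


def write_recurrence_table(table: pd.DataFrame, path: str) -> None:
    out = table.copy()
    if "patients_hit" in out.columns:
        out["patients_hit"] = out["patients_hit"].map(
            lambda s: ",".join(sorted(s)) if isinstance(s, (set, frozenset)) else s
        )
    out.to_csv(path, sep="\t", index=False)


def read_recurrence_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "patients_hit" in df.columns:
        df["patients_hit"] = df["patients_hit"].map(
            lambda s: set(str(s).split(",")) if pd.notna(s) and str(s) else set()
        )
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
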