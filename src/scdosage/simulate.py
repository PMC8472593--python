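"""Matched synthetic CNV + scRNA-seq datasets with planted dosage effects.

The generator emulates the study design the pipeline targets: a handful of
patients, each with bulk CNV segment calls and a few hundred single cells
quantified in TPM. Expression is log-normal per gene; genes inside a
patient's CNV segment have their mean multiplied by (CN/2)^beta, the gene
dosage effect (beta = 1 means expression proportional to copy number;
beta = 0 is the null model where CNV leaves expression untouched). Dropout
is an expression-dependent logistic on log expression, so lowly expressed
transcripts are lost far more often than abundant ones — the dominant
failure mode of droplet scRNA-seq. Columns are TPM-normalized to 1e6 after
dropout.

Every dataset ships its own ground truth (which genes sit in which planted
segment, and the planted dense network module), so recovery of the
concordance and module stages can be scored exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from . import io as _io
from .types import (
    CellMetadata,
    CNVSegmentSet,
    ExpressionMatrix,
    GeneAnnotation,
)

GENE_LENGTH = 1_000  # bp
GENE_STRIDE = 2_000  # bp between gene starts on a chromosome


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic dataset.

    Defaults describe a small three-patient cohort (600 cells) with fifty
    genes planted in copy-number-4 gain segments, a dosage exponent of 1
    (expression doubles at CN 4) and ~30% overall dropout.
    """

    n_patients: int = 3
    cells_per_patient: int = 200
    n_genes: int = 1000
    n_chromosomes: int = 4
    # segment plan, per patient
    segments_per_patient: int = 2
    segment_length_range: tuple[int, int] = (16_000, 18_000)  # ~8-9 genes each
    cn_distribution: dict[float, float] = field(default_factory=lambda: {4.0: 1.0})
    distinct_regions_per_patient: bool = True
    # expression model
    dosage_exponent: float = 1.0  # beta; 0 => null model
    baseline_log_mean: float = 2.0
    gene_log_mean_sd: float = 1.0
    baseline_log_sd: float = 0.4  # cell-to-cell noise on the log scale
    # dropout logistic: P(drop) = expit(intercept - slope * ln(expression))
    dropout_intercept: float = 1.7
    dropout_slope: float = 1.5
    # interaction network
    background_edge_p: float = 0.02
    module_size: int = 12
    module_density: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "cells_per_patient", "n_genes", "n_chromosomes",
                     "segments_per_patient"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.dosage_exponent < 0:
            raise ValidationError("dosage_exponent must be >= 0")
        lo, hi = self.segment_length_range
        if not 0 < lo <= hi:
            raise ValidationError("bad segment_length_range")
        probs = np.array(list(self.cn_distribution.values()), dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValidationError("cn_distribution must be a non-negative weight map")
        if any(cn < 0 for cn in self.cn_distribution):
            raise ValidationError("copy numbers must be non-negative")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    metadata: CellMetadata
    annotation: GeneAnnotation
    segments: CNVSegmentSet
    network: nx.Graph
    truth: pd.DataFrame       # columns: patient_id, gene_id, copy_number
    module_genes: frozenset   # planted dense-module members

    @property
    def truth_genes(self) -> frozenset:
        return frozenset(self.truth["gene_id"])

    def gain_truth_genes(self) -> frozenset:
        return frozenset(self.truth.loc[self.truth["copy_number"] > 2, "gene_id"])


class RecoveryMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float
    n_retained: int
    n_truth: int


def _gene_layout(config: SimulationConfig):
    """Non-overlapping ordered gene intervals, round-robin-free: genes fill
    chromosomes in blocks."""
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    gene_ids, chroms, starts = [], [], []
    for i in range(config.n_genes):
        c, j = divmod(i, per_chrom)
        gene_ids.append(f"G{i:04d}")
        chroms.append(f"chr{c + 1}")
        starts.append(j * GENE_STRIDE)
    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": [s + GENE_LENGTH for s in starts],
            "strand": ".",
        }
    )
    chrom_len = per_chrom * GENE_STRIDE
    return GeneAnnotation(ann), per_chrom, chrom_len


def _plan_segments(config: SimulationConfig, rng: np.random.Generator,
                   per_chrom: int, chrom_len: int):
    """Place gain/loss segments on the gene grid.

    Returns (segment table rows, cn_matrix patients x genes) where the cn
    matrix is 2.0 outside any segment.
    """
    cns = np.array(list(config.cn_distribution), dtype=float)
    weights = np.array(list(config.cn_distribution.values()), dtype=float)
    weights = weights / weights.sum()

    occupied_global: dict[str, set[int]] = {}
    cn_matrix = np.full((config.n_patients, config.n_genes), 2.0)
    rows = []
    for p in range(config.n_patients):
        occupied_local: dict[str, set[int]] = {}
        for _s in range(config.segments_per_patient):
            length = int(rng.integers(config.segment_length_range[0],
                                      config.segment_length_range[1] + 1))
            if length > chrom_len:
                raise ValidationError("segment plan infeasible: segment exceeds chromosome")
            # segment [j0*stride, j0*stride + L) touches gene j iff
            # (j - j0)*stride < L, i.e. exactly ceil(L / stride) genes
            n_cov = max(1, int(np.ceil(length / GENE_STRIDE)))
            placed = False
            for _attempt in range(2000):
                chrom_i = int(rng.integers(config.n_chromosomes))
                chrom = f"chr{chrom_i + 1}"
                max_start = per_chrom - n_cov
                if max_start < 0:
                    continue
                j0 = int(rng.integers(max_start + 1))
                span = set(range(j0 - 1, j0 + n_cov + 1))  # 1-gene buffer
                taken = occupied_local.setdefault(chrom, set())
                if span & taken:
                    continue
                if config.distinct_regions_per_patient and span & occupied_global.setdefault(chrom, set()):
                    continue
                cn = float(rng.choice(cns, p=weights))
                start = j0 * GENE_STRIDE
                end = min(start + length, chrom_len)
                gene_lo = chrom_i * per_chrom + j0
                covered = [g for g in range(gene_lo, min(gene_lo + n_cov, config.n_genes))]
                if not covered:
                    continue
                taken |= span
                occupied_global.setdefault(chrom, set()).update(span)
                rows.append((f"P{p + 1}", chrom, start, end, cn))
                cn_matrix[p, covered] = cn
                placed = True
                break
            if not placed:
                raise ValidationError(
                    "segment plan infeasible: could not place all segments disjointly"
                )
    return rows, cn_matrix


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate one fully reproducible matched dataset.

    ``seed`` overrides ``config.rng_seed``; identical (config, seed) pairs
    produce identical datasets. Per-patient randomness comes from spawned
    sub-streams so patient k's cells do not depend on how many cells earlier
    patients drew.
    """
    config = config or SimulationConfig()
    seed = config.rng_seed if seed is None else int(seed)
    root_ss = np.random.SeedSequence(seed)
    plan_ss, gene_ss, net_ss, *patient_ss = root_ss.spawn(3 + config.n_patients)
    rng = np.random.Generator(np.random.PCG64(plan_ss))

    annotation, per_chrom, chrom_len = _gene_layout(config)
    seg_rows, cn_matrix = _plan_segments(config, rng, per_chrom, chrom_len)
    segments = CNVSegmentSet(
        pd.DataFrame(seg_rows, columns=["patient_id", "chrom", "start", "end", "copy_number"])
    )

    gene_rng = np.random.Generator(np.random.PCG64(gene_ss))
    mu = gene_rng.normal(config.baseline_log_mean, config.gene_log_mean_sd, config.n_genes)

    beta = config.dosage_exponent
    cols, cell_ids, patient_of = [], [], {}
    for p in range(config.n_patients):
        prng = np.random.Generator(np.random.PCG64(patient_ss[p]))
        cn = cn_matrix[p]
        with np.errstate(divide="ignore"):
            shift = beta * np.log(cn / 2.0)  # -inf at CN 0 (homozygous loss)
        n = config.cells_per_patient
        logx = mu[:, None] + shift[:, None] + prng.normal(0.0, config.baseline_log_sd,
                                                          (config.n_genes, n))
        x = np.exp(logx)
        x[np.isneginf(logx)] = 0.0
        with np.errstate(divide="ignore"):
            p_drop = expit(config.dropout_intercept - config.dropout_slope * np.log(x, where=x > 0,
                                                                                    out=np.full_like(x, -np.inf)))
        p_drop[x == 0] = 1.0
        drop = prng.random(x.shape) < p_drop
        x[drop] = 0.0
        cols.append(x)
        for c in range(n):
            cid = f"P{p + 1}_C{c:03d}"
            cell_ids.append(cid)
            patient_of[cid] = f"P{p + 1}"

    raw = np.concatenate(cols, axis=1)
    colsum = raw.sum(axis=0)
    if (colsum == 0).any():
        raise ValidationError("simulated an all-zero cell; lower the dropout intercept")
    tpm = raw / colsum[None, :] * 1e6
    expression = ExpressionMatrix(list(annotation.table["gene_id"]), cell_ids, tpm)
    metadata = CellMetadata(patient_of)

    # truth: every (patient, gene) with non-diploid planted copy number
    pi, gi = np.nonzero(cn_matrix != 2.0)
    truth = pd.DataFrame(
        {
            "patient_id": [f"P{p + 1}" for p in pi],
            "gene_id": [expression.gene_ids[g] for g in gi],
            "copy_number": cn_matrix[pi, gi],
        }
    )

    network, module_genes = _simulate_network(config, net_ss, expression.gene_ids,
                                              sorted(set(truth.loc[truth["copy_number"] > 2,
                                                                   "gene_id"])))
    return SyntheticDataset(expression, metadata, annotation, segments, network,
                            truth, frozenset(module_genes))


def _simulate_network(config: SimulationConfig, ss, gene_ids, gain_genes):
    """Sparse background interactome plus one dense module planted among the
    gain genes (falling back to the gene universe if too few gains)."""
    rng = np.random.Generator(np.random.PCG64(ss))
    graph = nx.fast_gnp_random_graph(
        len(gene_ids), config.background_edge_p,
        seed=int(rng.integers(2**31)),
    )
    graph = nx.relabel_nodes(graph, dict(enumerate(gene_ids)))
    pool = gain_genes if len(gain_genes) >= config.module_size else list(gene_ids)
    members = list(rng.choice(np.array(pool, dtype=object), size=min(config.module_size, len(pool)),
                              replace=False))
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if rng.random() < config.module_density:
                graph.add_edge(a, b)
    return graph, members


def null_config(**overrides) -> SimulationConfig:
    """The default scenario with the dosage effect switched off (beta = 0)."""
    return SimulationConfig(dosage_exponent=0.0, **overrides)


def evaluate_recovery(recurrence, truth) -> RecoveryMetrics:
    """Precision/recall/F1 of the retained gene list against planted truth.

    ``recurrence`` may be the recurrence DataFrame or any iterable of gene
    ids; ``truth`` a SyntheticDataset truth frame, a dataset, or a gene set.
    """
    if isinstance(recurrence, pd.DataFrame):
        retained = set(recurrence["gene_id"])
    else:
        retained = set(recurrence)
    if isinstance(truth, SyntheticDataset):
        truth_genes = set(truth.gain_truth_genes())
    elif isinstance(truth, pd.DataFrame):
        truth_genes = set(truth["gene_id"])
    else:
        truth_genes = set(truth)
    if not truth_genes:
        raise ValidationError("truth gene set is empty")
    tp = len(retained & truth_genes)
    precision = tp / len(retained) if retained else 0.0
    recall = tp / len(truth_genes)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return RecoveryMetrics(precision, recall, f1, len(retained), len(truth_genes))


def write_dataset(dataset: SyntheticDataset, outdir: str) -> None:
    """Write the complete dataset in the pipeline's on-disk formats plus
    truth.tsv and module_genes.txt."""
    import os

    _io.ensure_dir(outdir)
    _io.write_expression_matrix(dataset.expression, os.path.join(outdir, "expression.tsv"))
    _io.write_cell_metadata(dataset.metadata, os.path.join(outdir, "cells.tsv"))
    _io.write_gene_annotation(dataset.annotation, os.path.join(outdir, "genes.bed"))
    _io.write_cnv_segments(dataset.segments, os.path.join(outdir, "cnv_segments.tsv"))
    _io.write_network(dataset.network, os.path.join(outdir, "network.tsv"))
    dataset.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "module_genes.txt"), "w") as fh:
        for g in sorted(dataset.module_genes):
            fh.write(g + "\n")
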