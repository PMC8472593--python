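"""End-to-end orchestration: zscore -> cnv map -> events -> recurrence ->
modules/enrichment -> states/diversity, with a JSON run report carrying
every census the stages produce."""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import cellstate, cnvmap, concordance, dosage, io as _io, netmod
from .errors import StageError, ValidationError

log = logging.getLogger("scdosage")


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run.

    Defaults mirror the analysis the pipeline was designed around: Z
    threshold 1.96 (two-sided 5%), moments over all cells including zeros,
    copy-number gain at CN >= 3, CNG-UP concordance, and a 100-cell
    recurrence cutoff (drop to ~5% of the cell count for small cohorts).
    """

    # inputs
    expression: str = ""
    expression_format: str = "dense_tsv"
    metadata: str = ""
    annotation: str = ""
    segments: str = ""
    coordinate_origin: str = "zero_half_open"
    network: str | None = None
    gene_sets: str | None = None
    embedding: str | None = None
    out_dir: str = "scdosage_out"
    # dosage
    z_threshold: float = dosage.DEFAULT_Z_THRESHOLD
    ddof: int = 1
    include_zeros_in_moments: bool = True
    pooling: str = "all"
    write_zscores: bool = False
    # cnv state rule
    gain_min_cn: float = 3.0
    loss_max_cn: float = 1.0
    cnv_mode: str = "absolute_cn"
    min_overlap_bp: int = 1
    # concordance
    min_cells: int = 100
    concordance_mode: str = "CNG_UP"
    # modules / enrichment
    mcode: netmod.MCODEParams = field(default_factory=netmod.MCODEParams)
    enrichment_background: str = "expression"  # or "annotation"
    # cell state
    score_method: str = "mean_z"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcode = netmod.MCODEParams(**raw.pop("mcode", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(mcode=mcode, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the JSON-serializable report.

    Stage outputs (TSV) and ``report.json`` land in ``config.out_dir``;
    any stage error aborts the run with the stage name attached.
    """
    out = _io.ensure_dir(config.out_dir)
    report: dict = {"params": config.to_dict(), "stages": []}

    expr, meta, ann, segs, network, sets, embedding = _load_inputs(config)
    z = _stage_zscore(config, expr, meta, out, report)
    assignment = _stage_cnvmap(config, ann, segs, out, report)
    events = _stage_events(config, z, assignment, meta, out, report)
    recurrence = _stage_recurrence(config, events, out, report)
    modules = _stage_modules(config, recurrence, network, out, report)
    _stage_enrichment(config, recurrence, sets, expr, ann, out, report)
    _stage_states(config, expr, meta, z, modules, embedding, out, report)

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    for name in ("expression", "metadata", "annotation", "segments"):
        if not getattr(config, name):
            raise ValidationError(f"config is missing the {name!r} input path")
    expr = _io.read_expression_matrix(config.expression, config.expression_format)
    meta = _io.read_cell_metadata(config.metadata)
    meta.validate_against(expr)
    ann = _io.read_gene_annotation(config.annotation)
    segs = _io.read_cnv_segments(config.segments, config.coordinate_origin)
    network = _io.read_network(config.network) if config.network else None
    sets = _io.read_gene_sets(config.gene_sets) if config.gene_sets else None
    embedding = None
    if config.embedding:
        embedding = pd.read_csv(config.embedding, sep="\t", index_col=0)
    return expr, meta, ann, segs, network, sets, embedding


@_stage("zscore")
def _stage_zscore(config, expr, meta, out, report):
    z = dosage.compute_zscores(
        expr, ddof=config.ddof,
        include_zeros_in_moments=config.include_zeros_in_moments,
        pooling=config.pooling, meta=meta,
    )
    census = dosage.entry_census(z)
    log.info("entry census: total=%d masked=%d retained=%d", *census)
    report["entry_census"] = census._asdict()
    report["z_tail_probability"] = dosage.two_sided_tail_probability(config.z_threshold)
    report["stages"].append("zscore")
    if config.write_zscores:
        pd.DataFrame(z.z, index=z.gene_ids, columns=z.cell_ids).to_csv(
            os.path.join(out, "zscores.tsv"), sep="\t", index_label="gene_id"
        )
    return z


@_stage("cnvmap")
def _stage_cnvmap(config, ann, segs, out, report):
    rule = cnvmap.CNVStateRule(config.gain_min_cn, config.loss_max_cn, config.cnv_mode)
    assignment = cnvmap.classify_cnv_state(
        cnvmap.overlap_genes(ann, segs, config.min_overlap_bp), rule
    )
    assignment.to_csv(os.path.join(out, "gene_cnv.tsv"), sep="\t", index=False)
    report["n_assignments"] = int((assignment["state"] != "UNKNOWN").sum())
    report["stages"].append("cnvmap")
    return assignment


@_stage("events")
def _stage_events(config, z, assignment, meta, out, report):
    events = concordance.call_events(z, assignment, meta, config.z_threshold)
    census = concordance.event_census(events)
    log.info("event census: total=%d informative=%d in %d cells", census.total,
             census.informative, census.n_cells)
    report["event_census"] = census._asdict()
    _io.write_event_table(events, os.path.join(out, "events.tsv"))
    report["stages"].append("events")
    return events


@_stage("recurrence")
def _stage_recurrence(config, events, out, report):
    kept = concordance.filter_concordant(events, config.concordance_mode)
    report["concordant_events"] = len(kept)
    recurrence = concordance.recurrence_table(kept, config.min_cells)
    _io.write_recurrence_table(recurrence, os.path.join(out, "recurrence.tsv"))
    report["retained_genes"] = list(recurrence["gene_id"])
    report["n_retained_genes"] = len(recurrence)
    report["stages"].append("recurrence")
    return recurrence


@_stage("modules")
def _stage_modules(config, recurrence, network, out, report):
    if network is None:
        report["modules"] = None
        return []
    modules = netmod.mcode_find_modules(network, config.mcode, query=set(recurrence["gene_id"]))
    frame = netmod.modules_to_frame(modules)
    frame.to_csv(os.path.join(out, "modules.tsv"), sep="\t", index=False)
    report["modules"] = frame.drop(columns=["members"]).to_dict(orient="records")
    report["stages"].append("modules")
    return modules


@_stage("enrichment")
def _stage_enrichment(config, recurrence, sets, expr, ann, out, report):
    if sets is None:
        report["enrichment"] = None
        return None
    if config.enrichment_background == "annotation":
        background = set(ann.table["gene_id"])
    else:
        background = set(expr.gene_ids)
    query = set(recurrence["gene_id"]) & background
    result = netmod.hypergeometric_enrichment(query, sets, background)
    result.to_csv(os.path.join(out, "enrichment.tsv"), sep="\t", index=False)
    report["enrichment"] = result.head(10).to_dict(orient="records")
    report["stages"].append("enrichment")
    return result


@_stage("states")
def _stage_states(config, expr, meta, z, modules, embedding, out, report):
    diversity = cellstate.diversity_table(expr, meta)
    diversity.to_csv(os.path.join(out, "diversity.tsv"), sep="\t", index=False)
    summary = cellstate.diversity_patient_summary(diversity)
    report["diversity"] = summary.to_dict(orient="records")

    extra = {}
    if modules:
        extra["top_module"] = sorted(modules[0].members)
    signatures = cellstate.make_signatures(extra)
    scores = cellstate.score_states(z, signatures, method=config.score_method)
    scores.to_csv(os.path.join(out, "states.tsv"), sep="\t", index_label="cell_id")
    if len(scores.columns):
        corr = cellstate.state_correlations(scores)
        corr.to_csv(os.path.join(out, "state_correlations.tsv"), sep="\t")
    if embedding is not None and len(scores.columns):
        fit = cellstate.fit_state_vectors(embedding, scores)
        fit.to_csv(os.path.join(out, "state_fit.tsv"), sep="\t", index=False)
        report["state_fit"] = fit.to_dict(orient="records")
    report["stages"].append("states")
    return scores
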