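import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import scdosage as sd

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")
from scdosage.types import CellMetadata, CNVSegmentSet, ExpressionMatrix, GeneAnnotation


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic cohort, shared read-only across tests."""
    return sd.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def dataset_run(dataset):
    """The default cohort pushed through zscore -> map -> events."""
    z = sd.compute_zscores(dataset.expression)
    assignment = sd.classify_cnv_state(
        sd.overlap_genes(dataset.annotation, dataset.segments)
    )
    events = sd.call_events(z, assignment, dataset.metadata)
    return {"z": z, "assignment": assignment, "events": events}


@pytest.fixture
def tiny_expr():
    """3 genes x 4 cells with zeros, two patients."""
    values = np.array(
        [
            [0.0, 0.0, 3.0, 9.0],
            [2.0, 4.0, 6.0, 8.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )
    expr = ExpressionMatrix(["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"], values)
    meta = CellMetadata({"c1": "P1", "c2": "P1", "c3": "P2", "c4": "P2"})
    return expr, meta


def make_annotation(rows):
    """rows: (gene_id, chrom, start, end)"""
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).assign(strand=".")
    )


def make_segments(rows):
    """rows: (patient_id, chrom, start, end, copy_number)"""
    return CNVSegmentSet(
        pd.DataFrame(rows, columns=["patient_id", "chrom", "start", "end", "copy_number"])
    )
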