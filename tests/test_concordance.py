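import numpy as np
import pandas as pd
import pytest

import scdosage as sd
from scdosage.errors import ValidationError
from scdosage.types import DOWN, GAIN, LOSS, NONE, UP, CellMetadata, ExpressionMatrix

from conftest import make_annotation, make_segments


def triple_loop_events(z, assignment, meta, threshold=1.96):
    """Exhaustive per-(gene, cell) enumeration oracle."""
    state_of = {
        (r.patient_id, r.gene_id): r.state
        for r in assignment.itertuples(index=False)
        if r.state in (GAIN, LOSS)
    }
    rows = []
    for i, gene in enumerate(z.gene_ids):
        for j, cell in enumerate(z.cell_ids):
            pat = meta.patient_of(cell)
            state = state_of.get((pat, gene))
            if state is None or z.masked[i, j]:
                continue
            zv = z.z[i, j]
            if zv > threshold:
                direction = UP
            elif zv < -threshold:
                direction = DOWN
            else:
                direction = NONE
            rows.append((gene, cell, pat, zv, state, direction, abs(zv) > threshold))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cell_id", "patient_id", "z", "cnv_state", "direction", "informative"],
    )


@pytest.fixture
def planted():
    """5 genes x 8 cells, 2 patients, planted gains/losses."""
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.5, 20, size=(5, 8))
    vals[0, 0] = 0.0
    vals[3, :] = np.array([1, 1, 1, 1, 1, 1, 1, 60.0])  # strong outlier cell
    expr = ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"c{j}" for j in range(8)], vals
    )
    meta = CellMetadata({f"c{j}": ("P1" if j < 4 else "P2") for j in range(8)})
    ann = make_annotation([(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(5)])
    segs = make_segments(
        [
            ("P1", "chr1", 0, 1600, 4.0),     # g0, g1 gained in P1
            ("P1", "chr1", 3000, 3600, 1.0),  # g3 lost in P1
            ("P2", "chr1", 1000, 4600, 4.0),  # g1..g4 gained in P2
        ]
    )
    z = sd.compute_zscores(expr)
    assignment = sd.classify_cnv_state(sd.overlap_genes(ann, segs))
    return z, assignment, meta


class TestCallEvents:
    def test_matches_triple_loop_oracle(self, planted):
        z, assignment, meta = planted
        got = sd.call_events(z, assignment, meta)
        want = triple_loop_events(z, assignment, meta).sort_values(
            ["gene_id", "cell_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got.astype({"informative": bool}), want.astype({"informative": bool})
        )

    def test_oracle_equivalence_on_simulated_cohort(self, dataset, dataset_run):
        # restrict to a slice to keep the cubic oracle under a thousand entries
        z, assignment = dataset_run["z"], dataset_run["assignment"]
        sub = sd.ZScoreMatrix(z.gene_ids[:40], z.cell_ids[:20],
                              z.z[:40, :20], z.masked[:40, :20])
        got = sd.call_events(sub, assignment, dataset.metadata)
        want = triple_loop_events(sub, assignment, dataset.metadata)
        assert len(got) == len(want)
        key = lambda df: set(zip(df["gene_id"], df["cell_id"], df["cnv_state"],
                                 df["direction"], df["informative"]))
        assert key(got) == key(want)

    def test_gain_with_high_z_yields_informative_up(self):
        z = sd.ZScoreMatrix(["g"], ["c1", "c2"], np.array([[2.5, 0.0]]),
                            np.array([[False, False]]))
        assignment = pd.DataFrame(
            {"patient_id": ["P1"], "gene_id": ["g"], "chrom": ["chr1"],
             "copy_number": [4.0], "state": [GAIN], "overlap_bp": [100]}
        )
        meta = CellMetadata({"c1": "P1", "c2": "P1"})
        ev = sd.call_events(z, assignment, meta)
        row = ev[ev["cell_id"] == "c1"].iloc[0]
        assert (row["cnv_state"], row["direction"], bool(row["informative"])) == (GAIN, UP, True)

    def test_neutral_everywhere_yields_no_events(self):
        z = sd.ZScoreMatrix(["g"], ["c1", "c2"], np.array([[5.0, -5.0]]),
                            np.zeros((1, 2), bool))
        assignment = pd.DataFrame(
            {"patient_id": ["P1"], "gene_id": ["g"], "chrom": ["chr1"],
             "copy_number": [2.0], "state": ["NEUTRAL"], "overlap_bp": [100]}
        )
        ev = sd.call_events(z, assignment, CellMetadata({"c1": "P1", "c2": "P1"}))
        assert len(ev) == 0

    def test_conservation_informative_plus_non(self, dataset_run):
        census = sd.event_census(dataset_run["events"])
        assert census.informative + census.non_informative == census.total

    def test_monotone_in_z_threshold(self, planted):
        z, assignment, meta = planted
        counts = [
            sd.event_census(sd.call_events(z, assignment, meta, t)).informative
            for t in (0.5, 1.0, 1.96)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestFilterConcordant:
    def test_mixed_list_keeps_only_informative_gain_up(self):
        events = pd.DataFrame(
            {
                "gene_id": list("abcd"),
                "cell_id": list("wxyz"),
                "patient_id": ["P1"] * 4,
                "z": [2.5, -2.5, -2.5, 1.0],
                "cnv_state": [GAIN, GAIN, LOSS, GAIN],
                "direction": [UP, DOWN, DOWN, NONE],
                "informative": [True, True, True, False],
            }
        )
        assert len(sd.filter_concordant(events, "CNG_UP")) == 1
        assert len(sd.filter_concordant(events, "CNL_DOWN")) == 1
        assert len(sd.filter_concordant(events, "BOTH")) == 2

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["gene_id", "cnv_state", "direction", "informative"])
        assert len(sd.filter_concordant(empty)) == 0

    def test_matches_predicate_oracle(self, dataset_run):
        events = dataset_run["events"]
        kept = sd.filter_concordant(events, "CNG_UP")
        want = events[
            (events["cnv_state"] == GAIN) & (events["direction"] == UP) & events["informative"]
        ]
        assert set(zip(kept["gene_id"], kept["cell_id"])) == set(
            zip(want["gene_id"], want["cell_id"])
        )


class TestRecurrence:
    @staticmethod
    def events_for(gene_cells: dict):
        rows = [
            (g, f"c{i}", "P1", 2.5, GAIN, UP, True)
            for g, n in gene_cells.items()
            for i in range(n)
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "cell_id", "patient_id", "z", "cnv_state",
                           "direction", "informative"],
        )

    def test_hard_cell_cutoff(self):
        table = sd.recurrence_table(self.events_for({"a": 100, "b": 99}), min_cells=100)
        assert list(table["gene_id"]) == ["a"]

    def test_min_cells_one_keeps_everything(self):
        table = sd.recurrence_table(self.events_for({"a": 3, "b": 1}), min_cells=1)
        assert set(table["gene_id"]) == {"a", "b"}

    def test_counts_distinct_cells_and_sorting(self, dataset_run):
        kept = sd.filter_concordant(dataset_run["events"])
        table = sd.recurrence_table(kept, min_cells=5)
        oracle = kept.groupby("gene_id")["cell_id"].nunique()
        for row in table.itertuples(index=False):
            assert row.n_cells == oracle[row.gene_id]
            assert row.n_cells <= row.n_events
        assert (np.diff(table["n_cells"]) <= 0).all()

    def test_monotone_in_min_cells(self, dataset_run):
        kept = sd.filter_concordant(dataset_run["events"])
        sizes = [len(sd.recurrence_table(kept, m)) for m in (1, 20, 100)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_min_cells_validation(self):
        with pytest.raises(ValidationError):
            sd.recurrence_table(self.events_for({"a": 2}), min_cells=0)

    def test_determinism_byte_identical(self, dataset_run, tmp_path):
        from scdosage import io as sio

        kept = sd.filter_concordant(dataset_run["events"])
        paths = []
        for i in (1, 2):
            p = tmp_path / f"r{i}.tsv"
            sio.write_recurrence_table(sd.recurrence_table(kept, 10), str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestCrossValidate:
    def test_identical_and_disjoint(self):
        a = pd.DataFrame({"gene_id": ["x", "y"]})
        cv = sd.cross_validate(a, a)
        assert cv.intersection == cv.genes_a
        cv2 = sd.cross_validate(a, pd.DataFrame({"gene_id": ["z"]}))
        assert cv2.intersection == frozenset()

    def test_twenty_twenty_share_seven(self):
        a = {f"a{i}" for i in range(13)} | {f"s{i}" for i in range(7)}
        b = {f"b{i}" for i in range(13)} | {f"s{i}" for i in range(7)}
        cv = sd.cross_validate(a, b)
        assert (len(cv.union), len(cv.intersection)) == (33, 7)
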