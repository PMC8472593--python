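import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scdosage as sd
from scdosage.cellstate import (
    DEFAULT_SIGNATURES,
    diversity_patient_summary,
    diversity_table,
    fit_state_vectors,
    make_signatures,
    score_states,
    shannon_index,
    simpson_index,
    state_correlations,
)
from scdosage.errors import ValidationError


class TestDiversityIndices:
    def test_uniform_cell_reaches_maxima(self):
        col = np.full(10, 3.3)
        assert shannon_index(col) == pytest.approx(np.log(10))
        assert simpson_index(col) == pytest.approx(1 - 1 / 10)

    def test_single_expressed_gene_is_degenerate(self):
        col = np.array([0.0, 7.0, 0.0])
        assert shannon_index(col) == pytest.approx(0.0)
        assert simpson_index(col) == pytest.approx(0.0)

    def test_hand_computed_three_gene_cell(self):
        col = np.array([0.5, 0.3, 0.2])
        h = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert shannon_index(col) == pytest.approx(h)
        assert h == pytest.approx(1.02965, abs=1e-5)
        assert simpson_index(col) == pytest.approx(0.62)

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValidationError):
            shannon_index(np.zeros(4))
        with pytest.raises(ValidationError):
            simpson_index(np.zeros(4))

    @pytest.mark.parametrize("scale", [0.001, 1.0, 1e6])
    def test_invariant_to_positive_rescaling(self, scale):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 50, 30)
        assert shannon_index(col * scale) == pytest.approx(shannon_index(col))
        assert simpson_index(col * scale) == pytest.approx(simpson_index(col))

    def test_h_zero_iff_d_zero_iff_single_gene(self, dataset):
        table = diversity_table(dataset.expression, dataset.metadata)
        h0 = table["shannon"] == 0
        d0 = table["simpson"] == 0
        s1 = (dataset.expression.values > 0).sum(axis=0) == 1
        assert (h0 == d0).all() and (h0.to_numpy() == s1).all()
        # bounds: H <= ln S, D <= 1 - 1/S
        S = (dataset.expression.values > 0).sum(axis=0)
        assert (table["shannon"] <= np.log(S) + 1e-9).all()
        assert (table["simpson"] <= 1 - 1 / S + 1e-12).all()

    def test_shannon_simpson_rank_correlated_on_cohort(self, dataset):
        table = diversity_table(dataset.expression, dataset.metadata)
        rho = stats.spearmanr(table["shannon"], table["simpson"]).statistic
        assert rho > 0.8

    def test_patient_summary_shape(self, dataset):
        table = diversity_table(dataset.expression, dataset.metadata)
        summary = diversity_patient_summary(table)
        assert set(summary["patient_id"]) == set(dataset.metadata.patients)
        assert {"shannon_mean", "simpson_median"} <= set(summary.columns)


def zmat(z, masked=None, genes=None):
    z = np.asarray(z, dtype=float)
    masked = np.zeros_like(z, bool) if masked is None else np.asarray(masked, bool)
    zz = z.copy()
    zz[masked] = np.nan
    return sd.ZScoreMatrix(
        genes or [f"G{i}" for i in range(z.shape[0])],
        [f"c{j}" for j in range(z.shape[1])],
        zz,
        masked,
    )


class TestScoreStates:
    def test_single_gene_signature_equals_that_z(self):
        z = zmat([[1.5, -0.5]], genes=["VIM"])
        scores = score_states(z, {"emt": ("VIM",)})
        np.testing.assert_allclose(scores["emt"], [1.5, -0.5])

    def test_all_masked_gives_na(self):
        z = zmat([[1.0, 2.0]], masked=[[True, False]], genes=["VIM"])
        scores = score_states(z, {"emt": ("VIM",)})
        assert np.isnan(scores["emt"].iloc[0]) and scores["emt"].iloc[1] == 2.0

    def test_three_gene_mean(self):
        z = zmat([[1.0], [2.0], [3.0]], genes=["A", "B", "C"])
        scores = score_states(z, {"s": ("A", "B", "C")})
        assert scores["s"].iloc[0] == pytest.approx(2.0)

    def test_absent_signature_skipped_with_warning(self):
        z = zmat([[1.0, 2.0]], genes=["A"])
        with pytest.warns(UserWarning):
            scores = score_states(z, {"ghost": ("NOPE",), "ok": ("A",)})
        assert list(scores.columns) == ["ok"]

    def test_default_panels_ship_published_markers(self):
        sigs = make_signatures()
        assert sigs["EMT_metastasis"] == ("SNAI1", "SNAI2", "FOSL1", "VIM", "CDH2", "ID1")
        assert sigs["pluripotency"] == ("POU5F1", "NANOG", "SOX2")
        extra = make_signatures({"srp_module": ["rpl3", "RPS6"]})
        assert extra["srp_module"] == ("RPL3", "RPS6")

    def test_rank_method_bounded(self):
        rng = np.random.default_rng(2)
        z = zmat(rng.normal(size=(20, 15)), genes=[f"G{i}" for i in range(20)])
        scores = score_states(z, {"s": tuple(f"G{i}" for i in range(5))}, method="rank")
        assert ((scores["s"] > 0) & (scores["s"] <= 1)).all()


class TestFitStateVectors:
    def embedding(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 2)), columns=["dim1", "dim2"],
            index=[f"c{j}" for j in range(n)],
        )

    def test_score_equal_to_axis_one(self):
        emb = self.embedding(100)
        scores = pd.DataFrame({"s": emb["dim1"]}, index=emb.index)
        fit = fit_state_vectors(emb, scores)
        assert fit.loc[0, "r2"] == pytest.approx(1.0)
        np.testing.assert_allclose([fit.loc[0, "dx"], fit.loc[0, "dy"]], [1, 0], atol=1e-8)

    def test_diagonal_dependence_gives_45_degrees(self):
        n = 200
        emb = pd.DataFrame(
            {"dim1": np.linspace(-1, 1, n), "dim2": np.sin(np.arange(n))},
            index=[f"c{j}" for j in range(n)],
        )
        emb -= emb.mean()
        scores = pd.DataFrame({"s": emb["dim1"] + emb["dim2"]}, index=emb.index)
        fit = fit_state_vectors(emb, scores)
        assert fit.loc[0, "r2"] == pytest.approx(1.0)
        # arrow along the (1,1) direction of the coefficient space
        np.testing.assert_allclose(fit.loc[0, "dx"], fit.loc[0, "dy"], atol=1e-6)

    def test_independent_noise_has_low_r2(self):
        emb = self.embedding(500, seed=1)
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"s": rng.normal(size=500)}, index=emb.index)
        fit = fit_state_vectors(emb, scores)
        assert fit.loc[0, "r2"] < 0.1
        # arrow length is sqrt(R^2)
        assert np.hypot(fit.loc[0, "dx"], fit.loc[0, "dy"]) == pytest.approx(
            np.sqrt(fit.loc[0, "r2"]), abs=1e-9
        )

    def test_r2_matches_normal_equations_oracle(self):
        emb = self.embedding(120, seed=3)
        rng = np.random.default_rng(4)
        y = 0.7 * emb["dim1"].to_numpy() - 0.2 * emb["dim2"].to_numpy() + rng.normal(0, 0.5, 120)
        fit = fit_state_vectors(emb, pd.DataFrame({"s": y}, index=emb.index))
        X = np.column_stack([np.ones(120), emb.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.loc[0, "r2"] == pytest.approx(r2, abs=1e-8)

    def test_degenerate_axis_rejected(self):
        emb = self.embedding(10)
        emb["dim2"] = 1.0
        with pytest.raises(ValidationError):
            fit_state_vectors(emb, pd.DataFrame({"s": np.arange(10.0)}, index=emb.index))


class TestStateCorrelations:
    def test_identical_signatures_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        z = zmat(rng.normal(size=(6, 40)), genes=list("ABCDEF"))
        scores = score_states(z, {"s1": ("A", "B"), "s2": ("A", "B"), "s3": ("E", "F")})
        corr = state_correlations(scores)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert (np.diag(corr) == 1.0).all()

    def test_planted_covariance_sign_recovered(self):
        rng = np.random.default_rng(6)
        latent = rng.normal(size=200)
        z = np.vstack([latent + rng.normal(0, 0.3, 200),
                       latent + rng.normal(0, 0.3, 200),
                       -latent + rng.normal(0, 0.3, 200)])
        scores = score_states(zmat(z, genes=["A", "B", "C"]),
                              {"pos1": ("A",), "pos2": ("B",), "neg": ("C",)})
        corr = state_correlations(scores)
        assert corr.loc["pos1", "pos2"] > 0.5
        assert corr.loc["pos1", "neg"] < -0.5

    def test_per_patient_grouping(self, dataset, dataset_run):
        scores = score_states(
            dataset_run["z"], {"m": tuple(sorted(dataset.module_genes)[:5])}
        )
        scores["other"] = scores["m"] * 0.5  # second state for a 2x2 matrix
        out = state_correlations(scores, grouping="per_patient", meta=dataset.metadata)
        assert set(out) == set(dataset.metadata.patients)
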