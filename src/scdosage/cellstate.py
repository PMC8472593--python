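"""Per-cell transcriptome diversity and cell-state signature scores.

Each cell is treated like an ecological plot whose "species" are its
expressed genes, with proportions p_i = TPM_i / sum(TPM) over the nonzero
genes. Two classic alpha-diversity indices summarize expression
heterogeneity:

* Shannon-Wiener  H = -sum_i p_i ln p_i   (richness + evenness; max ln S)
* Gini-Simpson    D = 1 - sum_i p_i^2     (dominance; max 1 - 1/S)

Cell states (EMT/metastasis, stemness, pluripotency, differentiation,
proliferation, plus any user-supplied module such as an SRP signature) are
scored per cell as the mean masked-aware Z-score over the signature's genes,
with a rank-based alternative. State vectors can be projected onto a 2-D
embedding (t-SNE/UMAP computed elsewhere) by least squares, envfit-style:
the arrow points where the score increases fastest and its length scales
with sqrt(R^2).
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import ZScoreMatrix
from .errors import ValidationError
from .types import CellMetadata, ExpressionMatrix

# marker panels for breast-cancer cell states
DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "EMT_metastasis": ("SNAI1", "SNAI2", "FOSL1", "VIM", "CDH2", "ID1"),
    "stemness": ("CD44", "ITGA6", "DNER", "ALDH1A3", "ABCG2"),
    "pluripotency": ("POU5F1", "NANOG", "SOX2"),
    "differentiation": ("CDH1", "CD24", "EPCAM", "ESR1", "PGR"),
    "proliferation": ("CCNA2", "MKI67", "ERBB2"),
}


def make_signatures(
    extra: Mapping[str, Iterable[str]] | None = None,
    include_defaults: bool = True,
) -> dict[str, tuple[str, ...]]:
    """Signature dictionary with uppercase-normalized gene ids.

    ``extra`` adds user panels, e.g. an SRP-module gene list from the
    concordance stage.
    """
    sigs: dict[str, tuple[str, ...]] = {}
    if include_defaults:
        sigs.update(DEFAULT_SIGNATURES)
    for name, genes in (extra or {}).items():
        genes = tuple(dict.fromkeys(str(g).upper() for g in genes))
        if not genes:
            raise ValidationError(f"signature {name!r} is empty")
        sigs[str(name)] = genes
    return {k: tuple(g.upper() for g in v) for k, v in sigs.items()}


def _proportions(column: np.ndarray) -> np.ndarray:
    column = np.asarray(column, dtype=float)
    nz = column[column > 0]
    if nz.size == 0:
        raise ValidationError("all-zero cell: diversity undefined")
    return nz / nz.sum()


def shannon_index(column: np.ndarray) -> float:
    """H = -sum p_i ln p_i over the cell's expressed genes (natural log)."""
    p = _proportions(column)
    return float(-(p * np.log(p)).sum())


def simpson_index(column: np.ndarray) -> float:
    """Gini-Simpson D = 1 - sum p_i^2 over the cell's expressed genes."""
    p = _proportions(column)
    return float(1.0 - (p * p).sum())


def diversity_table(expr: ExpressionMatrix, meta: CellMetadata | None = None) -> pd.DataFrame:
    """Per-cell Shannon and Simpson indices (plus patient when known)."""
    rows = []
    for j, cell in enumerate(expr.cell_ids):
        col = expr.values[:, j]
        rows.append(
            (
                cell,
                meta.patient_of(cell) if meta is not None else "",
                shannon_index(col),
                simpson_index(col),
            )
        )
    return pd.DataFrame(rows, columns=["cell_id", "patient_id", "shannon", "simpson"])


def diversity_patient_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/median of both indices per patient."""
    g = table.groupby("patient_id")
    out = g[["shannon", "simpson"]].agg(["mean", "median"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def score_states(
    z: ZScoreMatrix,
    signatures: Mapping[str, Iterable[str]],
    method: str = "mean_z",
) -> pd.DataFrame:
    """Cell x state score matrix.

    ``mean_z`` (default): mean of the unmasked Z-scores of the signature
    genes present in the matrix; NaN when every signature gene is masked in
    the cell. ``rank``: same mean over the within-cell average ranks of the
    unmasked Z-scores, scaled to (0, 1] — an ssGSEA-flavoured alternative
    that is robust to heavy-tailed Z.
    """
    if method not in ("mean_z", "rank"):
        raise ValidationError(f"unknown scoring method {method!r}")
    gene_pos = z.gene_index()
    if method == "rank":
        vals = np.full(z.shape, np.nan)
        for j in range(z.shape[1]):
            ok = ~z.masked[:, j]
            if ok.any():
                vals[ok, j] = stats.rankdata(z.z[ok, j]) / ok.sum()
    else:
        vals = z.z
    scores: dict[str, np.ndarray] = {}
    for state, genes in signatures.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            import warnings

            warnings.warn(f"state {state!r}: no signature gene in the matrix; skipped")
            continue
        sub = vals[idx, :]
        ok = ~z.masked[idx, :]
        n_ok = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(n_ok > 0, np.nansum(np.where(ok, sub, 0.0), axis=0) / np.maximum(n_ok, 1), np.nan)
        scores[state] = mean
    return pd.DataFrame(scores, index=list(z.cell_ids))


def fit_state_vectors(embedding: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """envfit-style linear fit of each state score onto a 2-D embedding.

    ``embedding`` is cells x 2 (index = cell ids). For each state, the score
    is regressed on the centered axes; the arrow is the coefficient
    direction normalized to unit length and scaled by sqrt(R^2).
    """
    if embedding.shape[1] != 2:
        raise ValidationError("embedding must have exactly 2 dimensions")
    emb = embedding.loc[scores.index].to_numpy(dtype=float)
    if np.ptp(emb, axis=0).min() == 0:
        raise ValidationError("degenerate (constant) embedding axis")
    rows = []
    for state in scores.columns:
        y = scores[state].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            raise ValidationError(f"state {state!r}: need >= 3 cells with a score")
        X = emb[ok] - emb[ok].mean(axis=0)
        yv = y[ok] - y[ok].mean()
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        yhat = X @ beta
        sst = float((yv**2).sum())
        r2 = float((yhat**2).sum() / sst) if sst > 0 else 0.0
        norm = float(np.hypot(*beta))
        direction = beta / norm if norm > 0 else np.zeros(2)
        arrow = direction * np.sqrt(max(r2, 0.0))
        rows.append((state, arrow[0], arrow[1], r2))
    return pd.DataFrame(rows, columns=["state", "dx", "dy", "r2"])


def state_correlations(
    scores: pd.DataFrame,
    grouping: str = "all",
    meta: CellMetadata | None = None,
    method: str = "pearson",
):
    """Pairwise correlation between state scores over cells.

    ``grouping='all'`` returns one state x state matrix; ``'per_patient'``
    a dict patient -> matrix. Pairs with fewer than 3 complete observations
    come back NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if grouping == "all":
        return scores.corr(method=method, min_periods=3)
    if grouping != "per_patient":
        raise ValidationError(f"unknown grouping {grouping!r}")
    if meta is None:
        raise ValidationError("per_patient correlations require cell metadata")
    out = {}
    patients = pd.Series({c: meta.patient_of(c) for c in scores.index})
    for pat in sorted(patients.unique()):
        out[pat] = scores.loc[patients[patients == pat].index].corr(
            method=method, min_periods=3
        )
    return out
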