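"""Relative-expression Z-scores with dropout masking.

For each gene, expression across cells is standardized: z = (x - mu) / sigma,
where mu and sigma are the mean and standard deviation of that gene's TPM
over the pooled cell set. Zeros in scRNA-seq are dominated by dropout
(capture failure), not true silence, so entries whose source TPM is zero are
masked and excluded from all downstream calls; genes with sigma = 0 carry no
relative signal and are masked entirely.

Calls are strict: a cell is up-regulated for a gene iff z > threshold and
down-regulated iff z < -threshold (default 1.96, the two-sided 5% point of
the standard normal). Values exactly at the threshold are not called.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .types import DOWN, NONE, UP, CellMetadata, ExpressionMatrix

DEFAULT_Z_THRESHOLD = 1.96


@dataclass
class ZScoreMatrix:
    """Gene x cell Z-scores plus a dropout/degenerate mask.

    ``masked[i, j]`` is True exactly where the source TPM was zero or the
    gene's sigma was zero (ddof-adjusted); ``z`` is finite wherever the mask
    is False and NaN where it is True.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    z: np.ndarray
    masked: np.ndarray
    ddof: int = 1
    include_zeros_in_moments: bool = True

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        self.masked = np.asarray(self.masked, dtype=bool)
        shape = (len(self.gene_ids), len(self.cell_ids))
        if self.z.shape != shape or self.masked.shape != shape:
            raise ValidationError("z / masked shape inconsistent with id lists")
        if not np.isfinite(self.z[~self.masked]).all():
            raise ValidationError("non-finite z outside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.cell_ids)}


class EntryCensus(NamedTuple):
    total: int
    masked: int
    retained: int


def _moments(values: np.ndarray, weights: np.ndarray, ddof: int):
    """Per-row mean/sd of `values` over entries where `weights` is 1.

    The mean is corrected with a second pass over the residuals so that a
    constant row yields sigma exactly 0 (naive one-pass summation can leave
    ~1e-17 residuals that would turn a constant gene into spurious z-noise).
    """
    n = weights.sum(axis=1)
    safe_n = np.maximum(n, 1)
    mu = (values * weights).sum(axis=1) / safe_n
    mu = mu + ((values - mu[:, None]) * weights).sum(axis=1) / safe_n
    ss = (((values - mu[:, None]) * weights) ** 2).sum(axis=1)
    denom = np.maximum(n - ddof, 1)
    sigma = np.sqrt(ss / denom)
    sigma[n - ddof < 1] = 0.0  # too few observations: degenerate
    return mu, sigma, n


def compute_zscores(
    expr: ExpressionMatrix,
    ddof: int = 1,
    include_zeros_in_moments: bool = True,
    pooling: str = "all",
    meta: CellMetadata | None = None,
) -> ZScoreMatrix:
    """Standardize each gene across cells and mask dropouts.

    Parameters
    ----------
    ddof
        Delta degrees of freedom for sigma (1 = sample standard deviation).
    include_zeros_in_moments
        If True (default), mu and sigma are computed over every cell,
        including zero-expression ones, and only the resulting Z-scores at
        zeros are discarded. If False, zeros are excluded from the moments
        as well.
    pooling
        "all" standardizes over the whole dataset (default); "per_patient"
        standardizes within each patient's cells (requires ``meta``).
    """
    if ddof not in (0, 1):
        raise ValidationError(f"ddof must be 0 or 1, got {ddof}")
    if expr.n_cells < 2:
        raise ValidationError("Z-scores need at least 2 cells")
    if pooling not in ("all", "per_patient"):
        raise ValidationError(f"unknown pooling mode {pooling!r}")

    x = expr.values
    zero = x == 0
    z = np.full(x.shape, np.nan)

    if pooling == "all":
        groups = [np.arange(expr.n_cells)]
    else:
        if meta is None:
            raise ValidationError("per_patient pooling requires cell metadata")
        meta.validate_against(expr)
        patients = np.array([meta.patient_of(c) for c in expr.cell_ids])
        groups = [np.flatnonzero(patients == p) for p in np.unique(patients)]

    masked = np.zeros(x.shape, dtype=bool)
    for cols in groups:
        xs = x[:, cols]
        weights = np.ones(xs.shape) if include_zeros_in_moments else (xs != 0).astype(float)
        mu, sigma, _n = _moments(xs, weights, ddof)
        # a spread below float precision of the data scale is measurement-
        # constant: standardizing it would amplify rounding noise into z
        scale = (np.abs(xs) * weights).max(axis=1, initial=0.0)
        degenerate = sigma <= scale * 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            zg = (xs - mu[:, None]) / sigma[:, None]
        zg[degenerate, :] = np.nan
        z[:, cols] = zg
        masked[:, cols] = zero[:, cols] | degenerate[:, None]

    z[masked] = np.nan
    return ZScoreMatrix(
        list(expr.gene_ids), list(expr.cell_ids), z, masked,
        ddof=ddof, include_zeros_in_moments=include_zeros_in_moments,
    )


def classify_regulation(z: ZScoreMatrix, threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """Per-entry regulation call: UP (z > t), DOWN (z < -t), else NONE.

    Inequalities are strict; masked entries are always NONE.
    """
    if not threshold > 0:
        raise ValidationError("z threshold must be positive")
    vals = np.where(z.masked, 0.0, np.nan_to_num(z.z))
    calls = np.full(z.shape, NONE, dtype=object)
    calls[vals > threshold] = UP
    calls[vals < -threshold] = DOWN
    return calls


def entry_census(z: ZScoreMatrix) -> EntryCensus:
    """Count total / masked / retained Z-score entries."""
    total = int(z.masked.size)
    masked = int(z.masked.sum())
    return EntryCensus(total=total, masked=masked, retained=total - masked)


def two_sided_tail_probability(threshold: float = DEFAULT_Z_THRESHOLD) -> float:
    """P(|Z| > threshold) under the standard normal; the significance level
    implied by a symmetric Z cutoff (0.05 at 1.96)."""
    return float(2.0 * stats.norm.sf(threshold))
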