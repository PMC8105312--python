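"""Median-of-ratios normalisation and bait-gene co-expression.

Counts are normalised with the median-of-ratios size-factor estimator
(the DESeq2 default): per sample, the size factor is the median over
genes of the ratio of that sample's count to the gene's geometric mean
across samples, computed over genes with no zero count. Co-expression
of a candidate cluster is then summarised as the Pearson correlation of
every member gene with a bait gene across all samples, and per-gene
Z-score matrices are emitted for heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CoexpressionResult",
    "size_factors",
    "normalize",
    "bait_correlation",
    "select_bait",
    "zscore_matrix",
]


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer counts, genes x samples.

    Sample ids are expected to follow the ``tissue_replicate``
    convention (e.g. ``roottip_1``) but any unique labels are accepted.
    """

    counts: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class CoexpressionResult:
    """Per-gene Pearson r against a bait gene.

    ``r`` maps gene id -> correlation; genes with zero variance across
    samples map to NaN and are excluded from downstream counting.
    """

    bait_id: str
    r: dict[str, float]
    n_samples: int


def size_factors(m: CountMatrix | pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Only genes with all counts > 0 (after any pseudocount) enter the
    median. Raises if no gene is eligible, suggesting a pseudocount.
    """
    df = m.counts if isinstance(m, CountMatrix) else m
    x = df.to_numpy(dtype=float) + pseudocount
    eligible = (x > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has all counts > 0; pass pseudocount > 0 to make "
            "genes eligible for the median-of-ratios estimator"
        )
    xe = x[eligible]
    geo = np.exp(np.mean(np.log(xe), axis=1))
    ratios = xe / geo[:, None]
    return pd.Series(np.median(ratios, axis=0), index=df.columns, name="size_factor")


def normalize(m: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    df = m.counts if isinstance(m, CountMatrix) else m
    if len(factors) != df.shape[1]:
        raise ValueError("one size factor per sample required")
    if (np.asarray(factors, dtype=float) <= 0).any():
        raise ValueError("size factors must be > 0")
    return df / np.asarray(factors, dtype=float)[None, :]


def bait_correlation(
    norm: pd.DataFrame,
    bait_id: str,
    gene_ids: list[str] | None = None,
    log2: bool = False,
) -> CoexpressionResult:
    """Pearson r of every gene against the bait across all samples.

    Correlations are computed on normalised counts; ``log2`` applies a
    log2(x + 1) transform first. Zero-variance genes get NaN; a
    zero-variance bait is an error.
    """
    if bait_id not in norm.index:
        raise ValueError(f"bait {bait_id!r} not in matrix")
    gene_ids = list(norm.index) if gene_ids is None else gene_ids
    missing = [g for g in gene_ids if g not in norm.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    if norm.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    sub = norm.loc[[bait_id] + [g for g in gene_ids if g != bait_id]]
    x = sub.to_numpy(dtype=float)
    if log2:
        x = np.log2(x + 1.0)
    bait = x[0]
    if np.ptp(bait) == 0:
        raise ValueError(f"bait {bait_id!r} has zero variance")
    xc = x - x.mean(axis=1, keepdims=True)
    bc = bait - bait.mean()
    sd = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ bc) / (sd * np.sqrt((bc**2).sum()))
    r[sd == 0] = np.nan
    out = {g: float(v) for g, v in zip(sub.index, r)}
    out[bait_id] = 1.0  # exact by definition
    return CoexpressionResult(bait_id=bait_id, r=out, n_samples=norm.shape[1])


def select_bait(norm: pd.DataFrame, gene_ids: list[str]) -> str:
    """Representative gene of a cluster: highest mean normalised
    expression, ties broken toward the lexicographically smallest id."""
    if not gene_ids:
        raise ValueError("empty gene set")
    means = norm.loc[gene_ids].mean(axis=1)
    best = means.max()
    return sorted(g for g in gene_ids if means[g] == best)[0]


def zscore_matrix(
    norm: pd.DataFrame, gene_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene Z-scores across samples (sample SD, n-1 denominator).

    Returns (Z matrix, flags) where flags marks zero-SD genes whose
    rows are set to 0 instead of dividing by zero.
    """
    sub = norm if gene_ids is None else norm.loc[gene_ids]
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 samples for Z-scores")
    x = sub.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (x - mu) / sd
    z[flat, :] = 0.0
    return (
        pd.DataFrame(z, index=sub.index, columns=sub.columns),
        pd.Series(flat, index=sub.index, name="zero_sd"),
    )
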