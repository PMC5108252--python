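"""Estimation of the phenotypic (P) and divergence (D) covariance matrices.

P is the within-population phenotypic variance–covariance matrix,
estimated here from common-garden samples pooled across rearing years
after within-year mean standardization (which removes between-year shifts
in multivariate means without touching within-year covariance structure).
Element-wise standard errors come from a delete-one jackknife.

D is the among-taxon divergence matrix: the sample covariance of
mean-standardized taxon mean vectors, each taxon weighted equally.  A
MANOVA moment estimator is also provided for individual-level data
grouped by taxon, correcting the naive among-means covariance for
within-taxon sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_TRAITS, TraitMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CovarianceMatrix",
    "TaxonSummary",
    "p_matrix",
    "jackknife_se",
    "d_matrix_from_means",
    "d_matrix_moments",
    "taxon_summaries_from_frame",
]


@dataclass
class CovarianceMatrix:
    """Labeled symmetric covariance matrix with provenance metadata."""

    matrix: np.ndarray
    trait_labels: tuple = DEFAULT_TRAITS
    n: int = 2
    scale_tag: str = "raw"
    se: np.ndarray | None = None
    kind: str = "other"  # P, D, gamma, other

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(self.matrix) < 0):
            raise ValueError("negative variance on diagonal")
        if self.n < 2:
            raise ValueError("effective sample size must be >= 2")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        labels = list(self.trait_labels)
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


@dataclass
class TaxonSummary:
    """One taxon's record: specimen count, per-trait means and SDs."""

    taxon: str
    n: int
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.n < 1:
            raise ValueError(f"taxon {self.taxon}: n must be >= 1")
        if np.any(self.sds < 0):
            raise ValueError(f"taxon {self.taxon}: negative SD")


def taxon_summaries_from_frame(
    df: pd.DataFrame, trait_labels=DEFAULT_TRAITS
) -> list[TaxonSummary]:
    """Build TaxonSummary records from a (taxon, n, <t>_mean, <t>_sd) table."""
    out = []
    for _, row in df.iterrows():
        out.append(
            TaxonSummary(
                taxon=str(row["taxon"]),
                n=int(row["n"]),
                means=[row[f"{t}_mean"] for t in trait_labels],
                sds=[row[f"{t}_sd"] for t in trait_labels],
            )
        )
    return out


def p_matrix(Z: TraitMatrix, pool_by: str | None = None) -> CovarianceMatrix:
    """Sample covariance of a trait table, optionally pooled across groups.

    With ``pool_by="group"`` each group's columns are divided by the
    group's own trait means (mean standardization within group) before a
    single sample covariance (n−1 denominator) is taken over the pooled
    rows.  This is the two-year pooling scheme: between-group mean shifts
    are removed so they do not inflate variance along the shift direction.
    """
    vals = Z.values
    scale_tag = Z.scale_tag
    if pool_by is not None:
        if Z.group is None:
            raise ValueError("pool_by requested but TraitMatrix has no group")
        groups = np.asarray(Z.group)
        pooled = np.empty_like(vals)
        for g in np.unique(groups):
            mask = groups == g
            if mask.sum() < 3:
                raise ValueError(
                    f"group {g!r} has {mask.sum()} rows; need at least 3"
                )
            gmeans = vals[mask].mean(axis=0)
            if np.any(gmeans <= 0):
                raise ValueError(
                    f"group {g!r} has non-positive trait mean; cannot "
                    "mean-standardize"
                )
            pooled[mask] = vals[mask] / gmeans
        vals = pooled
        scale_tag = "mean_standardized"
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate a covariance")
    cov = np.cov(vals, rowvar=False, ddof=1)
    return CovarianceMatrix(
        matrix=cov,
        trait_labels=Z.trait_labels,
        n=vals.shape[0],
        scale_tag=scale_tag,
        kind="P",
    )


def jackknife_se(Z: TraitMatrix) -> np.ndarray:
    """Delete-one jackknife SEs for every element of the covariance matrix.

    SE_jk = sqrt(((n−1)/n) · Σ_i (θ_(i) − θ̄_(·))²) over the n delete-one
    covariance replicates θ_(i).
    """
    vals = Z.values
    n, p = vals.shape
    if n < 3:
        raise ValueError("jackknife needs at least 3 rows")
    reps = np.empty((n, p, p))
    idx = np.arange(n)
    for i in range(n):
        reps[i] = np.cov(vals[idx != i], rowvar=False, ddof=1)
    mean_rep = reps.mean(axis=0)
    ss = ((reps - mean_rep) ** 2).sum(axis=0)
    return np.sqrt((n - 1) / n * ss)


def d_matrix_from_means(
    taxa: list[TaxonSummary], ref_means
) -> CovarianceMatrix:
    """Divergence matrix: covariance of mean-standardized taxon means.

    Each taxon's mean vector is divided elementwise by ``ref_means`` (the
    reference taxon's trait means), then the sample covariance (n−1)
    across taxa is taken with every taxon weighted equally.
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    ref = np.asarray(ref_means, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference means must be strictly positive")
    rows = []
    for t in taxa:
        if t.means.shape != ref.shape or np.isnan(t.means).any():
            raise ValueError(f"taxon {t.taxon}: incomplete trait means")
        rows.append(t.means / ref)
    M = np.asarray(rows)
    cov = np.cov(M, rowvar=False, ddof=1)
    return CovarianceMatrix(
        matrix=cov,
        n=len(taxa),
        scale_tag="mean_standardized",
        kind="D",
    )


def d_matrix_moments(X: TraitMatrix) -> CovarianceMatrix:
    """MANOVA moment estimator of the among-taxon covariance.

    D̂ = (MS_between − MS_within) / n₀ with n₀ the usual unbalanced-design
    coefficient (N − Σn_k²/N)/(K−1).  Negative eigenvalues of D̂ are
    truncated at zero (with a log entry) since a covariance matrix must be
    positive semidefinite.
    """
    if X.group is None:
        raise ValueError("d_matrix_moments requires a taxon group factor")
    vals = X.values
    groups = np.asarray(X.group)
    uniq = np.unique(groups)
    K = len(uniq)
    if K < 3:
        raise ValueError("need at least 3 taxa")
    counts = np.array([(groups == g).sum() for g in uniq])
    if np.all(counts < 2):
        raise ValueError("all taxa are singletons; within-taxon MS undefined")
    N = counts.sum()
    p = vals.shape[1]
    grand = vals.mean(axis=0)
    ssb = np.zeros((p, p))
    ssw = np.zeros((p, p))
    for g, nk in zip(uniq, counts):
        sub = vals[groups == g]
        mk = sub.mean(axis=0)
        d = mk - grand
        ssb += nk * np.outer(d, d)
        r = sub - mk
        ssw += r.T @ r
    msb = ssb / (K - 1)
    msw = ssw / (N - K)
    n0 = (N - (counts**2).sum() / N) / (K - 1)
    D = (msb - msw) / n0
    w, V = np.linalg.eigh(D)
    if np.any(w < 0):
        logger.warning(
            "moment estimate of D had %d negative eigenvalue(s); truncated "
            "at 0",
            int((w < 0).sum()),
        )
        D = (V * np.maximum(w, 0.0)) @ V.T
        D = (D + D.T) / 2
    return CovarianceMatrix(
        matrix=D,
        trait_labels=X.trait_labels,
        n=K,
        scale_tag=X.scale_tag,
        kind="D",
    )
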