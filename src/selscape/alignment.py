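"""Alignment of selection with variance and divergence.

Three tools: (i) the vector correlation ρ = |cos angle| between a
canonical selection axis and an eigenvector of P or D; (ii) permutation
tests that shuffle trait columns independently (destroying covariance
while preserving marginals) to ask how often a random covariance
structure would align as well with a fixed, error-free reference
direction; (iii) the directional variance e(m) = m′Am — the variance of
P or D along a stated direction, with an average over random directions
on the unit sphere as a yardstick (E[m′Am] = trace(A)/p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TraitMatrix
from .matrices import CovarianceMatrix, TaxonSummary

__all__ = [
    "AlignmentResult",
    "vector_correlation",
    "min_eigenvector",
    "alignment_permutation_test",
    "taxon_mean_permutation_test",
    "directional_variance",
    "random_direction_average",
]


@dataclass
class AlignmentResult:
    """Vector correlation between a fixed reference and a data eigenvector."""

    rho: float
    p_value: float
    reference_vector: np.ndarray
    target_vector: np.ndarray
    n_perm: int
    seed: object = None
    which: str = "min"
    degenerate: bool = False

    def __post_init__(self):
        self.reference_vector = np.asarray(self.reference_vector, float)
        self.target_vector = np.asarray(self.target_vector, float)


def vector_correlation(a, b) -> float:
    """|a·b| / (‖a‖‖b‖): 1 = parallel, 0 = orthogonal."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("vector correlation undefined for a zero vector")
    return float(abs(a @ b) / (na * nb))


def _as_matrix(A):
    return A.matrix if isinstance(A, CovarianceMatrix) else np.asarray(A, float)


def _extreme_eigenvector(M: np.ndarray, which: str):
    """Unit eigenvector of the smallest/largest eigenvalue + degeneracy flag."""
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(M)
    if which == "min":
        v, gap = vecs[:, 0], vals[1] - vals[0]
    elif which == "max":
        v, gap = vecs[:, -1], vals[-1] - vals[-2]
    else:
        raise ValueError("which must be 'min' or 'max'")
    degenerate = gap < 1e-8 * abs(np.trace(M))
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v, degenerate


def min_eigenvector(A, which: str = "min") -> np.ndarray:
    """Eigenvector of the smallest (default) or largest eigenvalue.

    Sign convention: the largest-|loading| entry is positive.  A warning
    is issued when the relevant eigenvalue gap is below 1e-8·trace
    (direction poorly identified).
    """
    v, degenerate = _extreme_eigenvector(_as_matrix(A), which)
    if degenerate:
        warnings.warn(
            "near-degenerate eigenvalues: the extreme eigenvector is not "
            "well identified",
            stacklevel=2,
        )
    return v


def _column_shuffle_null(rows, reference, which, n_perm, seed, rho_obs):
    """Shared permutation engine for the alignment tests."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n, p = rows.shape
    count = 0
    for _ in range(n_perm):
        perm = np.empty_like(rows)
        for j in range(p):
            perm[:, j] = rows[rng.permutation(n), j]
        M = np.cov(perm, rowvar=False, ddof=1)
        v, _ = _extreme_eigenvector(M, which)
        if vector_correlation(reference, v) >= rho_obs:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def alignment_permutation_test(
    X: TraitMatrix,
    reference,
    which: str = "min",
    n_perm: int = 10_000,
    seed=None,
) -> AlignmentResult:
    """Test alignment of a covariance eigenvector with a fixed reference.

    The observed ρ compares the designated (min- or max-variance)
    eigenvector of cov(X) with ``reference`` (treated as error-free).
    Each permutation shuffles every trait column independently, recomputes
    the covariance and its eigenvector, and records the null ρ;
    p = (1 + #{ρ_null ≥ ρ_obs}) / (n_perm + 1).
    """
    reference = np.asarray(reference, dtype=float)
    rows = X.values
    M = np.cov(rows, rowvar=False, ddof=1)
    target, degenerate = _extreme_eigenvector(M, which)
    rho_obs = vector_correlation(reference, target)
    p_val = _column_shuffle_null(rows, reference, which, n_perm, seed, rho_obs)
    return AlignmentResult(
        rho=rho_obs,
        p_value=p_val,
        reference_vector=reference / np.linalg.norm(reference),
        target_vector=target,
        n_perm=n_perm,
        seed=seed,
        which=which,
        degenerate=degenerate,
    )


def taxon_mean_permutation_test(
    taxa: list[TaxonSummary],
    reference,
    ref_means,
    which: str = "min",
    n_perm: int = 10_000,
    seed=None,
) -> AlignmentResult:
    """Alignment test where the rows are mean-standardized taxon means.

    The analogue of :func:`alignment_permutation_test` for the divergence
    matrix: D's designated eigenvector vs the fixed reference, with the
    column-wise shuffle applied to the taxon-mean table.
    """
    ref_means = np.asarray(ref_means, dtype=float)
    rows = np.asarray([t.means for t in taxa], dtype=float) / ref_means
    M = np.cov(rows, rowvar=False, ddof=1)
    if np.allclose(M, 0.0, atol=1e-14):
        raise ValueError("taxon means are identical: divergence matrix is zero")
    reference = np.asarray(reference, dtype=float)
    target, degenerate = _extreme_eigenvector(M, which)
    rho_obs = vector_correlation(reference, target)
    p_val = _column_shuffle_null(rows, reference, which, n_perm, seed, rho_obs)
    return AlignmentResult(
        rho=rho_obs,
        p_value=p_val,
        reference_vector=reference / np.linalg.norm(reference),
        target_vector=target,
        n_perm=n_perm,
        seed=seed,
        which=which,
        degenerate=degenerate,
    )


def directional_variance(A, m) -> float:
    """e(m) = m′Am: the variance of A in direction m (m renormalized)."""
    M = _as_matrix(A)
    m = np.asarray(m, dtype=float)
    if m.shape[0] != M.shape[0]:
        raise ValueError(
            f"direction has length {m.shape[0]} but matrix is {M.shape[0]}-d"
        )
    norm = np.linalg.norm(m)
    if norm == 0:
        raise ValueError("zero direction vector")
    if not np.isclose(norm, 1.0, atol=1e-8):
        warnings.warn("direction renormalized to unit length", stacklevel=2)
        m = m / norm
    else:
        m = m / norm
    return float(m @ M @ m)


def random_direction_average(A, k: int = 1000, seed=None):
    """Mean and SD of m′Am over k uniform random unit directions.

    Directions are Gaussian draws normalized to the sphere; the
    expectation is trace(A)/p.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    M = _as_matrix(A)
    p = M.shape[0]
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((k, p))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    e = np.einsum("ij,jk,ik->i", dirs, M, dirs)
    return float(e.mean()), float(e.std(ddof=1))
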