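"""Multivariate sexual dimorphism: the Mahalanobis index d_i.

For each taxon with both sexes measured, d_i is the Mahalanobis distance
between the male and female mean-standardized trait mean vectors, using
a phenotypic covariance matrix as the metric.  The metric can be a
pooled within-taxon both-sex covariance assembled from the per-taxon
SDs, or a supplied reference P-matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .matrices import CovarianceMatrix, TaxonSummary

logger = logging.getLogger(__name__)

__all__ = [
    "DimorphismIndex",
    "mahalanobis_dimorphism",
    "dimorphism_table",
    "dimorphism_summaries",
]


@dataclass
class DimorphismIndex:
    taxon: str
    d_i: float
    male_means: np.ndarray
    female_means: np.ndarray
    covariance_used: CovarianceMatrix


def mahalanobis_dimorphism(male_means, female_means, S) -> float:
    """sqrt((μ_m − μ_f)′ S⁻¹ (μ_m − μ_f)) for a positive-definite metric S."""
    mu_m = np.asarray(male_means, dtype=float)
    mu_f = np.asarray(female_means, dtype=float)
    M = S.matrix if isinstance(S, CovarianceMatrix) else np.asarray(S, float)
    if np.linalg.eigvalsh(M)[0] <= 0:
        raise ValueError("covariance metric must be positive definite")
    diff = mu_m - mu_f
    sol = linalg.solve(M, diff, assume_a="pos")
    return float(np.sqrt(diff @ sol))


def _pooled_within_taxon_cov(pairs, ref_means):
    """Diagonal pooled within-taxon both-sex covariance from summary SDs.

    Summary tables carry per-trait SDs but no within-taxon covariances,
    so the pooled metric is diagonal: variances pooled over taxa and
    sexes with n−1 weights, on the mean-standardized scale.
    """
    num = None
    dof = 0.0
    for male, female in pairs:
        for s in (male, female):
            if s.n < 2:
                continue
            var = (s.sds / ref_means) ** 2
            num = var * (s.n - 1) if num is None else num + var * (s.n - 1)
            dof += s.n - 1
    if num is None or dof <= 0:
        raise ValueError("no taxon has n >= 2 for pooled variance")
    return np.diag(num / dof), int(dof) + 1


def dimorphism_table(
    taxa_male: list[TaxonSummary],
    taxa_female: list[TaxonSummary],
    pooling: str = "pooled_within_taxon",
    reference_P: CovarianceMatrix | None = None,
    ref_means=None,
) -> list[DimorphismIndex]:
    """Per-taxon dimorphism indices for taxa with both sexes measured.

    Female records require n ≥ 2; taxa present in only one sex are
    skipped with a log entry.  ``ref_means`` (default: across-taxa male
    grand mean) puts both sexes on the mean-standardized scale before
    the distance is taken.
    """
    males = {t.taxon: t for t in taxa_male}
    females = {t.taxon: t for t in taxa_female}
    pairs = []
    for name, m in males.items():
        f = females.get(name)
        if f is None:
            logger.info("taxon %s has no female record; skipped", name)
            continue
        if f.n < 2:
            logger.info("taxon %s female n=%d < 2; skipped", name, f.n)
            continue
        pairs.append((m, f))
    if not pairs:
        raise ValueError("no taxa with both sexes measured")

    if ref_means is None:
        ref_means = np.mean([m.means for m, _ in pairs], axis=0)
    ref_means = np.asarray(ref_means, dtype=float)
    if np.any(ref_means <= 0):
        raise ValueError("reference means must be strictly positive")

    if pooling == "reference_P":
        if reference_P is None:
            raise ValueError("pooling='reference_P' requires reference_P")
        cov = reference_P
    elif pooling == "pooled_within_taxon":
        mat, n_eff = _pooled_within_taxon_cov(pairs, ref_means)
        cov = CovarianceMatrix(
            matrix=mat,
            n=n_eff,
            scale_tag="mean_standardized",
            kind="P",
        )
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    out = []
    for m, f in pairs:
        mu_m = m.means / ref_means
        mu_f = f.means / ref_means
        out.append(
            DimorphismIndex(
                taxon=m.taxon,
                d_i=mahalanobis_dimorphism(mu_m, mu_f, cov),
                male_means=mu_m,
                female_means=mu_f,
                covariance_used=cov,
            )
        )
    return out


def dimorphism_summaries(indices: list[DimorphismIndex], trait_labels=None):
    """Across-taxon bivariate summaries of the dimorphism table.

    Returns, per trait: the correlation of male mean-standardized means
    with d_i, and the male–female homologous-trait covariance and
    correlation across taxa.
    """
    if len(indices) < 3:
        raise ValueError("need at least 3 taxa for across-taxon summaries")
    d = np.array([ix.d_i for ix in indices])
    M = np.array([ix.male_means for ix in indices])
    F = np.array([ix.female_means for ix in indices])
    p = M.shape[1]
    labels = list(trait_labels) if trait_labels else [f"trait{i+1}" for i in range(p)]
    out = {}
    for j, lab in enumerate(labels):
        male_d_corr = float(np.corrcoef(M[:, j], d)[0, 1])
        mf_cov = float(np.cov(M[:, j], F[:, j], ddof=1)[0, 1])
        mf_corr = float(np.corrcoef(M[:, j], F[:, j])[0, 1])
        out[lab] = {
            "male_vs_d_corr": male_d_corr,
            "male_female_cov": mf_cov,
            "male_female_corr": mf_corr,
        }
    return out
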