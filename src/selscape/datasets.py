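"""Packaged *Phymata* fixtures: published summary tables as loaders.

The individual-level field and rearing data behind the selection and
P-matrix analyses were never deposited, so the package ships only the
published summary quantities: the 37-taxon museum trait table, the
variance-standardized selection gradients, the mean-standardized P and D
matrices (printed ×100 and ×10 respectively; loaders return the
unscaled matrices), and the mean-standardized canonical axes.  One file
(``phymata_taxon_means_verbatim.csv``) preserves a printing artifact in
the source table (an SD printed as "0190"); the default loader uses the
corrected copy — SDs never enter the divergence matrix, so the choice
has no numeric consequence downstream.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core import DEFAULT_TRAITS
from .matrices import CovarianceMatrix, TaxonSummary, taxon_summaries_from_frame
from .selection import GradientEstimates

__all__ = [
    "load_taxon_means",
    "load_taxon_summaries",
    "load_reference_means",
    "load_selection_gradients",
    "load_p_matrix",
    "load_d_matrix",
    "load_canonical_vectors",
    "load_canonical_table",
]

REFERENCE_TAXON = "P. americana americana"

#: Sample sizes behind the published matrices: 108 common-garden males
#: (50 + 58 across two years) for P; 37 museum taxa for D.
P_MATRIX_N = 108
D_MATRIX_N = 37


def _read(name: str) -> pd.DataFrame:
    with resources.files("selscape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_taxon_means(corrected: bool = True) -> pd.DataFrame:
    """The 37-taxon museum table: n, per-trait means and SDs."""
    name = (
        "phymata_taxon_means.csv"
        if corrected
        else "phymata_taxon_means_verbatim.csv"
    )
    df = _read(name)
    if not corrected:
        # the verbatim copy keeps the "0190" artifact as a string column
        df["PN_sd"] = pd.to_numeric(df["PN_sd"], errors="coerce")
    return df


def load_taxon_summaries(min_n: int = 1) -> list[TaxonSummary]:
    """Taxon records, optionally filtered to a minimum male sample size."""
    df = load_taxon_means()
    df = df[df["n"] >= min_n]
    return taxon_summaries_from_frame(df)


def load_reference_means() -> np.ndarray:
    """Trait means of the reference taxon (museum *P. a. americana* males)."""
    df = load_taxon_means()
    row = df[df["taxon"] == REFERENCE_TAXON].iloc[0]
    return np.array([row[f"{t}_mean"] for t in DEFAULT_TRAITS])


def load_selection_gradients() -> GradientEstimates:
    """Published variance-standardized β and γ with their SEs."""
    df = _read("selection_gradients_varstd.csv")
    labels = tuple(df["trait"])
    gamma = df[[f"gamma_{t}" for t in labels]].to_numpy()
    gamma_se = df[[f"gamma_se_{t}" for t in labels]].to_numpy()
    return GradientEstimates(
        beta=df["beta"].to_numpy(),
        beta_se=df["beta_se"].to_numpy(),
        gamma=gamma,
        gamma_se=gamma_se,
        trait_labels=labels,
        scale_tag="variance_standardized",
        doubling_applied=True,
    )


def _load_matrix(name: str, scale: float):
    df = _read(name)
    labels = tuple(df["trait"])
    return df[list(labels)].to_numpy() / scale, labels


def load_p_matrix() -> CovarianceMatrix:
    """Mean-standardized P (published ×100; returned unscaled)."""
    mat, labels = _load_matrix("p_matrix_meanstd_x100.csv", 100.0)
    se, _ = _load_matrix("p_matrix_se_meanstd_x100.csv", 100.0)
    return CovarianceMatrix(
        matrix=mat,
        trait_labels=labels,
        n=P_MATRIX_N,
        scale_tag="mean_standardized",
        se=se,
        kind="P",
    )


def load_d_matrix(kind: str = "species_means") -> CovarianceMatrix:
    """Mean-standardized D (published ×10; returned unscaled).

    ``kind="species_means"`` is the among-taxon-means estimate;
    ``kind="mixed_model"`` the REML random-effect estimate.
    """
    if kind == "species_means":
        mat, labels = _load_matrix("d_matrix_meanstd_x10.csv", 10.0)
    elif kind == "mixed_model":
        mat, labels = _load_matrix("d_matrix_mixed_meanstd_x10.csv", 10.0)
    else:
        raise ValueError(f"unknown D-matrix kind {kind!r}")
    return CovarianceMatrix(
        matrix=mat,
        trait_labels=labels,
        n=D_MATRIX_N,
        scale_tag="mean_standardized",
        kind="D",
    )


def load_canonical_vectors() -> dict:
    """Mean-standardized canonical axes (m_max, m_2, m_1) as unit-ish rows."""
    df = _read("canonical_vectors_meanstd.csv")
    return {
        row["axis"]: row[list(DEFAULT_TRAITS)].to_numpy(dtype=float)
        for _, row in df.iterrows()
    }


def load_canonical_table() -> pd.DataFrame:
    """Variance-standardized canonical axes with θ and λ."""
    return _read("canonical_varstd.csv")
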