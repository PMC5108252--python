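"""Synthetic data with the structure the analyses assume.

Three generators mirror the three empirical samples of the study design:
a field sample of males with mating success under a quadratic or
Gaussian fitness surface (default n = 44), a two-year common-garden
sample for P-matrix estimation (default 50 + 58 males with a
between-year mean shift), and a set of taxon means drawn around a grand
mean with between-taxon covariance D plus within-taxon sampling noise
(default 37 taxa).  Default parameter values are the published point
estimates: the Table-scale γ and β for the surface, and P/D converted
back to the raw trait scale via the reference trait means.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_TRAITS, DEFAULT_UNITS, TraitMatrix
from .matrices import TaxonSummary

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_selection_sample",
    "simulate_taxon_means",
    "simulate_two_year_p_sample",
]

# published point estimates used as generator defaults
_REF_MEANS = np.array([3.10, 236.13, 213.40])
_P_MEANSTD = np.array(
    [
        [0.243, 0.016, -0.063],
        [0.016, 0.265, 0.421],
        [-0.063, 0.421, 2.717],
    ]
) / 100.0
_D_MEANSTD = np.array(
    [
        [0.335, 0.036, -0.017],
        [0.036, 0.100, 0.026],
        [-0.017, 0.026, 0.236],
    ]
) / 10.0
_BETA = np.array([0.008, -0.029, 0.021])
_GAMMA = np.array(
    [
        [0.137, 0.005, -0.118],
        [0.005, -0.365, 0.214],
        [-0.118, 0.214, -0.206],
    ]
)


def _default_p_raw():
    return _P_MEANSTD * np.outer(_REF_MEANS, _REF_MEANS)


def _default_d_raw():
    return _D_MEANSTD * np.outer(_REF_MEANS, _REF_MEANS)


def _default_width_matrix():
    # ridge-shaped Gaussian surface: weak curvature everywhere, strong
    # stabilizing curvature along the published m_max direction
    u = np.array([0.111, -0.803, 0.585])
    u = u / np.linalg.norm(u)
    omega_inv = 0.1 * np.eye(3) + 0.5 * np.outer(u, u)
    return np.linalg.inv(omega_inv)


@dataclass
class SimulationConfig:
    """Knobs for all three generators; defaults emulate the study design."""

    n_individuals: int = 44
    trait_means: np.ndarray = field(default_factory=lambda: _REF_MEANS.copy())
    P_true: np.ndarray = field(default_factory=_default_p_raw)
    fitness_model: str = "quadratic_exact"  # or "gaussian_surface"
    beta_true: np.ndarray = field(default_factory=lambda: _BETA.copy())
    gamma_true: np.ndarray = field(default_factory=lambda: _GAMMA.copy())
    optimum: np.ndarray = field(default_factory=lambda: np.zeros(3))
    width_matrix: np.ndarray = field(default_factory=_default_width_matrix)
    fitness_noise: str = "bernoulli"  # none | poisson | bernoulli
    mating_rate: float = 0.5  # mean Bernoulli mating probability
    mean_count: float = 1.0  # mean Poisson mating count
    n_taxa: int = 37
    grand_mean: np.ndarray = field(default_factory=lambda: _REF_MEANS.copy())
    D_true: np.ndarray = field(default_factory=_default_d_raw)
    per_taxon_n: object = (4, 13)  # int or inclusive (low, high) range
    year_offsets: tuple = (
        np.zeros(3),
        np.array([0.05, 5.0, 5.0]),
    )

    def __post_init__(self):
        for name in ("P_true", "gamma_true", "width_matrix", "D_true"):
            M = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            setattr(self, name, M)
        for name in ("P_true", "width_matrix"):
            if np.linalg.eigvalsh(getattr(self, name))[0] <= 0:
                raise ValueError(f"{name} must be positive definite")
        if np.linalg.eigvalsh(self.D_true)[0] < -1e-10:
            raise ValueError("D_true must be positive semidefinite")
        if self.n_individuals < 1 or self.n_taxa < 1:
            raise ValueError("sample sizes must be positive")
        p = len(self.trait_means)
        for name in ("beta_true", "optimum", "grand_mean"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (p,):
                raise ValueError(f"{name} has wrong dimension")
            setattr(self, name, v)
        if self.gamma_true.shape != (p, p) or self.P_true.shape != (p, p):
            raise ValueError("matrix parameter dimensions inconsistent")


def _expected_fitness(cfg: SimulationConfig, z_std: np.ndarray):
    """Expected relative fitness on the standardized phenotype scale."""
    if cfg.fitness_model == "quadratic_exact":
        w = (
            1.0
            + z_std @ cfg.beta_true
            + 0.5 * np.einsum("ij,jk,ik->i", z_std, cfg.gamma_true, z_std)
        )
        n_trunc = int((w < 0).sum())
        if n_trunc:
            logger.info(
                "quadratic surface: %d of %d expected fitnesses truncated "
                "at 0",
                n_trunc,
                len(w),
            )
        return np.maximum(w, 0.0)
    if cfg.fitness_model == "gaussian_surface":
        dz = z_std - cfg.optimum
        inv = np.linalg.inv(cfg.width_matrix)
        q = np.einsum("ij,jk,ik->i", dz, inv, dz)
        return np.exp(-0.5 * q)
    raise ValueError(f"unknown fitness model {cfg.fitness_model!r}")


def simulate_selection_sample(cfg: SimulationConfig, seed=None):
    """Phenotypes + mating success under the configured fitness surface.

    Phenotypes ~ MVN(trait_means, P_true) on the raw scale; the surface
    is evaluated on the variance-standardized scale (standardized within
    the sample, as the estimators expect).  Realized fitness is the
    expected surface value (``none``), a Poisson count, or a Bernoulli
    mated/not indicator scaled to ``mating_rate``.

    Returns (TraitMatrix raw scale, absolute fitness vector).
    """
    rng = np.random.default_rng(seed)
    Z_raw = rng.multivariate_normal(
        cfg.trait_means, cfg.P_true, size=cfg.n_individuals
    )
    z_std = (Z_raw - Z_raw.mean(axis=0)) / Z_raw.std(axis=0, ddof=1)
    w_exp = _expected_fitness(cfg, z_std)
    if cfg.fitness_noise == "none":
        w = w_exp
    elif cfg.fitness_noise == "poisson":
        lam = w_exp / max(w_exp.mean(), 1e-300) * cfg.mean_count
        w = rng.poisson(lam).astype(float)
    elif cfg.fitness_noise == "bernoulli":
        prob = np.clip(
            w_exp / max(w_exp.mean(), 1e-300) * cfg.mating_rate, 0.0, 1.0
        )
        w = rng.binomial(1, prob).astype(float)
    else:
        raise ValueError(f"unknown fitness noise {cfg.fitness_noise!r}")
    X = TraitMatrix(
        Z_raw,
        trait_labels=DEFAULT_TRAITS[: Z_raw.shape[1]],
        units=DEFAULT_UNITS[: Z_raw.shape[1]],
        scale_tag="raw",
    )
    return X, w


def simulate_taxon_means(cfg: SimulationConfig, seed=None):
    """Taxon summaries: true means ~ MVN(grand_mean, D_true) plus
    within-taxon sampling (n_k individuals ~ MVN(mean_k, P_true) each)."""
    rng = np.random.default_rng(seed)
    D = cfg.D_true + 1e-12 * np.trace(cfg.D_true) * np.eye(len(cfg.grand_mean))
    true_means = rng.multivariate_normal(cfg.grand_mean, D, size=cfg.n_taxa)
    if isinstance(cfg.per_taxon_n, int):
        ns = np.full(cfg.n_taxa, cfg.per_taxon_n)
    else:
        low, high = cfg.per_taxon_n
        ns = rng.integers(low, high + 1, size=cfg.n_taxa)
    out = []
    for k in range(cfg.n_taxa):
        draws = rng.multivariate_normal(true_means[k], cfg.P_true, size=ns[k])
        out.append(
            TaxonSummary(
                taxon=f"taxon_{k + 1:03d}",
                n=int(ns[k]),
                means=draws.mean(axis=0),
                sds=draws.std(axis=0, ddof=1) if ns[k] > 1 else np.zeros_like(
                    cfg.grand_mean
                ),
            )
        )
    return out


def simulate_two_year_p_sample(
    cfg: SimulationConfig, n_per_year=(50, 58), seed=None
) -> TraitMatrix:
    """Two rearing-year samples with a between-year mean shift.

    Each year's phenotypes are MVN(trait_means + offset, P_true); pooling
    with within-year mean standardization recovers P_true despite the
    offsets.
    """
    if len(cfg.year_offsets) != 2 or len(n_per_year) != 2:
        raise ValueError("need exactly two year offsets and two sizes")
    rng = np.random.default_rng(seed)
    blocks, years = [], []
    for y, (off, n) in enumerate(zip(cfg.year_offsets, n_per_year), start=1):
        blocks.append(
            rng.multivariate_normal(
                cfg.trait_means + np.asarray(off, float), cfg.P_true, size=n
            )
        )
        years.extend([y] * n)
    vals = np.vstack(blocks)
    return TraitMatrix(
        vals,
        trait_labels=DEFAULT_TRAITS[: vals.shape[1]],
        units=DEFAULT_UNITS[: vals.shape[1]],
        scale_tag="raw",
        group=np.array(years),
    )
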