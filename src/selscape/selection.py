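"""Lande–Arnold selection-gradient estimation and canonical analysis.

The central model: ordinary least-squares regression of relative fitness
on variance-standardized traits.  The linear model gives the directional
gradients β; the full quadratic model gives the γ-matrix of quadratic and
correlational gradients (with the conventional doubling of the squared-term
coefficients).  Diagonalizing γ rotates the surface to canonical axes
m_i with curvatures λ_i; the axis with the most negative λ (``m_max``) is
the direction of strongest stabilizing selection.  Eigenvalue significance
is assessed by permuting fitness across individuals and rebuilding the
null distribution of rank-ordered eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import TraitMatrix, variance_standardize

__all__ = [
    "GradientEstimates",
    "CanonicalForm",
    "SelectionSurface",
    "SelectionSurfaceResults",
    "relative_fitness",
    "estimate_beta",
    "estimate_gamma",
    "canonical_analysis",
    "eigenvalue_permutation_test",
    "mean_standardize_gradients",
]


def relative_fitness(w) -> np.ndarray:
    """Divide absolute fitness by its sample mean (output mean exactly 1)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("absolute fitness must be non-negative")
    m = w.mean()
    if m <= 0:
        raise ValueError("all-zero fitness: relative fitness undefined")
    return w / m


@dataclass
class GradientEstimates:
    """Linear (β) and nonlinear (γ) selection gradients with OLS SEs."""

    beta: np.ndarray
    beta_se: np.ndarray
    gamma: np.ndarray
    gamma_se: np.ndarray
    trait_labels: tuple
    scale_tag: str = "variance_standardized"
    fit_stats: dict = field(default_factory=dict)
    doubling_applied: bool = True

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.allclose(self.gamma, self.gamma.T, atol=1e-12):
            raise ValueError("gamma must be symmetric")
        if self.beta_se is not None:
            self.beta_se = np.asarray(self.beta_se, dtype=float)
            if np.any(self.beta_se < 0):
                raise ValueError("SEs must be non-negative")
        if self.gamma_se is not None:
            self.gamma_se = np.asarray(self.gamma_se, dtype=float)
            if np.any(self.gamma_se < 0):
                raise ValueError("SEs must be non-negative")

    @property
    def p(self) -> int:
        return self.beta.shape[0]


@dataclass
class CanonicalForm:
    """Canonical rotation of a γ-matrix.

    ``m_vectors[i]`` is the i-th canonical axis (rows, unit norm), sorted
    by descending eigenvalue ``lambdas[i]``; ``thetas[i] = m_i·β`` is the
    directional gradient along that axis.  ``m_max_index`` points at the
    largest-magnitude negative eigenvalue (None if γ has no negative
    curvature).
    """

    m_vectors: np.ndarray
    lambdas: np.ndarray
    thetas: np.ndarray
    p_values: np.ndarray | None = None
    m_max_index: int | None = None
    trait_labels: tuple = ()

    def __post_init__(self):
        gram = self.m_vectors @ self.m_vectors.T
        if not np.allclose(gram, np.eye(len(self.lambdas)), atol=1e-10):
            raise ValueError("canonical vectors must be orthonormal")

    @property
    def m_max(self) -> np.ndarray | None:
        if self.m_max_index is None:
            return None
        return self.m_vectors[self.m_max_index]


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    """Flip sign so the largest-|loading| entry is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _quadratic_design(Z: np.ndarray):
    """[1 | z | z_i^2 | z_i z_j (i<j)] design and index bookkeeping."""
    n, p = Z.shape
    cols = [np.ones(n), *(Z[:, i] for i in range(p))]
    sq_idx = []
    for i in range(p):
        sq_idx.append(len(cols))
        cols.append(Z[:, i] ** 2)
    cross_idx = {}
    for i in range(p):
        for j in range(i + 1, p):
            cross_idx[(i, j)] = len(cols)
            cols.append(Z[:, i] * Z[:, j])
    return np.column_stack(cols), sq_idx, cross_idx


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit (statsmodels) returning (coef, se, R2, F, df1, df2, p_value)."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"insufficient observations: n={n}, parameters={k}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return (
        fit.params,
        fit.bse,
        float(fit.rsquared),
        float(fit.fvalue),
        int(fit.df_model),
        int(fit.df_resid),
        float(fit.f_pvalue),
    )


def _check_standardized(Z: TraitMatrix):
    if Z.scale_tag != "variance_standardized":
        raise ValueError(
            "gradient estimation expects variance-standardized traits; "
            f"got scale_tag={Z.scale_tag!r}"
        )


def estimate_beta(Z: TraitMatrix, w_rel) -> GradientEstimates:
    """Directional gradients: OLS of relative fitness on standardized traits."""
    _check_standardized(Z)
    w_rel = np.asarray(w_rel, dtype=float)
    n, p = Z.values.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 = {p + 1} individuals, got {n}")
    X = np.column_stack([np.ones(n), Z.values])
    coef, se, r2, F, df1, df2, pval = _ols(X, w_rel)
    return GradientEstimates(
        beta=coef[1:],
        beta_se=se[1:],
        gamma=np.zeros((p, p)),
        gamma_se=np.zeros((p, p)),
        trait_labels=Z.trait_labels,
        fit_stats={"linear": {"r2": r2, "F": F, "df": (df1, df2), "p": pval}},
        doubling_applied=False,
    )


def estimate_gamma(
    Z: TraitMatrix, w_rel, double_quadratic: bool = True
) -> GradientEstimates:
    """Full quadratic fit: γ from squared and cross-product terms.

    β is reported from the separate linear-only model (the conventional
    two-model presentation); diagonal γ entries are doubled squared-term
    coefficients unless ``double_quadratic=False``.
    """
    _check_standardized(Z)
    w_rel = np.asarray(w_rel, dtype=float)
    n, p = Z.values.shape
    n_min = p * (p + 3) // 2 + 1
    if n <= n_min:
        raise ValueError(
            f"quadratic fit needs n > {n_min} individuals for p={p}, got {n}"
        )
    X, sq_idx, cross_idx = _quadratic_design(Z.values)
    coef, se, r2, F, df1, df2, pval = _ols(X, w_rel)

    gamma = np.zeros((p, p))
    gamma_se = np.zeros((p, p))
    mult = 2.0 if double_quadratic else 1.0
    for i in range(p):
        gamma[i, i] = mult * coef[sq_idx[i]]
        gamma_se[i, i] = mult * se[sq_idx[i]]
    for (i, j), k in cross_idx.items():
        gamma[i, j] = gamma[j, i] = coef[k]
        gamma_se[i, j] = gamma_se[j, i] = se[k]

    linear = estimate_beta(Z, w_rel)
    fit_stats = dict(linear.fit_stats)
    fit_stats["nonlinear"] = {"r2": r2, "F": F, "df": (df1, df2), "p": pval}
    return GradientEstimates(
        beta=linear.beta,
        beta_se=linear.beta_se,
        gamma=gamma,
        gamma_se=gamma_se,
        trait_labels=Z.trait_labels,
        fit_stats=fit_stats,
        doubling_applied=double_quadratic,
    )


def canonical_analysis(g: GradientEstimates) -> CanonicalForm:
    """Diagonalize γ; λ_i descending, θ_i = m_i·β, m_max = most negative λ."""
    vals, vecs = np.linalg.eigh(g.gamma)
    order = np.argsort(vals)[::-1]
    lambdas = vals[order]
    m = np.array([_sign_normalize(vecs[:, k]) for k in order])
    thetas = m @ g.beta
    m_max_index = None
    if lambdas.min() < 0:
        m_max_index = int(np.argmin(lambdas))
    return CanonicalForm(
        m_vectors=m,
        lambdas=lambdas,
        thetas=thetas,
        m_max_index=m_max_index,
        trait_labels=g.trait_labels,
    )


def _fast_gamma_eigs(X_design, sq_idx, cross_idx, p, w, double=True):
    """Sorted (descending) eigenvalues of γ refit on fitness vector w."""
    coef, _, _, _ = np.linalg.lstsq(X_design, w, rcond=None)
    gamma = np.zeros((p, p))
    mult = 2.0 if double else 1.0
    for i in range(p):
        gamma[i, i] = mult * coef[sq_idx[i]]
    for (i, j), k in cross_idx.items():
        gamma[i, j] = gamma[j, i] = coef[k]
    return np.sort(np.linalg.eigvalsh(gamma))[::-1]


def eigenvalue_permutation_test(
    Z: TraitMatrix,
    w,
    n_perm: int = 1000,
    seed=None,
    double_quadratic: bool = True,
    two_tailed: bool = False,
):
    """Permutation null for canonical eigenvalues.

    Fitness is shuffled across individuals (phenotypes held fixed), γ is
    re-estimated and re-diagonalized each time, and the observed rank-r
    eigenvalue is compared with the null distribution of rank-r
    eigenvalues.  One-tailed in the observed sign direction by default;
    p = (1 + #{as-or-more-extreme}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_standardized(Z)
    w_rel = relative_fitness(w)
    n, p = Z.values.shape
    X, sq_idx, cross_idx = _quadratic_design(Z.values)
    obs = _fast_gamma_eigs(X, sq_idx, cross_idx, p, w_rel, double_quadratic)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, p))
    for b in range(n_perm):
        null[b] = _fast_gamma_eigs(
            X, sq_idx, cross_idx, p, rng.permutation(w_rel), double_quadratic
        )

    pvals = np.empty(p)
    for r in range(p):
        if two_tailed:
            count = np.sum(np.abs(null[:, r]) >= abs(obs[r]))
        elif obs[r] >= 0:
            count = np.sum(null[:, r] >= obs[r])
        else:
            count = np.sum(null[:, r] <= obs[r])
        pvals[r] = (1.0 + count) / (n_perm + 1.0)
    return obs, pvals


def mean_standardize_gradients(
    g: GradientEstimates, means, sds
) -> GradientEstimates:
    """Convert variance-standardized gradients to mean-standardized units.

    β_μ,i = β_σ,i / CV_i and γ_μ,ij = γ_σ,ij / (CV_i CV_j) with
    CV_i = sd_i / mean_i; puts selection in proportional (per-trait-mean)
    units comparable with mean-standardized P and D.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(means <= 0) or np.any(sds <= 0):
        raise ValueError("means and sds must be strictly positive")
    cv = sds / means
    if np.any(cv == 0):
        raise ValueError("zero coefficient of variation")
    outer = np.outer(cv, cv)
    return GradientEstimates(
        beta=g.beta / cv,
        beta_se=None if g.beta_se is None else g.beta_se / cv,
        gamma=g.gamma / outer,
        gamma_se=None if g.gamma_se is None else g.gamma_se / outer,
        trait_labels=g.trait_labels,
        scale_tag="mean_standardized",
        fit_stats=g.fit_stats,
        doubling_applied=g.doubling_applied,
    )


class SelectionSurface:
    """Quadratic (Lande–Arnold) fitness-surface model.

    Parameters
    ----------
    fitness : array-like
        Absolute fitness per individual (e.g. mating-success count or
        0/1 mated indicator).  Converted to relative fitness internally.
    traits : TraitMatrix or ndarray
        Phenotypes; variance-standardized internally unless already so.
    trait_labels : sequence of str, optional
        Used only when ``traits`` is a bare array.

    Examples
    --------
    >>> model = SelectionSurface(w, Z)
    >>> res = model.fit()
    >>> res.canonical().lambdas
    """

    def __init__(self, fitness, traits, trait_labels=None):
        if not isinstance(traits, TraitMatrix):
            arr = np.atleast_2d(np.asarray(traits, dtype=float))
            labels = tuple(
                trait_labels
                if trait_labels is not None
                else [f"z{i + 1}" for i in range(arr.shape[1])]
            )
            traits = TraitMatrix(
                arr, trait_labels=labels, units=("",) * arr.shape[1]
            )
        if traits.scale_tag != "variance_standardized":
            traits = variance_standardize(traits)
        self.traits = traits
        self.fitness = np.asarray(fitness, dtype=float)
        if self.fitness.shape[0] != traits.n:
            raise ValueError("fitness length does not match trait rows")
        self.w_rel = relative_fitness(self.fitness)

    def fit(self, double_quadratic: bool = True) -> "SelectionSurfaceResults":
        grads = estimate_gamma(self.traits, self.w_rel, double_quadratic)
        return SelectionSurfaceResults(self, grads)


class SelectionSurfaceResults:
    """Fitted selection surface: gradients, canonical form, tests."""

    def __init__(self, model: SelectionSurface, gradients: GradientEstimates):
        self.model = model
        self.gradients = gradients

    # convenience passthroughs
    @property
    def beta(self):
        return self.gradients.beta

    @property
    def gamma(self):
        return self.gradients.gamma

    @property
    def fit_stats(self):
        return self.gradients.fit_stats

    def canonical(self) -> CanonicalForm:
        return canonical_analysis(self.gradients)

    def eigenvalue_permutation_test(self, n_perm=1000, seed=None,
                                    two_tailed=False):
        obs, pvals = eigenvalue_permutation_test(
            self.model.traits,
            self.model.fitness,
            n_perm=n_perm,
            seed=seed,
            double_quadratic=self.gradients.doubling_applied,
            two_tailed=two_tailed,
        )
        return obs, pvals

    def mean_standardized(self, means=None, sds=None) -> GradientEstimates:
        """Gradients in mean-standardized units (defaults: the sample's)."""
        spec = self.model.traits.scaling
        if means is None:
            means = spec.reference_means
        if sds is None:
            sds = spec.reference_sds
        return mean_standardize_gradients(self.gradients, means, sds)

    def summary(self) -> str:
        g = self.gradients
        labels = g.trait_labels
        lines = ["Selection surface (variance-standardized scale)", ""]
        ls = g.fit_stats.get("linear", {})
        ns = g.fit_stats.get("nonlinear", {})
        if ls:
            lines.append(
                f"Linear model:    R2 = {ls['r2']:.3f}, "
                f"F_{ls['df'][0]},{ls['df'][1]} = {ls['F']:.3f}, "
                f"p = {ls['p']:.3f}"
            )
        if ns:
            lines.append(
                f"Quadratic model: R2 = {ns['r2']:.3f}, "
                f"F_{ns['df'][0]},{ns['df'][1]} = {ns['F']:.3f}, "
                f"p = {ns['p']:.3f}"
            )
        lines.append("")
        lines.append("trait      beta (SE)")
        for i, lab in enumerate(labels):
            lines.append(
                f"{lab:<8}  {g.beta[i]: .3f} ({g.beta_se[i]:.3f})"
            )
        lines.append("")
        lines.append("gamma (SE), lower triangle")
        for i, lab in enumerate(labels):
            cells = [
                f"{g.gamma[i, j]: .3f} ({g.gamma_se[i, j]:.3f})"
                for j in range(i + 1)
            ]
            lines.append(f"{lab:<8}  " + "  ".join(cells))
        can = self.canonical()
        lines.append("")
        lines.append("canonical axes: lambda, theta, loadings")
        for i in range(len(can.lambdas)):
            load = ", ".join(f"{x: .3f}" for x in can.m_vectors[i])
            tag = "  <- m_max" if i == can.m_max_index else ""
            lines.append(
                f"m{i + 1}: lambda = {can.lambdas[i]: .3f}, "
                f"theta = {can.thetas[i]: .3f}, [{load}]{tag}"
            )
        return "\n".join(lines)
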