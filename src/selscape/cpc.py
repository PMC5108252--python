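"""Flury common-principal-components hierarchy for comparing covariances.

Two covariance matrices can be related in nested ways: identical
(equality), identical up to a scalar (proportionality), sharing all
eigenvectors but not eigenvalues (CPC), sharing one eigenvector
(CPC(1)), or unrelated.  Each model is fitted by maximum likelihood
under a Wishart sampling model and scored against the unrelated model
with a likelihood-ratio χ² ("jump-up"); adjacent models are compared via
the difference of jump-up χ² ("model building"), with AIC counting free
parameters relative to the equality model.

The common-eigenvector rotation is found by pairwise Jacobi-style
rotations, each pair's angle solved by exact one-dimensional
minimization of the CPC log-likelihood (a monotone descent scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .matrices import CovarianceMatrix

__all__ = [
    "CPCModelFit",
    "fg_common_eigenvectors",
    "flury_hierarchy",
    "best_model",
]

MODEL_ORDER = ("equality", "proportionality", "cpc", "cpc1", "unrelated")


@dataclass
class CPCModelFit:
    """One row of the Flury-hierarchy table."""

    model: str
    chi2_step: float
    df_step: int
    chi2_jumpup: float
    df_jumpup: int
    aic: float
    p_jumpup: float
    p_step: float = np.nan


def _as_mat(S):
    return S.matrix if isinstance(S, CovarianceMatrix) else np.asarray(S, float)


def _check_spd(S_list):
    mats = []
    for S in S_list:
        M = _as_mat(S)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("covariance matrices must be symmetric")
        if np.linalg.eigvalsh(M)[0] <= 0:
            raise ValueError("covariance matrices must be positive definite")
        mats.append((M + M.T) / 2)
    return mats


def _cpc_objective_pair(theta, T_list, n_list):
    """Σ nᵢ ln(product of rotated 2×2 diagonal) for rotation angle theta."""
    c, s = np.cos(theta), np.sin(theta)
    total = 0.0
    for T, n in zip(T_list, n_list):
        d1 = c * c * T[0, 0] + 2 * c * s * T[0, 1] + s * s * T[1, 1]
        d2 = s * s * T[0, 0] - 2 * c * s * T[0, 1] + c * c * T[1, 1]
        if d1 <= 0 or d2 <= 0:
            return np.inf
        total += n * (np.log(d1) + np.log(d2))
    return total


def fg_common_eigenvectors(
    S_list, n_list, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Orthonormal rotation B maximizing the common-eigenvector likelihood.

    Minimizes Σᵢ nᵢ ln det diag(BᵀSᵢB) by sweeping over column pairs and
    solving each pair's rotation angle exactly (Brent).  Converges when
    the largest rotation angle in a sweep falls below √tol.
    """
    mats = _check_spd(S_list)
    n_list = [float(n) for n in n_list]
    p = mats[0].shape[0]
    # start from the eigenbasis of the pooled matrix
    pooled = sum(n * M for n, M in zip(n_list, mats)) / sum(n_list)
    _, B = np.linalg.eigh(pooled)
    angle_tol = np.sqrt(tol)
    for _ in range(max_iter):
        max_angle = 0.0
        for a in range(p - 1):
            for b in range(a + 1, p):
                Bp = B[:, [a, b]]
                T_list = [Bp.T @ M @ Bp for M in mats]
                f0 = _cpc_objective_pair(0.0, T_list, n_list)
                res = optimize.minimize_scalar(
                    _cpc_objective_pair,
                    bounds=(-np.pi / 4, np.pi / 4),
                    args=(T_list, n_list),
                    method="bounded",
                    options={"xatol": tol},
                )
                theta = float(res.x)
                # a flat objective (degenerate eigenvalues) gives arbitrary
                # angles: only rotate on a real improvement
                if res.fun >= f0 - 1e-12 * max(1.0, abs(f0)):
                    theta = 0.0
                if abs(theta) > 1e-14:
                    c, s = np.cos(theta), np.sin(theta)
                    R = np.array([[c, -s], [s, c]])
                    B[:, [a, b]] = Bp @ R
                max_angle = max(max_angle, abs(theta))
        if max_angle < angle_tol:
            # final orthonormalization against accumulated round-off
            U, _, Vt = np.linalg.svd(B)
            return U @ Vt
    raise RuntimeError(
        f"FG rotation did not converge in {max_iter} sweeps "
        f"(last max angle {max_angle:.2e})"
    )


def _lr_chi2(fitted_list, S_list, n_list):
    """Σ nᵢ ln(det Σ̂ᵢ / det Sᵢ): LR statistic vs the unrelated model."""
    total = 0.0
    for F, S, n in zip(fitted_list, S_list, n_list):
        total += n * (np.log(np.linalg.det(F)) - np.log(np.linalg.det(S)))
    return float(total)


def _fit_equality(mats, n_list):
    N = sum(n_list)
    Sbar = sum(n * M for n, M in zip(n_list, mats)) / N
    return [Sbar for _ in mats]


def _fit_proportionality(mats, n_list, tol=1e-12, max_iter=500):
    """ML fit of Σᵢ = ρᵢ·Σ (Flury 1986), by alternating updates."""
    N = sum(n_list)
    p = mats[0].shape[0]
    rhos = np.ones(len(mats))
    Sigma = sum(n * M for n, M in zip(n_list, mats)) / N
    for _ in range(max_iter):
        Sigma_new = sum(
            n * M / r for n, M, r in zip(n_list, mats, rhos)
        ) / N
        inv = np.linalg.inv(Sigma_new)
        rhos_new = np.array([np.trace(inv @ M) / p for M in mats])
        # fix the scale indeterminacy (rho_1 = 1)
        Sigma_new = Sigma_new * rhos_new[0]
        rhos_new = rhos_new / rhos_new[0]
        if np.max(np.abs(rhos_new - rhos)) < tol and np.max(
            np.abs(Sigma_new - Sigma)
        ) < tol * max(1.0, np.abs(Sigma).max()):
            rhos, Sigma = rhos_new, Sigma_new
            break
        rhos, Sigma = rhos_new, Sigma_new
    return [r * Sigma for r in rhos], rhos


def _fit_cpc(mats, n_list, B=None):
    if B is None:
        B = fg_common_eigenvectors(mats, n_list)
    fitted = []
    for M in mats:
        d = np.diag(B.T @ M @ B).copy()
        fitted.append(B @ np.diag(d) @ B.T)
    return fitted, B


def _cpc1_chi2_for_direction(b, mats, n_list):
    """Profile LR χ² for CPC(1) with common component b (unit vector)."""
    b = b / np.linalg.norm(b)
    p = len(b)
    # orthonormal basis of the complement of b
    Q, _ = np.linalg.qr(np.column_stack([b, np.eye(p)[:, : p - 1]]))
    Q = Q[:, 1:]
    total = 0.0
    for M, n in zip(mats, n_list):
        det_fit = (b @ M @ b) * np.linalg.det(Q.T @ M @ Q)
        total += n * (np.log(det_fit) - np.log(np.linalg.det(M)))
    return float(total)


def _fit_cpc1(mats, n_list, B=None):
    """Partial CPC with one shared component, chosen by maximum likelihood.

    Each FG column is a candidate; the best is refined by direct search
    on the sphere.  Ties (within 1e-12) break toward the candidate with
    the largest pooled eigenvalue.
    """
    if B is None:
        B = fg_common_eigenvectors(mats, n_list)
    N = sum(n_list)
    pooled = sum(n * M for n, M in zip(n_list, mats)) / N
    candidates = [B[:, j] for j in range(B.shape[1])]
    scored = []
    for j, b in enumerate(candidates):
        chi2 = _cpc1_chi2_for_direction(b, mats, n_list)
        scored.append((chi2, -float(b @ pooled @ b), j, b))
    scored.sort(key=lambda t: (round(t[0], 12), t[1]))
    _, _, _, b0 = scored[0]
    res = optimize.minimize(
        lambda v: _cpc1_chi2_for_direction(v, mats, n_list),
        b0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    b = res.x / np.linalg.norm(res.x)
    chi2 = _cpc1_chi2_for_direction(b, mats, n_list)
    return chi2, b


def flury_hierarchy(
    S1, n1, S2, n2, n_is_effective: bool = False
) -> list[CPCModelFit]:
    """Fit the full hierarchy for two groups and tabulate both procedures.

    ``n1``/``n2`` are the group sample sizes N; the Wishart effective
    sizes N−1 are used internally unless ``n_is_effective=True``.  The
    returned rows follow the order equality, proportionality, cpc, cpc1,
    unrelated; each carries the jump-up χ² (vs unrelated), the step χ²
    (vs the model below), and AIC = χ²_jumpup + 2·(free parameters
    relative to equality).
    """
    mats = _check_spd([S1, S2])
    k = 2
    p = mats[0].shape[0]
    ns = [float(n1), float(n2)]
    if not n_is_effective:
        ns = [n - 1.0 for n in ns]
    if min(ns) < p + 1:
        raise ValueError("each effective sample size must exceed p")

    df_eq = (k - 1) * p * (p + 1) // 2
    df_prop = df_eq - (k - 1)
    df_cpc = (k - 1) * p * (p - 1) // 2
    df_cpc1 = (k - 1) * (p - 1)

    chi2_eq = _lr_chi2(_fit_equality(mats, ns), mats, ns)
    fitted_prop, _ = _fit_proportionality(mats, ns)
    chi2_prop = _lr_chi2(fitted_prop, mats, ns)
    B = fg_common_eigenvectors(mats, ns)
    fitted_cpc, _ = _fit_cpc(mats, ns, B)
    chi2_cpc = _lr_chi2(fitted_cpc, mats, ns)
    chi2_cpc1, _ = _fit_cpc1(mats, ns, B)

    jump = {
        "equality": (chi2_eq, df_eq),
        "proportionality": (chi2_prop, df_prop),
        "cpc": (chi2_cpc, df_cpc),
        "cpc1": (chi2_cpc1, df_cpc1),
        "unrelated": (0.0, 0),
    }
    fits = []
    for i, model in enumerate(MODEL_ORDER):
        chi2_j, df_j = jump[model]
        if model == "unrelated":
            step_chi2, step_df, p_step = np.nan, 0, np.nan
        else:
            lower = MODEL_ORDER[i + 1]
            chi2_l, df_l = jump[lower]
            step_chi2 = chi2_j - chi2_l
            step_df = df_j - df_l
            p_step = float(stats.chi2.sf(max(step_chi2, 0.0), step_df))
        aic = chi2_j + 2.0 * (df_eq - df_j)
        p_j = float(stats.chi2.sf(chi2_j, df_j)) if df_j > 0 else np.nan
        fits.append(
            CPCModelFit(
                model=model,
                chi2_step=step_chi2,
                df_step=step_df,
                chi2_jumpup=chi2_j,
                df_jumpup=df_j,
                aic=aic,
                p_jumpup=p_j,
                p_step=p_step,
            )
        )
    return fits


def best_model(fits: list[CPCModelFit], method: str = "model_building_aic",
               alpha: float = 0.05) -> str:
    """Select the preferred model of matrix similarity.

    ``model_building_aic``: lowest AIC.  ``jump_up`` (or ``alpha``): the
    highest model in the hierarchy whose jump-up test against the
    unrelated model is not rejected at ``alpha``.
    """
    by_name = {f.model: f for f in fits}
    if set(by_name) != set(MODEL_ORDER):
        raise ValueError("fits must contain the complete hierarchy")
    if method == "model_building_aic":
        return min(fits, key=lambda f: f.aic).model
    if method in ("jump_up", "alpha"):
        for model in MODEL_ORDER[:-1]:
            f = by_name[model]
            if f.p_jumpup >= alpha:
                return model
        return "unrelated"
    raise ValueError(f"unknown method {method!r}")
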