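"""Joint estimation of the four component equations and additive prediction.

Each age group's selected component equations form a seemingly unrelated
regression (SUR) system: the same trees feed all four log-scale equations,
whose errors are correlated across components (a tree with an unusually
heavy trunk tends to carry unusually heavy branches).  Estimation is
iterated feasible generalised least squares:

1. equation-by-equation OLS for starting residuals;
2. Sigma-hat[i, j] = (1/n) * sum_t e_i(t) e_j(t);
3. GLS on the stacked system with weight Sigma-hat^-1 (x) I_n;
4. repeat 2-3 until the largest absolute coefficient change falls below a
   tolerance.

Per-equation residual variances and Baskerville correction factors are
recomputed from the converged system residuals.  Total biomass is predicted
as the exact sum of the four bias-corrected component predictions — the
additivity identity is computed, never re-fitted — so component and total
estimates can never disagree.

Two classical degenerate cases double as correctness checks: when every
equation shares one design matrix, or when Sigma-hat is diagonal, SUR
collapses to per-equation OLS (Kruskal equivalence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .candidate_models import (
    DfConvention,
    ModelSpec,
    OlsFit,
    _resolve_df,
    build_design,
    correction_factor,
    design_row,
)
from .tree_data import (
    BIOMASS_COMPONENTS,
    AgeGroup,
    Component,
    TreeRecord,
    ValidationError,
    total_biomass,
)

__all__ = [
    "SystemSpec",
    "SurFit",
    "fit_sur",
    "predict_components",
    "predict_total",
    "residual_cross_correlation",
]


@dataclass(frozen=True)
class SystemSpec:
    """The four selected component forms for one age group."""

    group: AgeGroup | None
    specs: dict[Component, ModelSpec]

    def __post_init__(self) -> None:
        missing = [c for c in BIOMASS_COMPONENTS if c not in self.specs]
        if missing:
            raise ValidationError(f"system is missing equations for {missing}")
        extra = [c for c in self.specs if c not in BIOMASS_COMPONENTS]
        if extra:
            raise ValidationError(f"system has non-component equations {extra}")


@dataclass(frozen=True)
class SurFit:
    """A jointly estimated four-equation biomass system."""

    system: SystemSpec
    params: dict[Component, np.ndarray]
    cov_params: dict[Component, np.ndarray]
    sigma_hat: np.ndarray          # 4x4 cross-equation residual covariance
    sigma2: dict[Component, float]  # per-equation df-adjusted MSE
    cf: dict[Component, float]
    residuals: dict[Component, np.ndarray]
    iterations: int
    converged: bool
    n: int

    @property
    def bse(self) -> dict[Component, np.ndarray]:
        return {c: np.sqrt(np.diag(v)) for c, v in self.cov_params.items()}


def _stack_designs(
    records: Sequence[TreeRecord], system: SystemSpec
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    Xs, ys = [], []
    for comp in BIOMASS_COMPONENTS:
        X, y = build_design(system.specs[comp], records, comp)
        Xs.append(X)
        ys.append(y)
    return Xs, ys


def _gls_solve(
    Xs: list[np.ndarray], ys: list[np.ndarray], sigma_inv: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Stacked GLS with weight Sigma^-1 (x) I, via normal-equation blocks.

    Returns per-equation coefficient vectors and the inverse normal matrix
    (the joint coefficient covariance up to the Sigma scaling already folded
    into the weights).
    """
    m = len(Xs)
    ks = [X.shape[1] for X in Xs]
    offs = np.concatenate([[0], np.cumsum(ks)])
    K = offs[-1]
    A = np.zeros((K, K))
    b = np.zeros(K)
    for i in range(m):
        for j in range(m):
            w = sigma_inv[i, j]
            if w == 0.0:
                continue
            A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] += w * (Xs[i].T @ Xs[j])
            b[offs[i]:offs[i + 1]] += w * (Xs[i].T @ ys[j])
    A_inv = np.linalg.inv(A)
    beta = A_inv @ b
    return [beta[offs[i]:offs[i + 1]] for i in range(m)], A_inv


SigmaDivisor = Literal["n", "df"]


def fit_sur(
    records: Sequence[TreeRecord],
    system: SystemSpec,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    sigma_divisor: SigmaDivisor = "n",
    diagonal_sigma: bool = False,
    ridge: float = 0.0,
    cf_df: DfConvention = "nk",
    total_as_equation: bool = False,
) -> SurFit:
    """Iterated feasible GLS for the four-equation biomass system.

    Parameters
    ----------
    records
        Trees feeding all four equations (a balanced system).  When the
        system carries a group, records are filtered to it.
    tol, max_iter
        Convergence is declared when the largest absolute coefficient change
        between iterations is below ``tol``; otherwise the fit is returned
        with ``converged=False`` and a warning after ``max_iter`` rounds.
    sigma_divisor
        ``"n"`` (maximum-likelihood convention, default — the equations have
        unequal coefficient counts, so no single df correction is exact) or
        ``"df"`` using the geometric mean sqrt((n-k_i)(n-k_j)).
    diagonal_sigma
        Zero the off-diagonal residual covariances each iteration; the fit
        then reproduces equation-by-equation OLS.
    ridge
        Optional jitter added to Sigma-hat's diagonal when it is near
        singular (off by default).
    cf_df
        Degrees-of-freedom convention for per-equation sigma^2 and CF,
        as in :func:`treeallom.candidate_models.fit_log_ols`.
    total_as_equation
        Experimental: append the arithmetic-scale total-biomass identity as
        a fifth estimated equation and solve the stacked nonlinear system by
        Gauss-Newton.  By default the total line is a deterministic
        prediction identity only, because the observed total is exactly the
        sum of observed components and contributes no information.
    """
    if system.group is not None:
        records = [r for r in records if r.group is system.group]
    records = list(records)
    n = len(records)
    Xs, ys = _stack_designs(records, system)
    max_k = max(X.shape[1] for X in Xs)
    if n <= max_k:
        raise ValidationError(
            f"need n > {max_k} observations for the largest equation, got {n}"
        )

    # Stage 1: per-equation OLS start.
    betas = [np.linalg.lstsq(X, y, rcond=None)[0] for X, y in zip(Xs, ys)]

    if total_as_equation:
        betas, sigma_hat, cov_blocks, iters, converged = _gauss_newton_with_total(
            records, Xs, ys, betas, tol=tol, max_iter=max_iter,
            sigma_divisor=sigma_divisor, ridge=ridge, cf_df=cf_df,
        )
    else:
        betas, sigma_hat, cov_blocks, iters, converged = _iterate_fgls(
            Xs, ys, betas, tol=tol, max_iter=max_iter,
            sigma_divisor=sigma_divisor, diagonal_sigma=diagonal_sigma,
            ridge=ridge,
        )
    if not converged:
        warnings.warn(
            f"SUR did not converge in {max_iter} iterations "
            f"(tol={tol}); returning last iterate",
            stacklevel=2,
        )

    params, cov_params, sigma2, cf, residuals = {}, {}, {}, {}, {}
    for idx, comp in enumerate(BIOMASS_COMPONENTS):
        resid = ys[idx] - Xs[idx] @ betas[idx]
        df = _resolve_df(n, Xs[idx].shape[1], cf_df)
        if df <= 0:
            raise ValidationError("no residual degrees of freedom for CF")
        s2 = float(resid @ resid) / df
        params[comp] = betas[idx]
        cov_params[comp] = cov_blocks[idx]
        sigma2[comp] = s2
        cf[comp] = correction_factor(s2)
        residuals[comp] = resid
    return SurFit(
        system=system,
        params=params,
        cov_params=cov_params,
        sigma_hat=sigma_hat,
        sigma2=sigma2,
        cf=cf,
        residuals=residuals,
        iterations=iters,
        converged=converged,
        n=n,
    )


def _estimate_sigma(
    E: np.ndarray,
    ks: Sequence[int],
    sigma_divisor: SigmaDivisor,
    diagonal_sigma: bool,
    ridge: float,
) -> np.ndarray:
    n = E.shape[0]
    S = E.T @ E
    if sigma_divisor == "n":
        S = S / n
    elif sigma_divisor == "df":
        d = np.array([n - k for k in ks], dtype=float)
        S = S / np.sqrt(np.outer(d, d))
    else:
        raise ValueError(f"sigma_divisor must be 'n' or 'df', got {sigma_divisor!r}")
    if diagonal_sigma:
        S = np.diag(np.diag(S))
    if ridge > 0:
        S = S + ridge * np.eye(S.shape[0])
    return S


def _invert_sigma(S: np.ndarray) -> np.ndarray:
    try:
        cond = np.linalg.cond(S)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            "cross-equation residual covariance is numerically singular; "
            "consider the ridge jitter option"
        )
    return np.linalg.inv(S)


def _iterate_fgls(
    Xs, ys, betas, *, tol, max_iter, sigma_divisor, diagonal_sigma, ridge
):
    ks = [X.shape[1] for X in Xs]
    # Exact interpolation (noise-free data): the OLS start already solves
    # every equation and Sigma-hat is numerically zero, so GLS reweighting is
    # both meaningless and singular.  Return the OLS solution as the limit.
    E0 = np.column_stack([y - X @ b for X, y, b in zip(Xs, ys, betas)])
    y_scale = max(1.0, max(float(np.max(np.abs(y))) for y in ys))
    if float(np.max(np.abs(E0))) < 1e-10 * y_scale:
        sigma_hat = _estimate_sigma(E0, ks, sigma_divisor, diagonal_sigma, ridge)
        cov_blocks = [np.zeros((k, k)) for k in ks]
        return betas, sigma_hat, cov_blocks, 0, True
    sigma_hat = None
    cov_blocks = None
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        E = np.column_stack([y - X @ b for X, y, b in zip(Xs, ys, betas)])
        sigma_hat = _estimate_sigma(E, ks, sigma_divisor, diagonal_sigma, ridge)
        sigma_inv = _invert_sigma(sigma_hat)
        new_betas, A_inv = _gls_solve(Xs, ys, sigma_inv)
        delta = max(
            float(np.max(np.abs(nb - ob))) for nb, ob in zip(new_betas, betas)
        )
        betas = new_betas
        offs = np.concatenate([[0], np.cumsum(ks)])
        cov_blocks = [
            A_inv[offs[i]:offs[i + 1], offs[i]:offs[i + 1]]
            for i in range(len(Xs))
        ]
        if delta < tol:
            converged = True
            break
    # report Sigma-hat from the final coefficients, not the last weights
    E = np.column_stack([y - X @ b for X, y, b in zip(Xs, ys, betas)])
    sigma_hat = _estimate_sigma(E, ks, sigma_divisor, diagonal_sigma, ridge)
    return betas, sigma_hat, cov_blocks, iters, converged


def _gauss_newton_with_total(
    records, Xs, ys, betas, *, tol, max_iter, sigma_divisor, ridge, cf_df
):
    """Experimental 5-equation mode: the four log equations plus the
    arithmetic-scale total identity, solved by Gauss-Newton on the stacked
    nonlinear GLS system.  The fifth equation mixes scales (kg vs log-kg);
    its residual variance enters Sigma-hat like any other equation."""
    n = len(records)
    ks = [X.shape[1] for X in Xs]
    offs = np.concatenate([[0], np.cumsum(ks)])
    K = offs[-1]
    w_total = np.array([total_biomass(r) for r in records])
    converged = False
    iters = 0
    sigma_hat5 = None
    A_inv = None
    for iters in range(1, max_iter + 1):
        # CFs from current residuals, held fixed within the iteration.
        fitted = [X @ b for X, b in zip(Xs, betas)]
        resid_log = [y - f for y, f in zip(ys, fitted)]
        cfs = []
        for i in range(4):
            df = _resolve_df(n, ks[i], cf_df)
            cfs.append(correction_factor(float(resid_log[i] @ resid_log[i]) / df))
        comp_pred = [np.exp(f) * c for f, c in zip(fitted, cfs)]
        resid_tot = w_total - sum(comp_pred)
        E = np.column_stack(resid_log + [resid_tot])
        sigma_hat5 = _estimate_sigma(E, ks + [K], sigma_divisor, False, ridge)
        sigma_inv = _invert_sigma(sigma_hat5)
        # Jacobian rows: eq i<4 linear in beta_i; eq 5 couples all equations.
        J5 = np.zeros((n, K))
        for i in range(4):
            J5[:, offs[i]:offs[i + 1]] = comp_pred[i][:, None] * Xs[i]
        Js = [None] * 5
        rs = resid_log + [resid_tot]
        A = np.zeros((K, K))
        g = np.zeros(K)

        def block(i):
            if i < 4:
                Z = np.zeros((n, K))
                Z[:, offs[i]:offs[i + 1]] = Xs[i]
                return Z
            return J5

        for i in range(5):
            Ji = block(i)
            for j in range(5):
                w = sigma_inv[i, j]
                if w == 0.0:
                    continue
                A += w * (Ji.T @ block(j))
                g += w * (Ji.T @ rs[j])
        A_inv = np.linalg.inv(A)
        step = A_inv @ g
        delta = float(np.max(np.abs(step)))
        flat = np.concatenate(betas) + step
        betas = [flat[offs[i]:offs[i + 1]] for i in range(4)]
        if delta < tol:
            converged = True
            break
    cov_blocks = [
        A_inv[offs[i]:offs[i + 1], offs[i]:offs[i + 1]] for i in range(4)
    ]
    # Report the 4x4 log-scale block for comparability with the default mode.
    return betas, sigma_hat5[:4, :4], cov_blocks, iters, converged


def predict_components(fit: SurFit, record: TreeRecord) -> dict[Component, float]:
    """Bias-corrected back-transformed prediction for each component, kg."""
    out = {}
    for comp in BIOMASS_COMPONENTS:
        spec = fit.system.specs[comp]
        x = design_row(spec, record.D, record.H, record.CR)
        out[comp] = math.exp(float(x @ fit.params[comp])) * fit.cf[comp]
    return out


def predict_total(fit: SurFit, record: TreeRecord) -> float:
    """Total biomass: exactly the sum of the component predictions."""
    return sum(predict_components(fit, record).values())


def residual_cross_correlation(fit: SurFit) -> np.ndarray:
    """Sigma-hat rescaled to unit diagonal (cross-equation correlations)."""
    d = np.sqrt(np.diag(fit.sigma_hat))
    if np.any(d <= 0):
        raise ValidationError("an equation has zero residual variance")
    corr = fit.sigma_hat / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr
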