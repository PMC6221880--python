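"""Single-variance-component mixed linear model fitted by REML.

Model: y = X beta + Z u + e with var(u) = A sigma_a^2 (A = 2K on the VanRaden
scale), var(e) = I sigma_e^2.  Writing delta = sigma_e^2 / sigma_a^2 the
phenotypic covariance is sigma_a^2 * H with H = Z A Z' + delta I, so after one
eigendecomposition of Z A Z' the restricted likelihood is a cheap 1-D function
of delta (the EMMA device): sigma_a^2 profiles out analytically and delta is
found by a log-grid scan refined with bounded scalar optimization.

Random effects for any set of levels covered by a relationship matrix --
phenotyped or not -- are predicted by the usual conditional expectation
u_hat = A Z' H^{-1} (y - X beta_hat), which coincides with the Henderson
mixed-model-equation solution on the phenotyped levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix

__all__ = [
    "VarianceComponents",
    "RemlFit",
    "BlupResult",
    "reml_fit",
    "full_loglik",
    "solve_mme",
    "predict_unphenotyped",
    "estimate_h2",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    delta: float


@dataclass
class RemlFit:
    """REML solution: variance components, fixed effects and the restricted
    log-likelihood at the optimum.

    Carries the (observed) data it was fitted to so that downstream
    prediction can rebuild the joint system without re-supplying y, X and the
    incidence map.
    """

    varcomps: VarianceComponents
    beta: np.ndarray
    logLik_restricted: float
    neg2LL: float
    identifiability_flag: bool
    n_obs: int
    q: int
    u_hat: np.ndarray = field(repr=False)
    level_ids: list = field(repr=False)
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    Z_levels: np.ndarray = field(repr=False)  # level index per observation

    @property
    def delta(self) -> float:
        return self.varcomps.delta


@dataclass
class BlupResult:
    levels: list
    u_hat: np.ndarray
    beta_hat: np.ndarray


def _as_incidence(Z_levels: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((Z_levels.size, n_levels))
    Z[np.arange(Z_levels.size), Z_levels] = 1.0
    return Z


def _check_X(X: np.ndarray, n_obs: int) -> int:
    X = np.asarray(X, dtype=float)
    q = np.linalg.matrix_rank(X)
    if q < X.shape[1]:
        raise ValueError("rank-deficient fixed effects")
    if n_obs < q + 1:
        raise ValueError(f"fewer observed phenotypes ({n_obs}) than q+1 ({q + 1})")
    return q


def _profile_reml(delta, lam, Xr, yr, n, q, logdet_XtX):
    """Restricted log-likelihood at delta, with sigma_a^2 profiled out.

    lam are eigenvalues of Z A Z', Xr/yr the eigenvector-rotated design and
    response.  Returns (logLik, beta, sigma_a2).
    """
    d = lam + delta
    Xw = Xr / d[:, None]
    XtHiX = Xr.T @ Xw
    beta = np.linalg.solve(XtHiX, Xw.T @ yr)
    r = yr - Xr @ beta
    rHr = float(np.sum(r * r / d))
    sigma_a2 = rHr / (n - q)
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return -np.inf, beta, sigma_a2
    ll = -0.5 * (
        (n - q) * (_LOG2PI + np.log(sigma_a2))
        + (n - q)
        + float(np.sum(np.log(d)))
        + logdet_XtHiX
        - logdet_XtX
    )
    return ll, beta, sigma_a2


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    A,
    Z_levels: np.ndarray | None = None,
    level_ids=None,
    delta_range: tuple = (1e-5, 1e5),
    n_grid: int = 100,
    flat_tol: float = 1e-6,
) -> RemlFit:
    """Estimate delta = sigma_e^2/sigma_a^2 by REML on a log grid plus local
    refinement, then recover sigma_a^2, beta and level BLUPs.

    Parameters
    ----------
    y : observed phenotypes (no missing entries; mask upstream).
    X : fixed-effect design, first column the intercept; must be full rank.
    A : (L, L) relationship matrix over random-effect levels on the 2K scale
        (a ``KinshipMatrix`` or bare array).
    Z_levels : integer level index per observation (identity if omitted).
    """
    if isinstance(A, KinshipMatrix):
        if level_ids is None:
            level_ids = A.ids
        A = A.values
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows do not match observed phenotypes")
    if n < 2 or np.var(y) == 0:
        raise ValueError("need at least 2 observed phenotypes with nonzero variance")
    q = _check_X(X, n)
    L = A.shape[0]
    if Z_levels is None:
        if L != n:
            raise ValueError("A dimension must equal n when Z is omitted")
        Z_levels = np.arange(n)
    Z_levels = np.asarray(Z_levels, dtype=int)
    if Z_levels.size != n or Z_levels.min() < 0 or Z_levels.max() >= L:
        raise ValueError("invalid incidence map")
    if level_ids is None:
        level_ids = list(range(L))

    Z = _as_incidence(Z_levels, L)
    M = Z @ A @ Z.T
    lam, U = np.linalg.eigh(0.5 * (M + M.T))
    lam = np.clip(lam, 0.0, None)
    Xr, yr = U.T @ X, U.T @ y
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)

    lo, hi = np.log10(delta_range[0]), np.log10(delta_range[1])
    grid = np.logspace(lo, hi, n_grid)
    lls = np.array([_profile_reml(d, lam, Xr, yr, n, q, logdet_XtX)[0] for d in grid])

    flag = False
    span = lls.max() - lls.min()
    if span < flat_tol * max(1.0, abs(lls.max())):
        # flat profile: delta not identifiable, report the smallest delta
        flag = True
        best_delta, best_ll = grid[0], lls[0]
    else:
        i = int(np.argmax(lls))
        if i in (0, n_grid - 1):
            flag = True
        blo = np.log10(grid[max(i - 1, 0)])
        bhi = np.log10(grid[min(i + 1, n_grid - 1)])
        res = minimize_scalar(
            lambda t: -_profile_reml(10.0 ** t, lam, Xr, yr, n, q, logdet_XtX)[0],
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        best_delta, best_ll = 10.0 ** res.x, -res.fun
        if best_ll < lls[i]:  # keep the grid/optimizer maximum
            best_delta, best_ll = grid[i], lls[i]

    ll, beta, sigma_a2 = _profile_reml(best_delta, lam, Xr, yr, n, q, logdet_XtX)
    # BLUPs of all levels at the optimum
    d = lam + best_delta
    r = yr - Xr @ beta
    u = A @ Z.T @ (U @ (r / d))
    return RemlFit(
        varcomps=VarianceComponents(sigma_a2, best_delta * sigma_a2, best_delta),
        beta=beta,
        logLik_restricted=ll,
        neg2LL=-2.0 * ll,
        identifiability_flag=flag,
        n_obs=n,
        q=q,
        u_hat=u,
        level_ids=list(level_ids),
        y=y,
        X=X,
        Z_levels=Z_levels,
    )


def full_loglik(y, X, beta, A, vc: VarianceComponents, Z_levels=None) -> float:
    """Full Gaussian log-likelihood of y with mean X beta and covariance
    sigma_a^2 * H, H = Z A Z' + delta I."""
    if isinstance(A, KinshipMatrix):
        A = A.values
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    n = y.size
    if vc.sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    if Z_levels is None:
        M = A
    else:
        Z = _as_incidence(np.asarray(Z_levels, dtype=int), A.shape[0])
        M = Z @ A @ Z.T
    H = 0.5 * (M + M.T) + vc.delta * np.eye(n)
    lam, U = np.linalg.eigh(H)
    if lam.min() <= 0:
        raise ValueError(f"H is not positive definite (eigenvalue {lam.min():.3e})")
    r = U.T @ (y - X @ beta)
    quad = float(np.sum(r * r / lam))
    return 0.5 * (-n * (_LOG2PI + np.log(vc.sigma_a2)) - float(np.sum(np.log(lam))) - quad / vc.sigma_a2)


def solve_mme(y, X, Z_levels, A, delta: float, ridge: float = 1e-6) -> BlupResult:
    """Solve Henderson's mixed model equations

        [X'X   X'Z          ] [beta]   [X'y]
        [Z'X   Z'Z + delta A^{-1}] [u  ] = [Z'y]

    A (= 2K) is inverted directly; if near-singular, a ridge of
    ``ridge * mean(diag(A))`` is added first (preserves solutions to ~5
    decimals while guaranteeing solvability).
    """
    level_ids = None
    if isinstance(A, KinshipMatrix):
        level_ids = A.ids
        A = A.values
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if delta <= 0:
        raise ValueError("delta must be positive")
    L = A.shape[0]
    if level_ids is None:
        level_ids = list(range(L))
    Z = _as_incidence(np.asarray(Z_levels, dtype=int), L)

    lam = np.linalg.eigvalsh(0.5 * (A + A.T))
    if lam.min() < 1e-10 * max(np.mean(np.diag(A)), 1e-300):
        A = A + ridge * np.mean(np.diag(A)) * np.eye(L)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular relationship matrix after ridge") from e

    q = X.shape[1]
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + delta * Ainv]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular mixed-model coefficient matrix") from e
    return BlupResult(levels=list(level_ids), u_hat=sol[q:], beta_hat=sol[:q])


def predict_unphenotyped(fit: RemlFit, K_full: KinshipMatrix, ref_ids=None, inf_ids=None) -> BlupResult:
    """BLUP of every level of ``K_full`` (reference and inference) from a fit
    obtained on reference phenotypes only.

    Equivalent to solving the joint mixed-model equations once with Z mapping
    only the observed phenotypes: u_hat = A Z' H^{-1} (y - X beta_hat) with
    A = 2K over all levels and H built on the phenotyped block.
    """
    pos = {v: i for i, v in enumerate(K_full.ids)}
    missing = [i for i in fit.level_ids if i not in pos]
    if inf_ids is not None:
        missing += [i for i in inf_ids if i not in pos and i not in missing]
    if missing:
        raise KeyError(f"ids absent from kinship matrix: {missing}")
    A = K_full.values
    # map each observation to its level's position in K_full
    obs_levels = np.array([pos[fit.level_ids[j]] for j in fit.Z_levels], dtype=int)
    Z = _as_incidence(obs_levels, len(K_full.ids))
    M = Z @ A @ Z.T
    H = 0.5 * (M + M.T) + fit.delta * np.eye(fit.n_obs)
    Hi_X = np.linalg.solve(H, fit.X)
    beta = np.linalg.solve(fit.X.T @ Hi_X, Hi_X.T @ fit.y)
    u = A @ Z.T @ np.linalg.solve(H, fit.y - fit.X @ beta)
    return BlupResult(levels=list(K_full.ids), u_hat=u, beta_hat=beta)


def estimate_h2(fit: RemlFit) -> float:
    """Narrow-sense heritability sigma_a^2/(sigma_a^2+sigma_e^2) = 1/(1+delta),
    valid under the 2K kinship normalization."""
    if fit.identifiability_flag:
        warnings.warn("variance ratio not uniquely identified; h2 estimate unreliable")
    return 1.0 / (1.0 + fit.delta)
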