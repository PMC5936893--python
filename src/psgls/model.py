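"""Joint phylogenetic-spatial generalized least squares.

The error covariance of the regression is a convex combination of three
components on a common unit-diagonal scale,

    V(lambda, phi) = gamma * I + lambda' * Sigma* + phi * W,

where ``Sigma*`` is the normalized phylogenetic covariance (Brownian-motion
expectation), ``W`` the spatial similarity matrix, and the weights are the
reparameterized proportions lambda' = (1 - phi) * lambda and
gamma = (1 - phi) * (1 - lambda), so gamma + lambda' + phi = 1.  The raw
weights lambda and phi are estimated by maximum likelihood over an
exhaustive grid on [0, 1]^2 and tested with likelihood-ratio tests between
the four nested models (both / lambda only / phi only / neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "CovarianceWeights",
    "GLSFit",
    "GridFitResult",
    "NotPositiveDefiniteError",
    "combine_covariance",
    "derived_weights",
    "gls_fit",
    "likelihood_ratio_test",
    "profile_grid_fit",
]

#: eigenvalue window treated as numerical noise and repaired with a ridge
_PSD_TOL = 1e-8
_RIDGE = 1e-10


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Covariance matrix is not positive definite beyond numerical noise."""


@dataclass(frozen=True)
class CovarianceWeights:
    """Raw weights (lam, phi) and the derived covariance proportions.

    Attributes
    ----------
    lam : float
        Ancestry weight in [0, 1]; 0 means no phylogenetic signal, 1 the
        full Brownian-motion expectation.
    phi : float
        Spatial-proximity weight in [0, 1].
    """

    lam: float
    phi: float

    def __post_init__(self) -> None:
        for name, val in (("lam", self.lam), ("phi", self.phi)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val!r}")

    @property
    def lam_prime(self) -> float:
        """Proportion of modelled covariance attributable to ancestry."""
        return (1.0 - self.phi) * self.lam

    @property
    def gamma(self) -> float:
        """Proportion of modelled covariance independent of ancestry and space."""
        return (1.0 - self.phi) * (1.0 - self.lam)


def derived_weights(lam: float, phi: float) -> CovarianceWeights:
    """Return the weight partition (gamma, lambda', phi) for raw (lam, phi)."""
    return CovarianceWeights(lam=float(lam), phi=float(phi))


@dataclass
class GLSFit:
    """Maximum-likelihood GLS fit at a fixed covariance structure.

    ``sigma2`` is the ML scale (residual quadratic form / n) and enters the
    log-likelihood; coefficient standard errors use the unbiased n - k
    denominator so that with V = I the fit reproduces ordinary least
    squares t statistics exactly.
    """

    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    loglik: float
    n: int
    p_values: np.ndarray
    df_resid: int


@dataclass
class GridFitResult:
    """Result of the exhaustive (lam, phi) grid search on one tree."""

    weights: CovarianceWeights
    fit: GLSFit
    surface: np.ndarray           # loglik, shape (len(lam_grid), len(phi_grid))
    lam_grid: np.ndarray
    phi_grid: np.ndarray
    mode: str
    lrt_p: dict[str, float] = field(default_factory=dict)


def combine_covariance(
    weights: CovarianceWeights,
    sigma_star: np.ndarray,
    w: np.ndarray | None,
) -> np.ndarray:
    """Mix identity, phylogenetic and spatial components into V.

    Both ``sigma_star`` and ``w`` must be unit-diagonal and in the same
    taxon order; ``w`` may be None when phi == 0.
    """
    sigma_star = np.asarray(sigma_star, dtype=float)
    n = sigma_star.shape[0]
    if sigma_star.shape != (n, n):
        raise ValueError("sigma_star must be square")
    if w is None:
        if weights.phi != 0.0:
            raise ValueError("spatial matrix required when phi > 0")
        w = np.zeros_like(sigma_star)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != sigma_star.shape:
            raise ValueError(
                f"matrix shapes differ: {sigma_star.shape} vs {w.shape}"
            )
    v = (
        weights.gamma * np.eye(n)
        + weights.lam_prime * sigma_star
        + weights.phi * w
    )
    return 0.5 * (v + v.T)


def _cholesky_with_repair(v: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of V, ridging away eigenvalues in (-tol, 0].

    Eigenvalues below -1e-8 mean a genuinely indefinite matrix and are a
    hard error; ones inside the noise window are lifted by a ridge just
    large enough to clear them (at least 1e-10).
    """
    try:
        return np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(v)[0])
        if smallest <= -_PSD_TOL:
            raise NotPositiveDefiniteError(
                f"covariance has eigenvalue {smallest:.3e} below -{_PSD_TOL:g}"
            ) from None
        ridge = _RIDGE + max(0.0, -smallest)
        try:
            return np.linalg.cholesky(v + ridge * np.eye(v.shape[0]))
        except np.linalg.LinAlgError:
            raise NotPositiveDefiniteError(
                "covariance not positive definite after ridge repair"
            ) from None


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> GLSFit:
    """Fit y = X beta + e, e ~ N(0, sigma2 * V), by maximum likelihood.

    The scale sigma2 is profiled analytically:
    beta_hat = (X' V^-1 X)^-1 X' V^-1 y, sigma2_hat = r' V^-1 r / n, and
    loglik = -n/2 log(2 pi sigma2_hat) - log|V|/2 - n/2.  Coefficient
    p-values use a t reference with n - k degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError(f"design has {X.shape[0]} rows for {n} observations")
    k = X.shape[1]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations, got {n}")

    L = _cholesky_with_repair(np.asarray(V, dtype=float))
    # whiten: solve L z = X and L u = y, so the problem becomes OLS of u on z
    z = linalg.solve_triangular(L, X, lower=True)
    u = linalg.solve_triangular(L, y, lower=True)
    xtvix = z.T @ z
    try:
        c_xx = linalg.cho_factor(xtvix)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular design (collinear columns)") from None
    beta = linalg.cho_solve(c_xx, z.T @ u)
    resid = u - z @ beta
    q = float(resid @ resid)
    sigma2 = q / n
    if sigma2 <= 0.0:
        sigma2 = np.finfo(float).tiny
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * logdet_v - 0.5 * n

    df_resid = n - k
    xtvix_inv = linalg.cho_solve(c_xx, np.eye(k))
    se = np.sqrt(np.diag(xtvix_inv) * q / df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return GLSFit(
        beta=beta,
        se=se,
        sigma2=sigma2,
        loglik=loglik,
        n=n,
        p_values=p_values,
        df_resid=df_resid,
    )


def _grid_axis(step: float) -> np.ndarray:
    cells = 1.0 / step
    if abs(cells - round(cells)) > 1e-9:
        raise ValueError(f"grid step {step} does not divide 1 exactly")
    return np.linspace(0.0, 1.0, int(round(cells)) + 1)


def _surface_batched(
    y: np.ndarray,
    X: np.ndarray,
    sigma_star: np.ndarray,
    w: np.ndarray | None,
    lam: np.ndarray,
    phi: np.ndarray,
) -> np.ndarray:
    """Profiled loglik at each (lam, phi) pair via batched Cholesky.

    Grid points whose V is not positive definite (beyond the ridge-repair
    window) get -inf; only when every point fails does the caller error.
    """
    n = y.size
    k = X.shape[1]
    gamma = (1.0 - phi) * (1.0 - lam)
    lam_p = (1.0 - phi) * lam
    eye = np.eye(n)
    w_mat = np.zeros_like(sigma_star) if w is None else w
    v = (
        gamma[:, None, None] * eye
        + lam_p[:, None, None] * sigma_star
        + phi[:, None, None] * w_mat
    )
    try:
        L = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        # at least one grid point is non-PD: fall back to a per-point loop
        out = np.empty(lam.size)
        for i in range(lam.size):
            try:
                out[i] = gls_fit(y, X, v[i]).loglik
            except (np.linalg.LinAlgError, ValueError):
                out[i] = -np.inf
        if not np.isfinite(out).any():
            raise np.linalg.LinAlgError(
                "covariance singular at every grid point"
            ) from None
        return out

    g = lam.size
    zb = np.linalg.solve(L, np.broadcast_to(X, (g, n, k)))
    ub = np.linalg.solve(L, np.broadcast_to(y[:, None], (g, n, 1)))
    xtvix = zb.transpose(0, 2, 1) @ zb
    xtviy = zb.transpose(0, 2, 1) @ ub
    beta = np.linalg.solve(xtvix, xtviy)
    resid = ub - zb @ beta
    q = np.einsum("gij,gij->g", resid, resid)
    q = np.maximum(q, np.finfo(float).tiny)
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    return -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n


_MODES = ("both", "lambda_only", "phi_only", "neither")


def profile_grid_fit(
    y: np.ndarray,
    X: np.ndarray,
    sigma_star: np.ndarray,
    w: np.ndarray | None,
    step: float = 0.02,
    mode: str = "both",
) -> GridFitResult:
    """Exhaustive ML grid search over the active covariance weights.

    Inactive parameters are pinned at 0 (``neither`` evaluates the single
    point lam = phi = 0, i.e. ordinary least squares).  On exact loglik
    ties the smallest lam, then the smallest phi, wins — parsimony toward
    the null.  The likelihood-ratio p-values in ``lrt_p`` compare the
    maximized surface against the nested sub-models, read off the same
    surface: ``lambda`` and ``phi`` free one parameter (chi-square df 1),
    ``joint`` frees both (df 2).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sigma_star = np.asarray(sigma_star, dtype=float)
    if w is not None:
        w = np.asarray(w, dtype=float)

    axis = _grid_axis(step)
    zero = np.zeros(1)
    lam_grid = axis if mode in ("both", "lambda_only") else zero
    phi_grid = axis if mode in ("both", "phi_only") else zero
    lam_flat = np.repeat(lam_grid, phi_grid.size)
    phi_flat = np.tile(phi_grid, lam_grid.size)

    ll = _surface_batched(y, X, sigma_star, w, lam_flat, phi_flat)
    surface = ll.reshape(lam_grid.size, phi_grid.size)

    best = np.flatnonzero(ll == np.nanmax(ll))
    # ties: flattened order is lam-major then phi ascending, so take first
    i_best = int(best[0])
    weights = CovarianceWeights(lam=float(lam_flat[i_best]), phi=float(phi_flat[i_best]))
    fit = gls_fit(y, X, combine_covariance(weights, sigma_star, w))

    lrt_p: dict[str, float] = {}
    ll_max = fit.loglik
    if mode == "both":
        ll_lam_only = float(np.max(surface[:, 0]))   # phi pinned at 0
        ll_phi_only = float(np.max(surface[0, :]))   # lam pinned at 0
        ll_neither = float(surface[0, 0])
        lrt_p["lambda"] = _lrt_p(ll_max, ll_phi_only, 1)
        lrt_p["phi"] = _lrt_p(ll_max, ll_lam_only, 1)
        lrt_p["joint"] = _lrt_p(ll_max, ll_neither, 2)
    elif mode == "lambda_only":
        lrt_p["lambda"] = _lrt_p(ll_max, float(surface[0, 0]), 1)
    elif mode == "phi_only":
        lrt_p["phi"] = _lrt_p(ll_max, float(surface[0, 0]), 1)

    return GridFitResult(
        weights=weights,
        fit=fit,
        surface=surface,
        lam_grid=lam_grid,
        phi_grid=phi_grid,
        mode=mode,
        lrt_p=lrt_p,
    )


def _lrt_p(ll_full: float, ll_reduced: float, df: int) -> float:
    stat = 2.0 * (ll_full - ll_reduced)
    return float(stats.chi2.sf(max(stat, 0.0), df))


def likelihood_ratio_test(
    full: GLSFit | float,
    reduced: GLSFit | float,
    df: int,
    boundary_mixture: bool = False,
) -> float:
    """Upper-tail chi-square p-value for 2 * (loglik_full - loglik_reduced).

    With ``boundary_mixture`` (df = 1 only) the reference is the
    0.5*chi2_0 + 0.5*chi2_1 mixture appropriate when the null pins the
    parameter at the boundary of [0, 1]; the plain chi-square default is
    conservative there.
    """
    ll_full = full.loglik if isinstance(full, GLSFit) else float(full)
    ll_red = reduced.loglik if isinstance(reduced, GLSFit) else float(reduced)
    if df < 1:
        raise ValueError("df must be a positive integer")
    stat = 2.0 * (ll_full - ll_red)
    if stat < -1e-8:
        raise ValueError(
            f"full model loglik {ll_full} below reduced {ll_red}: not nested"
        )
    stat = max(stat, 0.0)
    if boundary_mixture:
        if df != 1:
            raise ValueError("boundary mixture reference implemented for df=1")
        return 1.0 if stat == 0.0 else float(0.5 * stats.chi2.sf(stat, 1))
    return float(stats.chi2.sf(stat, df))
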