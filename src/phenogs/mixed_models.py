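"""Mixed-model machinery for genomic prediction.

Four model families are provided, mirroring the standard toolkit for
marker-based prediction with secondary phenotypes:

1. univariate GBLUP / rrBLUP (markers only),
2. ordinary least squares on spectral indices only,
3. GBLUP with spectral indices as fixed covariates,
4. multi-trait GBLUP with unstructured genetic (H) and residual (R)
   trait covariance, fitted by EM-REML, with conditional prediction so
   that lines observed only for secondary traits still contribute — and
   receive — information.

Single-trait variance components are estimated by profiled REML on the
spectrum of the relationship matrix: after rotating into the eigenbasis
of the projected kinship, the restricted likelihood is a smooth 1-D
function of the variance ratio delta = sigma2_e / sigma2_a, maximized by
a coarse grid plus bounded Brent refinement.

The multi-trait EM runs in the eigenbasis of G, where the mixed-model
equations become an arrow matrix (one t x t block per eigenvalue plus a
t x t fixed-effect block), giving O(n t^3) per-iteration cost after a
single O(n^3) eigendecomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

LOG_DELTA_BOUNDS = (-10.0, 10.0)
BRENT_TOL = 1e-8


# ---------------------------------------------------------------------------
# variance-component containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Single-trait REML estimates.

    ``sigma2_a`` is the genetic variance on the scale of the supplied
    relationship matrix; when the model is fitted with marker incidence Z
    and K = ZZ', it coincides with the marker-effect variance sigma2_u.
    ``lam`` is the ridge parameter sigma2_e / sigma2_a.
    """

    sigma2_a: float
    sigma2_e: float
    loglik: float
    at_boundary: bool = False

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def delta(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class MultiTraitVC:
    """Unstructured genetic (H) and residual (R) trait covariance."""

    H: np.ndarray
    R: np.ndarray
    traits: list
    converged: bool
    n_iter: int
    loglik_path: np.ndarray

    def genetic_correlation(self, a=0, b=1) -> tuple[float, bool]:
        """r_G between two traits, clamped to [-1, 1] with a flag."""
        if isinstance(a, str):
            a = self.traits.index(a)
        if isinstance(b, str):
            b = self.traits.index(b)
        denom = np.sqrt(self.H[a, a] * self.H[b, b])
        if denom <= 0:
            raise ValueError("zero genetic variance: r_G undefined")
        r = self.H[a, b] / denom
        clamped = abs(r) > 1.0
        return float(np.clip(r, -1.0, 1.0)), clamped


# ---------------------------------------------------------------------------
# single-trait REML (spectral / profiled likelihood)
# ---------------------------------------------------------------------------

def _design_or_intercept(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_full_rank(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns from the pivoted QR diagonal
        _, Rq, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rq))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        dep = piv[rank:]
        labels = [names[j] if names is not None else j for j in dep]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {labels}")


def reml_single_trait(
    y,
    K: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    X=None,
    grid_size: int = 64,
) -> VarianceComponents:
    """Profiled REML for y = X beta + g + e with g ~ N(0, K sigma2_a).

    Either the relationship matrix ``K`` or a marker incidence ``Z`` (in
    which case K = ZZ') must be supplied.  The restricted likelihood is
    profiled down to the ratio delta = sigma2_e/sigma2_a and maximized by
    a coarse log-scale grid followed by bounded Brent refinement, so the
    optimum is never worse than the best grid point.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError(f"need n >= 10 observations for REML, got {n}")
    if K is None:
        if Z is None:
            raise ValueError("supply K or Z")
        Z = np.asarray(Z, dtype=float)
        K = Z @ Z.T
    K = np.asarray(K, dtype=float)
    X = _design_or_intercept(X, n)
    _check_full_rank(X)
    p = X.shape[1]
    q = n - p

    # REML on error contrasts: rotate into an orthonormal basis of the
    # orthogonal complement of span(X), then eigendecompose the rotated
    # kinship.  (Projecting K with S = I - X(X'X)^-1 X' and keeping the
    # top n-p eigenvectors is not safe when K is rank deficient: the
    # zero eigenspace of SKS then mixes fixed-effect directions with
    # genuine error contrasts.)
    Qfull, _ = np.linalg.qr(X, mode="complete")
    Q2 = Qfull[:, p:]
    A = Q2.T @ K @ Q2
    A = (A + A.T) / 2.0
    w, V = np.linalg.eigh(A)
    xi = np.clip(w, 0.0, None)
    eta = V.T @ (Q2.T @ y)
    eta2 = eta ** 2

    if eta2.sum() <= 1e-20 * max(1.0, float((y ** 2).sum())):
        raise ValueError("response has zero residual variation after projection")

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = xi + d
        ss = (eta2 / denom).sum()
        ll = 0.5 * (
            q * (np.log(q / (2 * np.pi)) - 1.0 - np.log(ss))
            - np.log(denom).sum()
        )
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite restricted likelihood at log(delta)={log_delta:.3f} "
                f"(ss={ss:.3e}); check the response and kinship for degeneracy"
            )
        return -ll

    lo, hi = LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, grid_size)
    grid_vals = np.array([neg_restricted_ll(g) for g in grid])
    j = int(grid_vals.argmin())
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, grid_size - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(a, b), method="bounded",
        options={"xatol": BRENT_TOL},
    )
    log_delta = res.x if res.fun <= grid_vals[j] else grid[j]
    delta = float(np.exp(log_delta))

    sigma2_a = float((eta2 / (xi + delta)).sum() / q)
    sigma2_e = delta * sigma2_a
    at_boundary = bool(log_delta <= lo + 1e-6 or log_delta >= hi - 1e-6)
    if at_boundary:
        logger.warning(
            "REML variance ratio at search boundary (log delta = %.2f): "
            "estimate flagged, not errored", log_delta,
        )
    return VarianceComponents(
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        loglik=float(-neg_restricted_ll(log_delta)),
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# rrBLUP closed form
# ---------------------------------------------------------------------------

def solve_rrblup(y, Z, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-regression BLUP marker effects u = Z'(ZZ' + lam I)^-1 (y - ybar).

    Returns ``(u, gebv)`` with GEBV = Z u for the training lines.  GEBVs
    for any other line follow by multiplying its (identically centered)
    marker row with ``u``.
    """
    if lam <= 0:
        raise ValueError(f"ridge parameter must be positive, got {lam}")
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    yc = y - y.mean()
    n = y.size
    A = Z @ Z.T + lam * np.eye(n)
    u = Z.T @ np.linalg.solve(A, yc)
    return u, Z @ u


# ---------------------------------------------------------------------------
# GBLUP fits (univariate and with fixed covariates)
# ---------------------------------------------------------------------------

@dataclass
class GBLUPFit:
    """A fitted (covariate-)GBLUP model, ready for prediction."""

    vc: VarianceComponents
    beta: np.ndarray
    alpha: np.ndarray           # (K_tt + delta I)^-1 (y - X beta)
    gebv_train: np.ndarray
    coef_names: list = field(default_factory=list)

    def predict(self, K_cross: np.ndarray, X_new=None, include_fixed: bool = False):
        """GEBV for new lines from their kinship rows to the training set.

        ``include_fixed`` adds x' beta (used by covariate models when the
        new lines' index values are observed).
        """
        g = np.asarray(K_cross, dtype=float) @ self.alpha
        if include_fixed:
            if X_new is None:
                raise ValueError("include_fixed=True requires X_new")
            X_new = np.asarray(X_new, dtype=float)
            if X_new.ndim == 1:
                X_new = X_new[:, None]
            if X_new.shape[1] == self.beta.size - 1:
                # bare covariates: prepend the intercept column
                X_new = np.column_stack([np.ones(X_new.shape[0]), X_new])
            g = g + X_new @ self.beta
        return g


def fit_gblup(y, K, X=None, coef_names=None) -> GBLUPFit:
    """REML + BLUP for y = X beta + g + e, g ~ N(0, K sigma2_a)."""
    y = np.asarray(y, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    Xd = _design_or_intercept(X, y.size)
    _check_full_rank(Xd, coef_names)
    vc = reml_single_trait(y, K=K, X=Xd)
    delta = vc.delta
    Vs = K + delta * np.eye(y.size)          # V / sigma2_a
    Vinv_X = np.linalg.solve(Vs, Xd)
    Vinv_y = np.linalg.solve(Vs, y)
    beta = np.linalg.solve(Xd.T @ Vinv_X, Xd.T @ Vinv_y)
    alpha = np.linalg.solve(Vs, y - Xd @ beta)
    gebv = K @ alpha
    return GBLUPFit(
        vc=vc, beta=beta, alpha=alpha, gebv_train=gebv,
        coef_names=list(coef_names) if coef_names else [],
    )


def fit_covariate_gs(y, X_sri, K, sri_names=None) -> GBLUPFit:
    """GBLUP with spectral indices (or any covariates) as fixed effects.

    The fixed design is [1 | X_sri]; collinear index columns raise with
    the offending names.  Prediction for a new line is x' beta + g_hat
    via :meth:`GBLUPFit.predict`.
    """
    X_sri = np.asarray(X_sri, dtype=float)
    if X_sri.ndim == 1:
        X_sri = X_sri[:, None]
    names = ["intercept"] + (
        list(sri_names) if sri_names is not None
        else [f"sri{j}" for j in range(X_sri.shape[1])]
    )
    X = np.column_stack([np.ones(len(X_sri)), X_sri])
    return fit_gblup(y, K, X=X, coef_names=names)


# ---------------------------------------------------------------------------
# index-only ordinary least squares
# ---------------------------------------------------------------------------

@dataclass
class SRIRegression:
    coef: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[:, None]
        return self.coef.iloc[0] + X_new @ self.coef.iloc[1:].to_numpy()


def fit_sri_regression(y, X_sri, sri_names=None) -> SRIRegression:
    """OLS of the trait on spectral indices alone (no markers)."""
    y = np.asarray(y, dtype=float).ravel()
    X_sri = np.asarray(X_sri, dtype=float)
    if X_sri.ndim == 1:
        X_sri = X_sri[:, None]
    if y.size <= X_sri.shape[1] + 1:
        raise ValueError(
            f"need n > number of indices + 1: n={y.size}, p={X_sri.shape[1]}"
        )
    names = ["intercept"] + (
        list(sri_names) if sri_names is not None
        else [f"sri{j}" for j in range(X_sri.shape[1])]
    )
    X = np.column_stack([np.ones(y.size), X_sri])
    _check_full_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return SRIRegression(
        coef=pd.Series(coef, index=names), fitted=fitted, residuals=y - fitted
    )


# ---------------------------------------------------------------------------
# multi-trait GBLUP: EM-REML + conditional prediction
# ---------------------------------------------------------------------------

def _clip_psd(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    if w.min() >= floor:
        return (M + M.T) / 2.0
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def _mt_restricted_ll(Ystar, c, d, H, R) -> float:
    """REML log-likelihood (up to a constant) in the eigenbasis of G."""
    n, t = Ystar.shape
    Sig = d[:, None, None] * H[None] + R[None]              # (n, t, t)
    Sinv = np.linalg.inv(Sig)
    sign, logdet = np.linalg.slogdet(Sig)
    XtVX = np.einsum("i,ijk->jk", c ** 2, Sinv)
    rhs = np.einsum("i,ijk,ik->j", c, Sinv, Ystar)
    beta = np.linalg.solve(XtVX, rhs)
    resid = Ystar - c[:, None] * beta[None, :]
    quad = np.einsum("ij,ijk,ik->", resid, Sinv, resid)
    s2, ld2 = np.linalg.slogdet(XtVX)
    return float(-0.5 * (logdet.sum() + ld2 + quad))


def fit_multitrait_em(
    Y: np.ndarray,
    G: np.ndarray,
    traits=None,
    max_iter: int = 500,
    tol: float = 1e-6,
    eig_floor: float = 1e-8,
) -> MultiTraitVC:
    """EM-REML for the multi-trait GBLUP on complete records.

    ``Y`` is n x t with no missing entries; the model per trait stack is
    y = (I_t x 1_n) mu + g + e with g ~ N(0, H x G) and e ~ N(0, R x I).
    The MME-inverse EM updates are evaluated in the eigenbasis of G.
    """
    Y = np.asarray(Y, dtype=float)
    n, t = Y.shape
    if np.isnan(Y).any():
        raise ValueError("EM estimation requires complete records")
    if t < 2:
        raise ValueError("need >= 2 traits; use reml_single_trait for one")
    sd = Y.std(axis=0)
    if (sd <= 0).any():
        bad = [i for i, s in enumerate(sd) if s <= 0]
        raise ValueError(f"trait(s) with zero variance at columns {bad}")

    d, U = np.linalg.eigh((G + G.T) / 2.0)
    d = np.clip(d, eig_floor, None)
    c = U.T @ np.ones(n)
    Ystar = U.T @ Y

    S0 = np.cov(Y, rowvar=False)
    if t == 1:
        S0 = np.atleast_2d(S0)
    H = _clip_psd(S0 / 2.0)
    R = _clip_psd(S0 / 2.0)

    lls = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Hi = np.linalg.inv(H)
        Ri = np.linalg.inv(R)
        D = Ri[None] + Hi[None] / d[:, None, None]          # (n, t, t)
        Dinv = np.linalg.inv(D)
        F = Dinv @ Ri[None]                                  # D^-1 R^-1
        E = Ri[None] @ F                                     # R^-1 D^-1 R^-1
        c2 = c ** 2
        A = c2.sum() * Ri
        Schur = A - np.einsum("i,ijk->jk", c2, E)
        rhs = np.einsum("i,jk,ik->j", c, Ri, Ystar) - np.einsum(
            "i,ijk,ik->j", c, E, Ystar
        )
        beta = np.linalg.solve(Schur, rhs)
        Sinv = np.linalg.inv(Schur)

        resid_fixed = Ystar - c[:, None] * beta[None, :]
        g = np.einsum("ijk,ik->ij", F, resid_fixed)          # BLUP in eigenbasis

        FS = F @ Sinv[None]                                  # (n, t, t)
        Cgg = Dinv + c2[:, None, None] * (FS @ np.transpose(F, (0, 2, 1)))
        cross = c2[:, None, None] * (Sinv[None] @ np.transpose(F, (0, 2, 1)))
        M = (
            c2[:, None, None] * Sinv[None]
            - cross
            - np.transpose(cross, (0, 2, 1))
            + Cgg
        )

        lls.append(_mt_restricted_ll(Ystar, c, d, H, R))

        ghat_outer = np.einsum("ij,ik->ijk", g, g)
        H_new = ((ghat_outer + Cgg) / d[:, None, None]).sum(axis=0) / n
        ehat = resid_fixed - g
        R_new = (np.einsum("ij,ik->ijk", ehat, ehat) + M).sum(axis=0) / n

        H = _clip_psd(H_new, eig_floor)
        R = _clip_psd(R_new, eig_floor)

        if it > 1:
            rel = abs(lls[-1] - lls[-2]) / (abs(lls[-2]) + 1.0)
            if rel < tol:
                converged = True
                break
    if not converged:
        logger.warning(
            "multi-trait EM-REML did not converge in %d iterations "
            "(last relative change above %g); returning last iterate",
            max_iter, tol,
        )
    lls.append(_mt_restricted_ll(Ystar, c, d, H, R))
    trait_names = list(traits) if traits is not None else list(range(t))
    return MultiTraitVC(
        H=H, R=R, traits=trait_names, converged=converged,
        n_iter=it, loglik_path=np.asarray(lls),
    )


def conditional_multitrait_blup(
    Y: np.ndarray,
    G: np.ndarray,
    H: np.ndarray,
    R: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP genetic values for every line x trait given observed cells.

    ``Y`` may contain NaN; a line observed only for secondary traits
    still contributes those records, which is what transfers
    secondary-trait information to the prediction of its primary trait.
    Returns ``(gebv, beta)`` with gebv of shape (n_lines, n_traits).
    """
    Y = np.asarray(Y, dtype=float)
    n, t = Y.shape
    obs = np.argwhere(~np.isnan(Y))
    if obs.size == 0:
        raise ValueError("no observed records")
    ln, tr = obs[:, 0], obs[:, 1]
    y_obs = Y[ln, tr]

    V = H[np.ix_(tr, tr)] * G[np.ix_(ln, ln)] + R[np.ix_(tr, tr)] * (
        ln[:, None] == ln[None, :]
    )
    # intercepts only for traits that actually have observations
    obs_traits = np.unique(tr)
    X = np.zeros((len(y_obs), len(obs_traits)))
    for col, j in enumerate(obs_traits):
        X[tr == j, col] = 1.0

    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y_obs)
    beta_obs = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    beta = np.zeros(t)
    beta[obs_traits] = beta_obs
    alpha = np.linalg.solve(V, y_obs - X @ beta_obs)

    gebv = np.empty((n, t))
    for j in range(t):
        weights = H[j, tr] * alpha
        gebv[:, j] = G[:, ln] @ weights
    return gebv, beta


@dataclass
class MultiTraitFit:
    vc: MultiTraitVC
    beta: np.ndarray
    gebv: pd.DataFrame
    n_train: int


def fit_multitrait_gs(
    Y: pd.DataFrame,
    G: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_obs_per_trait: int = 30,
) -> MultiTraitFit:
    """Multi-trait GBLUP: EM-REML on complete records, conditional BLUP for all.

    ``Y`` is a line x trait DataFrame aligned with ``G``; NaN marks
    missing records (e.g. the primary trait of unharvested lines).  H and
    R are estimated on lines with complete records only; every line then
    receives a BLUP genetic value per trait from the full multi-trait
    system including partially observed lines.

    With a single trait the fit reduces exactly to the univariate
    spectral-REML path.
    """
    traits = list(Y.columns)
    Yv = Y.to_numpy(dtype=float)
    n, t = Yv.shape
    if G.shape != (n, n):
        raise ValueError(f"G shape {G.shape} does not match {n} lines")
    n_obs = (~np.isnan(Yv)).sum(axis=0)
    low = [traits[j] for j in range(t) if n_obs[j] < min_obs_per_trait]
    if low:
        raise ValueError(
            f"trait(s) observed on fewer than {min_obs_per_trait} lines: {low}"
        )

    if t == 1:
        mask = ~np.isnan(Yv[:, 0])
        fit = fit_gblup(Yv[mask, 0], G[np.ix_(mask, mask)])
        gebv = fit.predict(G[:, mask])
        vc = MultiTraitVC(
            H=np.array([[fit.vc.sigma2_a]]),
            R=np.array([[fit.vc.sigma2_e]]),
            traits=traits, converged=True, n_iter=0,
            loglik_path=np.array([fit.vc.loglik]),
        )
        return MultiTraitFit(
            vc=vc, beta=fit.beta,
            gebv=pd.DataFrame(gebv[:, None], index=Y.index, columns=traits),
            n_train=int(mask.sum()),
        )

    complete = ~np.isnan(Yv).any(axis=1)
    if complete.sum() < max(min_obs_per_trait, t + 2):
        raise ValueError(
            f"only {int(complete.sum())} lines with complete records; "
            "too few to estimate H and R"
        )
    vc = fit_multitrait_em(
        Yv[complete], G[np.ix_(complete, complete)], traits=traits,
        max_iter=max_iter, tol=tol,
    )
    gebv, beta = conditional_multitrait_blup(Yv, G, vc.H, vc.R)
    return MultiTraitFit(
        vc=vc, beta=beta,
        gebv=pd.DataFrame(gebv, index=Y.index, columns=traits),
        n_train=int(complete.sum()),
    )
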