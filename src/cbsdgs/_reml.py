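"""Restricted maximum likelihood (REML) machinery.

Three flavours are used throughout the package:

* :func:`reml_independent` — several independent random effects with identity
  covariance (trial-design models: clone, block, range).  Fitted by profiling
  the residual variance out of the restricted likelihood and optimising the
  variance ratios via Henderson's mixed-model equations.
* :func:`reml_kernel` — a single random effect with an arbitrary covariance
  kernel (GRM or Gaussian kernel).  Fitted by the spectral (eigen-rotation)
  trick, leaving a one-dimensional profile likelihood in the variance ratio.
* :func:`reml_multikernel` — several covariance kernels each with its own
  variance component, fitted by quasi-Newton optimisation of the restricted
  likelihood with analytic gradients.

All three return the variance-component estimates together with BLUEs of the
fixed effects and enough by-products to form BLUPs and prediction error
variances downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def drop_aliased_columns(X: np.ndarray, names: list[str] | None = None,
                         tol: float = 1e-10) -> tuple[np.ndarray, list[int]]:
    """Return ``X`` with linearly dependent columns removed (rank-revealing QR).

    A warning is logged naming (or indexing) the dropped columns.
    """
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * (diag[0] if diag.size else 1.0)))
    keep = sorted(piv[:rank])
    if rank < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        labels = [names[j] if names else str(j) for j in dropped]
        logger.warning("dropping aliased fixed-effect columns: %s", labels)
    return X[:, keep], keep


@dataclass
class IndependentREMLFit:
    """Result of a multi-term independent-random-effects REML fit."""

    varcomps: dict[str, float]          # term -> sigma^2 (includes "residual")
    beta: np.ndarray                    # fixed-effect BLUEs
    blups: dict[str, np.ndarray]        # term -> BLUP vector
    pevs: dict[str, np.ndarray]         # term -> prediction error variances
    loglik: float                       # restricted log-likelihood
    n_obs: int
    n_fixed: int
    converged: bool = True
    history: list[float] = field(default_factory=list)


def _neg2reml_independent(loglam, XtX, XtZ, ZtZ, Xty, Zty, yty, sizes, n, p):
    """-2 * restricted log-likelihood (profiled over sigma_e^2), up to a constant.

    ``loglam`` holds log variance ratios lambda_i = sigma_i^2 / sigma_e^2,
    one per random term.  Uses the identity
    log|H| + log|X'H^-1 X| = log|D| + log|C| with C the MME coefficient matrix.
    """
    lam = np.exp(loglam)
    dinv = np.concatenate([np.full(q, 1.0 / l) for q, l in zip(sizes, lam)])
    q_tot = dinv.size
    C = np.empty((p + q_tot, p + q_tot))
    C[:p, :p] = XtX
    C[:p, p:] = XtZ
    C[p:, :p] = XtZ.T
    C[p:, p:] = ZtZ + np.diag(dinv)
    rhs = np.concatenate([Xty, Zty])
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError:
        return np.inf, None, None
    theta = linalg.cho_solve(cf, rhs)
    ypy = yty - float(theta @ rhs)
    ypy = max(ypy, 1e-300)
    sigma_e2 = ypy / (n - p)
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    logdetD = float(np.sum(sizes * loglam))
    neg2 = (n - p) * np.log(sigma_e2) + logdetD + logdetC
    return neg2, theta, sigma_e2


def reml_independent(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
                     term_names: list[str] | None = None,
                     tol: float = 1e-10) -> IndependentREMLFit:
    """Fit ``y = X b + sum_i Z_i u_i + e`` with ``u_i ~ N(0, I sigma_i^2)`` by REML.

    Variance ratios are profiled against the residual variance and optimised
    on the log scale (Nelder-Mead polish after L-BFGS-B), which keeps every
    variance boxed at >= 0 and reproduces the balanced-design ANOVA estimators
    to optimiser precision.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n = y.size
    X, _ = drop_aliased_columns(X)
    p = X.shape[1]
    if term_names is None:
        term_names = [f"u{i}" for i in range(len(Z_list))]
    if n - p < 2:
        raise ValueError("not enough residual degrees of freedom")

    # Degenerate: constant response -> every component is zero.
    if np.var(y) < 1e-30:
        vc = {t: 0.0 for t in term_names}
        vc["residual"] = 0.0
        return IndependentREMLFit(
            varcomps=vc, beta=np.linalg.lstsq(X, y, rcond=None)[0],
            blups={t: np.zeros(Z.shape[1]) for t, Z in zip(term_names, Z_list)},
            pevs={t: np.zeros(Z.shape[1]) for t, Z in zip(term_names, Z_list)},
            loglik=0.0, n_obs=n, n_fixed=p)

    Z = np.hstack(Z_list)
    sizes = np.array([Zi.shape[1] for Zi in Z_list])
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)
    history: list[float] = []

    def objective(loglam):
        val = _neg2reml_independent(np.clip(loglam, -25, 25), XtX, XtZ, ZtZ,
                                    Xty, Zty, yty, sizes, n, p)[0]
        history.append(-0.5 * (val + (n - p) * (1.0 + _LOG2PI)))
        return val

    k = len(Z_list)
    # Keep the function-evaluation budget bounded: each evaluation costs a
    # Cholesky of the (p + q) mixed-model equations.
    big = (p + int(sizes.sum())) > 600
    starts = ([0.0] * k,) if big else ([0.0] * k, [-3.0] * k, [2.0] * k)
    best = None
    for start in starts:
        res = optimize.minimize(objective, np.array(start), method="L-BFGS-B",
                                bounds=[(-25, 25)] * k,
                                options={"ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    # Derivative-free polish for tight convergence near the optimum.
    res = optimize.minimize(objective, best.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-13,
                                     "maxfev": 200 * k if big else 2000})
    if res.fun > best.fun:
        res = best
    loglam = np.clip(res.x, -25, 25)
    neg2, theta, sigma_e2 = _neg2reml_independent(
        loglam, XtX, XtZ, ZtZ, Xty, Zty, yty, sizes, n, p)
    if not np.isfinite(neg2):
        raise RuntimeError("REML did not converge (singular mixed-model equations)")

    lam = np.exp(loglam)
    # Treat ratios at the lower box as zero variances.
    lam = np.where(lam < 1e-9, 0.0, lam)
    varcomps = {t: float(l * sigma_e2) for t, l in zip(term_names, lam)}
    varcomps["residual"] = float(sigma_e2)

    beta = theta[:p]
    # PEVs from the inverse MME coefficient matrix (sigma_e^2 * C^-1 block).
    dinv = np.concatenate([np.full(q, 1.0 / max(l, 1e-12))
                           for q, l in zip(sizes, np.exp(loglam))])
    q_tot = dinv.size
    C = np.empty((p + q_tot, p + q_tot))
    C[:p, :p] = XtX
    C[:p, p:] = XtZ
    C[p:, :p] = XtZ.T
    C[p:, p:] = ZtZ + np.diag(dinv)
    Cinv = linalg.inv(C)
    blups, pevs = {}, {}
    off = p
    for t, q, l in zip(term_names, sizes, lam):
        u = theta[off:off + q]
        pev = sigma_e2 * np.diag(Cinv)[off:off + q]
        if l == 0.0:
            u = np.zeros(q)
            pev = np.zeros(q)
        blups[t] = u
        # PEV is bounded by the prior variance of the effect.
        pevs[t] = np.minimum(np.maximum(pev, 0.0), max(l * sigma_e2, 0.0))
        off += q

    loglik = -0.5 * (neg2 + (n - p) * (1.0 + _LOG2PI))
    return IndependentREMLFit(varcomps=varcomps, beta=beta, blups=blups,
                              pevs=pevs, loglik=loglik, n_obs=n, n_fixed=p,
                              history=history)


@dataclass
class KernelREMLFit:
    """Single-kernel mixed model fitted by eigen-rotation REML."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    loglik: float
    h2: float
    n_obs: int
    # Spectral by-products needed for BLUP / GWAS rotations.
    eigvals: np.ndarray
    eigvecs: np.ndarray


def bend_psd(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues of a nearly-PSD matrix (with a warning)."""
    K = 0.5 * (K + K.T)
    s, U = np.linalg.eigh(K)
    floor = -tol * max(1.0, float(np.abs(s).max()))
    if s.min() < floor:
        warnings.warn("kernel is not PSD; bending negative eigenvalues to zero")
        s = np.clip(s, 0.0, None)
        return (U * s) @ U.T
    return K


def reml_kernel(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                n_grid: int = 64) -> KernelREMLFit:
    """REML fit of ``y = X b + g + e`` with ``g ~ N(0, K sigma_g^2)``.

    One eigendecomposition of ``K`` reduces the restricted likelihood to a
    1-D profile in ``delta = sigma_e^2 / sigma_g^2``, scanned on a log grid
    and refined by bounded minimisation.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    X, _ = drop_aliased_columns(X)
    n, p = X.shape
    K = 0.5 * (np.asarray(K, float) + np.asarray(K, float).T)
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg2(logdelta):
        d = s + np.exp(logdelta)
        Xd = Xt / d[:, None]
        XtDX = Xt.T @ Xd
        try:
            cf = linalg.cho_factor(XtDX)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cf, Xd.T @ yt)
        r = yt - Xt @ beta
        ypy = float(np.sum(r * r / d))
        if ypy <= 0:
            return np.inf
        sg2 = ypy / (n - p)
        return ((n - p) * np.log(sg2) + float(np.sum(np.log(d)))
                + 2.0 * float(np.sum(np.log(np.diag(cf[0])))))

    grid = np.linspace(-14.0, 14.0, n_grid)
    vals = np.array([neg2(g) for g in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(neg2, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    logdelta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = np.exp(logdelta)

    d = s + delta
    Xd = Xt / d[:, None]
    XtDX = Xt.T @ Xd
    beta = linalg.solve(XtDX, Xd.T @ yt, assume_a="pos")
    r = yt - Xt @ beta
    sg2 = float(np.sum(r * r / d)) / (n - p)
    se2 = delta * sg2
    neg2_val = neg2(logdelta)
    loglik = -0.5 * (neg2_val + (n - p) * (1.0 + _LOG2PI))
    h2 = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0
    return KernelREMLFit(sigma_g2=sg2, sigma_e2=se2, beta=beta, loglik=loglik,
                         h2=float(h2), n_obs=n, eigvals=s, eigvecs=U)


@dataclass
class MultiKernelREMLFit:
    """Multi-kernel mixed model: one variance component per kernel."""

    sigma2: dict[str, float]            # kernel name -> variance
    sigma_e2: float
    beta: np.ndarray
    loglik: float
    Vinv_resid: np.ndarray              # V^-1 (y - X beta), for BLUP components
    converged: bool


def reml_multikernel(y: np.ndarray, X: np.ndarray,
                     kernels: dict[str, np.ndarray]) -> MultiKernelREMLFit:
    """REML for ``y = X b + sum_k g_k + e``, ``g_k ~ N(0, K_k sigma_k^2)``.

    Optimises log variances with analytic gradients
    ``d(-2l)/d sigma_k^2 = tr(P K_k) - y' P K_k P y``.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    X, _ = drop_aliased_columns(X)
    n, p = X.shape
    names = list(kernels)
    Ks = [0.5 * (np.asarray(kernels[k], float) + np.asarray(kernels[k], float).T)
          for k in names]
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("constant response")
    scale = vy

    def neg2_and_grad(logs2):
        s2 = np.exp(np.clip(logs2, -30, 30)) * scale
        V = np.eye(n) * s2[-1]
        for sk, Kk in zip(s2[:-1], Ks):
            V += sk * Kk
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(logs2)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vinv = linalg.cho_solve(cf, np.eye(n))
        VinvX = Vinv @ X
        A = X.T @ VinvX
        Ainv = linalg.inv(A)
        P = Vinv - VinvX @ Ainv @ VinvX.T
        Py = P @ y
        neg2 = logdetV + float(np.log(np.abs(np.linalg.det(A)) + 1e-300)) \
            + float(y @ Py)
        grads = np.empty_like(s2)
        for j, Kk in enumerate(Ks):
            grads[j] = np.sum(P * Kk) - float(Py @ Kk @ Py)
        grads[-1] = np.trace(P) - float(Py @ Py)
        # chain rule to log scale (and the 1/2 from -2l -> -2l; keep -2l units)
        return neg2, grads * s2
    k = len(Ks)
    x0 = np.log(np.full(k + 1, 1.0 / (k + 1)))
    res = optimize.minimize(neg2_and_grad, x0, jac=True, method="L-BFGS-B",
                            bounds=[(-30, 10)] * (k + 1),
                            options={"ftol": 1e-12, "gtol": 1e-8,
                                     "maxiter": 500})
    s2 = np.exp(np.clip(res.x, -30, 30)) * scale
    V = np.eye(n) * s2[-1]
    for sk, Kk in zip(s2[:-1], Ks):
        V += sk * Kk
    cf = linalg.cho_factor(V, lower=True)
    Vinv = linalg.cho_solve(cf, np.eye(n))
    VinvX = Vinv @ X
    A = X.T @ VinvX
    beta = linalg.solve(A, VinvX.T @ y)
    resid = y - X @ beta
    Vinv_resid = Vinv @ resid
    loglik = -0.5 * (res.fun + (n - p) * _LOG2PI)
    sigma2 = {nm: float(v) for nm, v in zip(names, s2[:-1])}
    sigma2 = {nm: (0.0 if v < 1e-10 * scale else v) for nm, v in sigma2.items()}
    return MultiKernelREMLFit(sigma2=sigma2, sigma_e2=float(s2[-1]), beta=beta,
                              loglik=float(loglik), Vinv_resid=Vinv_resid,
                              converged=bool(res.success))
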