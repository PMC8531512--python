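"""REML estimation and BLUP solving for Gaussian mixed models.

This is the numerical core behind the trial models and the genomic
prediction schemes.  A mixed model here is

    y = X b + sum_r Z_r u_r + e,      u_r ~ N(0, s2_r * K_r),
    e ~ N(0, s2_e * I),

with each random term carrying a known covariance kernel ``K_r``
(identity for classical designs, a genomic relationship matrix G for
GBLUP, or block I (x) G for genotype-by-environment terms).

Four solvers are provided, each exact REML on its domain:

``reml_single_kernel``
    One random term.  The restricted likelihood is profiled down to a
    one-dimensional search over the variance ratio lambda = s2_e/s2_g
    using the eigendecomposition of Z K Z' (the spectral shortcut that
    makes GBLUP equivalent to ridge regression).

``reml_multi_kernel``
    Any number of terms, arbitrary (possibly unbalanced) designs.
    EM-REML iterations with a monotonically non-decreasing restricted
    likelihood; unconditionally stable at desk scale.

``reml_from_strata``
    Balanced crossed designs with identity kernels collapse into a small
    number of orthogonal strata with diagonal covariance; REML becomes a
    few-parameter optimization over the strata likelihood.  Used by the
    phenotypic trial models whenever the data form a complete grid.

``reml_gxe_spectral``
    The multi-environment GBLUP model (fixed environment intercepts, a
    main genetic term with kernel G shared across environments and a
    G-by-E term with kernel I (x) G) on a complete line-by-environment
    grid.  G and the environment structure are simultaneously
    diagonalizable, so REML reduces to three variance parameters with
    O(n) likelihood evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "KernelError",
    "NumericalError",
    "RandomTerm",
    "MixedModelProblem",
    "MixedModelSolution",
    "GxESolution",
    "reml_single_kernel",
    "reml_multi_kernel",
    "reml_from_strata",
    "reml_gxe_spectral",
    "blup_predict",
]

#: eigenvalues of a kernel may be this negative (relative to the largest)
#: before the kernel is rejected as non-PSD
_PSD_TOL = 1e-8


class KernelError(ValueError):
    """A covariance kernel is not symmetric positive semi-definite."""


class NumericalError(RuntimeError):
    """The solver hit a numerically singular system."""


@dataclass
class RandomTerm:
    """One random effect: design matrix, kernel and level identifiers.

    ``K is None`` means the identity kernel.  ``levels`` names the
    columns of ``Z`` (and rows/columns of ``K``); levels without any
    observation (all-zero columns of ``Z``) are legal and receive BLUPs
    through their kernel covariances with observed levels.
    """

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None
    levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.Z.shape[1], self.Z.shape[1]):
                raise ValueError(
                    f"term {self.name!r}: K shape {self.K.shape} does not match "
                    f"Z columns ({self.Z.shape[1]})"
                )
            if not np.allclose(self.K, self.K.T, atol=1e-8):
                raise KernelError(f"term {self.name!r}: kernel is not symmetric")
        if self.levels is None:
            self.levels = np.arange(self.Z.shape[1])
        else:
            self.levels = np.asarray(self.levels)
            if len(self.levels) != self.Z.shape[1]:
                raise ValueError(f"term {self.name!r}: levels/Z mismatch")

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]

    def h_matrix(self) -> np.ndarray:
        """Observation-space covariance contribution Z K Z'."""
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class MixedModelProblem:
    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row counts of y and X disagree")
        for t in self.terms:
            if t.Z.shape[0] != self.y.shape[0]:
                raise ValueError(f"term {t.name!r}: Z has wrong number of rows")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]


@dataclass
class MixedModelSolution:
    """Fitted fixed effects, per-term BLUPs and variance components."""

    beta: np.ndarray
    blups: dict[str, np.ndarray]
    levels: dict[str, np.ndarray]
    components: dict[str, float]  # per-term variances plus "residual"
    loglik: float
    converged: bool
    n_iter: int
    method: str
    history: list[float] = field(default_factory=list)

    def component(self, name: str) -> float:
        return self.components[name]


def blup_predict(solution: MixedModelSolution, target_ids, term: str | None = None) -> np.ndarray:
    """Predicted genetic values for ``target_ids`` from a fitted model.

    Targets must be levels of the random term's kernel; they may be
    absent from the training data (all-zero design columns), in which
    case their BLUP was already propagated through the kernel.
    """
    if term is None:
        if len(solution.blups) != 1:
            raise ValueError("multiple random terms: specify `term`")
        term = next(iter(solution.blups))
    levels = solution.levels[term]
    index = {lev: i for i, lev in enumerate(levels)}
    try:
        pos = [index[t] for t in target_ids]
    except KeyError as exc:
        raise KeyError(f"target {exc.args[0]!r} is not a level of term {term!r}") from None
    return solution.blups[term][pos]


# ---------------------------------------------------------------------------
# single kernel: spectral REML
# ---------------------------------------------------------------------------


def _check_psd_eigh(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = 0.5 * (H + H.T)
    d, U = linalg.eigh(H)
    scale = max(d[-1], 1.0)
    if d[0] < -_PSD_TOL * scale:
        raise KernelError(f"kernel matrix has negative eigenvalue {d[0]:.3e}")
    return np.clip(d, 0.0, None), U


def reml_single_kernel(
    problem: MixedModelProblem,
    log_lambda_bounds: tuple[float, float] = (-10.0, 10.0),
) -> MixedModelSolution:
    """Exact REML for a model with a single random term.

    Rotates the model by the eigenvectors of Z K Z', reducing the
    restricted likelihood to a bounded scalar optimization over
    log(lambda), lambda = s2_e / s2_g.  BLUPs at the optimum are exact
    and cover every kernel level, including unphenotyped ones.
    """
    if len(problem.terms) != 1:
        raise ValueError("reml_single_kernel requires exactly one random term")
    term = problem.terms[0]
    y, X = problem.y, problem.X
    n, p = X.shape
    if n - p < 2:
        raise ValueError("not enough residual degrees of freedom")

    d, U = _check_psd_eigh(term.h_matrix())
    yt = U.T @ y
    Xt = U.T @ X

    def profile(loglam: float):
        lam = np.exp(loglam)
        w = 1.0 / (d + lam)
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        try:
            c, low = linalg.cho_factor(XtWX)
        except linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalError("X'V^-1X singular") from exc
        beta = linalg.cho_solve((c, low), XtW.T @ yt)
        resid = yt - Xt @ beta
        ss = float(np.sum(w * resid**2))
        ss = max(ss, 1e-300)
        s2g = ss / (n - p)
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(c))))
        neg2ll = (
            (n - p) * np.log(s2g)
            + float(np.sum(np.log(d + lam)))
            + logdet_xvx
            + (n - p)
        )
        return neg2ll, beta, resid, w, s2g

    res = optimize.minimize_scalar(
        lambda x: profile(x)[0],
        bounds=log_lambda_bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    loglam = float(res.x)
    neg2ll, beta, resid, w, s2g = profile(loglam)
    lam = np.exp(loglam)
    s2e = lam * s2g

    # u = K Z' V^-1 (y - Xb) ; V^-1 r = U diag(w) resid_rot / s2g, the s2g
    # cancels against the s2g in Cov(u, y).
    vr = U @ (w * resid)
    if term.K is None:
        u = term.Z.T @ vr
    else:
        u = term.K @ (term.Z.T @ vr)

    return MixedModelSolution(
        beta=beta,
        blups={term.name: u},
        levels={term.name: term.levels},
        components={term.name: s2g, "residual": s2e},
        loglik=-0.5 * neg2ll,
        converged=bool(res.success),
        n_iter=int(res.nfev),
        method="spectral",
    )


# ---------------------------------------------------------------------------
# multi kernel: EM-REML
# ---------------------------------------------------------------------------


def restricted_loglik(problem: MixedModelProblem, components: dict[str, float]) -> float:
    """Restricted log-likelihood (up to an additive constant) at given
    variance components.  Used both by the EM solver and, in tests, as an
    implementation-independent oracle."""
    y, X = problem.y, problem.X
    n = y.shape[0]
    V = components["residual"] * np.eye(n)
    for t in problem.terms:
        V += components[t.name] * t.h_matrix()
    c, low = linalg.cho_factor(V)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise NumericalError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdet_v + logdet_xvx + yPy)


def reml_multi_kernel(
    problem: MixedModelProblem,
    max_iter: int = 500,
    tol: float = 1e-6,
    start: dict[str, float] | None = None,
) -> MixedModelSolution:
    """EM-REML for an arbitrary number of random terms.

    Each iteration updates every variance component from its conditional
    expectation given the data; the restricted likelihood is guaranteed
    non-decreasing.  Convergence is declared when the largest relative
    component change drops below ``tol``; otherwise the best iterate is
    returned with ``converged=False``.
    """
    y, X = problem.y, problem.X
    n, p = X.shape
    terms = problem.terms
    if not terms:
        raise ValueError("at least one random term required")

    H = [t.h_matrix() for t in terms]
    for t, h in zip(terms, H):
        _check_psd_eigh(h)  # validates, result discarded

    vary = float(np.var(y, ddof=1)) or 1.0
    if start is None:
        s2 = np.full(len(terms), vary / (len(terms) + 1))
        s2e = vary / (len(terms) + 1)
    else:
        s2 = np.array([start[t.name] for t in terms], dtype=float)
        s2e = float(start["residual"])

    floor = 1e-12 * vary
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = s2e * np.eye(n)
        for sr, h in zip(s2, H):
            V += sr * h
        try:
            c, low = linalg.cho_factor(V)
        except linalg.LinAlgError as exc:
            cond = np.linalg.cond(V)
            raise NumericalError(
                f"covariance matrix singular at iteration {it} (cond ~ {cond:.2e})"
            ) from exc
        Vi = linalg.cho_solve((c, low), np.eye(n))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        try:
            cx = linalg.cho_factor(XtViX)
        except linalg.LinAlgError as exc:
            raise NumericalError("X'V^-1X singular; check fixed-effect design") from exc
        P = Vi - ViX @ linalg.cho_solve(cx, ViX.T)
        Py = P @ y

        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        history.append(ll)

        s2_new = np.empty_like(s2)
        for r, (sr, h, t) in enumerate(zip(s2, H, terms)):
            q = t.n_levels
            quad = float(Py @ (h @ Py))
            tr = float(np.sum(P * h))
            s2_new[r] = sr + sr**2 * (quad - tr) / q
        s2e_new = s2e + s2e**2 * (float(Py @ Py) - float(np.trace(P))) / n

        s2_new = np.clip(s2_new, 0.0, None)
        s2e_new = max(s2e_new, floor)

        denom = np.maximum(np.append(s2, s2e), 1e-8 * vary)
        delta = np.abs(np.append(s2_new, s2e_new) - np.append(s2, s2e)) / denom
        s2, s2e = s2_new, s2e_new
        if float(np.max(delta)) < tol:
            converged = True
            break

    # final BLUPs at the last components
    V = s2e * np.eye(n)
    for sr, h in zip(s2, H):
        V += sr * h
    c, low = linalg.cho_factor(V)
    Vi = linalg.cho_solve((c, low), np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ y
    blups = {}
    for sr, t in zip(s2, terms):
        zy = t.Z.T @ Py
        blups[t.name] = sr * (zy if t.K is None else t.K @ zy)

    components = {t.name: float(sr) for t, sr in zip(terms, s2)}
    components["residual"] = float(s2e)
    return MixedModelSolution(
        beta=beta,
        blups=blups,
        levels={t.name: t.levels for t in terms},
        components=components,
        loglik=history[-1] if history else np.nan,
        converged=converged,
        n_iter=it,
        method="em",
        history=history,
    )


# ---------------------------------------------------------------------------
# balanced crossed designs: strata likelihood
# ---------------------------------------------------------------------------


@dataclass
class StrataFit:
    components: np.ndarray        # one variance per column of coef
    names: list[str]
    loglik: float
    cov: np.ndarray               # inverse Fisher information
    converged: bool

    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def reml_from_strata(
    dims: np.ndarray,
    ss: np.ndarray,
    coef: np.ndarray,
    names: list[str],
) -> StrataFit:
    """Exact REML for a balanced design reduced to orthogonal strata.

    ``dims[s]`` is the dimension of stratum s, ``ss[s]`` the squared norm
    of the data projection onto it, and ``coef[s, j]`` the coefficient of
    variance component j in the stratum variance v_s = coef[s] . theta.
    Minimizes sum_s (dims_s log v_s + ss_s / v_s) subject to theta >= 0.
    The last component must be the residual (coefficient 1 in every
    stratum) so that v_s > 0 is guaranteed.
    """
    dims = np.asarray(dims, dtype=float)
    ss = np.asarray(ss, dtype=float)
    coef = np.asarray(coef, dtype=float)
    k = coef.shape[1]
    if not np.all(coef[:, -1] == 1.0):
        raise ValueError("last component must be the residual (coefficient 1 everywhere)")

    ms = ss / dims
    scale = max(float(np.mean(ms)), 1e-12)

    def objective(theta: np.ndarray):
        v = coef @ theta
        v = np.maximum(v, 1e-300)
        f = float(np.sum(dims * np.log(v) + ss / v))
        grad = coef.T @ (dims / v - ss / v**2)
        return f, grad

    # ANOVA (method-of-moments) start, clipped into the feasible region
    theta0, _ = optimize.nnls(coef * np.sqrt(dims)[:, None], ms * np.sqrt(dims))
    theta0 = np.maximum(theta0, 0.0)
    theta0[-1] = max(theta0[-1], 1e-6 * scale)
    starts = [theta0, np.full(k, scale / k)]

    best = None
    bounds = [(0.0, None)] * (k - 1) + [(1e-12 * scale, None)]
    for t0 in starts:
        res = optimize.minimize(
            objective, t0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.maximum(best.x, 0.0)

    v = np.maximum(coef @ theta, 1e-300)
    fisher = 0.5 * (coef.T * (dims / v**2)) @ coef
    cov = np.linalg.pinv(fisher)
    return StrataFit(
        components=theta,
        names=list(names),
        loglik=-0.5 * float(best.fun),
        cov=cov,
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# multi-environment GBLUP on a complete grid: spectral REML
# ---------------------------------------------------------------------------


@dataclass
class GxESolution:
    """Fit of y_ij = E_i + g_j + gE_ij + e_ij on a complete grid.

    ``g_hat``/``ge_hat`` cover every level of the kernel, so lines absent
    from the training grid are predicted through their relationships.
    """

    env_effects: np.ndarray          # fixed intercept per training environment
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    g_hat: np.ndarray                # (n_kernel,)
    ge_hat: np.ndarray               # (n_train_env, n_kernel)
    loglik: float
    converged: bool

    @property
    def components(self) -> dict[str, float]:
        return {
            "genetic": self.sigma2_g,
            "gxe": self.sigma2_ge,
            "residual": self.sigma2_e,
        }


def _orthonormal_with_mean_first(m: int) -> np.ndarray:
    """Orthonormal m x m basis whose first column is the normalized mean."""
    A = np.eye(m)
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    if Q[0, 0] < 0:
        Q[:, 0] *= -1.0
    return Q


def reml_gxe_spectral(
    Y: np.ndarray,
    K: np.ndarray,
    train_idx: np.ndarray,
) -> GxESolution:
    """Exact REML for the multi-environment GBLUP model on a complete
    environment-by-line grid.

    Parameters
    ----------
    Y
        (n_env, n_train) response grid (one adjusted phenotype per
        training line and environment).
    K
        (n, n) genomic relationship kernel over *all* lines, training and
        target alike.
    train_idx
        Integer positions (into K) of the columns of Y.

    The main genetic term has covariance s2_g * (J (x) K_tt) and the
    interaction term s2_ge * (I (x) K_tt); both are diagonal in the
    basis (mean/contrast of environments) (x) (eigenvectors of K_tt),
    so each restricted-likelihood evaluation is O(n_env * n_train).
    """
    Y = np.asarray(Y, dtype=float)
    E, t = Y.shape
    train_idx = np.asarray(train_idx)
    Ktt = K[np.ix_(train_idx, train_idx)]
    d, U = _check_psd_eigh(Ktt)
    if E == 1:
        warnings.warn(
            "single training environment: genetic and G-by-E variances are "
            "not separately identifiable",
            stacklevel=2,
        )

    P = _orthonormal_with_mean_first(E)
    Yt = P.T @ Y @ U                      # (E, t) rotated responses
    u = U.T @ np.ones(t)                  # rotated design of the intercepts
    u2 = u**2

    def variances(theta: np.ndarray) -> np.ndarray:
        s2g, s2ge, s2e = theta
        v = np.empty((E, t))
        v[:] = s2ge * d + s2e
        v[0] += s2g * E * d
        return v

    def neg2ll(x: np.ndarray) -> float:
        v = variances(np.exp(x))
        s = (u2 / v).sum(axis=1)          # per rotated-env scale of X'V^-1 X
        tvec = (u * Yt / v).sum(axis=1)
        ypy = float((Yt**2 / v).sum() - (tvec**2 / s).sum())
        return float(np.log(v).sum() + np.log(s).sum() + ypy)

    vtot = float(np.var(Y, ddof=1)) or 1.0
    starts = [
        np.log(np.array([vtot / 3, vtot / 3, vtot / 3])),
        np.log(np.array([0.6 * vtot, 0.15 * vtot, 0.25 * vtot])),
        np.log(np.array([0.1 * vtot, 0.1 * vtot, 0.8 * vtot])),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg2ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    s2g, s2ge, s2e = (float(x) for x in theta)

    v = variances(theta)
    s = (u2 / v).sum(axis=1)
    tvec = (u * Yt / v).sum(axis=1)
    # X'V^-1 X = P diag(s) P', so b = P (t / s)
    b = P @ (tvec / s)
    Rm = Y - b[:, None]
    Q = P @ ((P.T @ Rm @ U) / v) @ U.T    # V^-1 (y - Xb) as an (E, t) grid
    Kft = K[:, train_idx]
    g_hat = s2g * (Kft @ Q.sum(axis=0))
    ge_hat = s2ge * (Kft @ Q.T).T

    return GxESolution(
        env_effects=b,
        sigma2_g=s2g,
        sigma2_ge=s2ge,
        sigma2_e=s2e,
        g_hat=g_hat,
        ge_hat=ge_hat,
        loglik=-0.5 * float(best.fun),
        converged=bool(best.success),
    )
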