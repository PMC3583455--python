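"""Marker-effect estimators: RR-BLUP, BayesC-pi, forward-backward OLS.

All three estimators fit the same linear model for entry means,

    y_i = mu + sum_j z_ij u_j d_j + e_i,

with marker codes z_ij in {-1, 0, +1} and differ only in the treatment
of the effects u_j and the inclusion indicators d_j:

* RR-BLUP: d_j = 1 for all markers, u_j ~ N(0, sigma_u^2) with the
  variance ratio estimated by (RE)ML through a one-time spectral
  decomposition; all effects are shrunken equally.
* BayesC-pi: d_j = 0 with probability pi (learned from the data under a
  Uniform(0, 1) prior); included effects share one variance sigma_u^2
  with a scaled-inverse-chi-square prior whose scale is tied to the
  phenotypic variance of line means.
* OLS: forward selection / backward elimination of markers by partial
  t-tests at a fixed p-value threshold, with unshrunken least-squares
  coefficients for the selected subset.

A genomic estimated breeding value (GEBV) is the sum over markers of
genotype code times estimated effect; the intercept is omitted (all
accuracies are correlations, so this is consequence-free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ModelFit",
    "BayesCPiConfig",
    "fit_rrblup",
    "fit_bayescpi",
    "fit_ols_stepwise",
    "predict",
    "accuracy",
]


@dataclass(frozen=True)
class ModelFit:
    """Intercept plus per-marker effect estimates from any estimator.

    ``inclusion`` is a 0/1 indicator for OLS and RR-BLUP (always 1) and a
    posterior inclusion probability for BayesC-pi.
    """

    mu: float
    effects: np.ndarray  # (m,) float
    inclusion: np.ndarray  # (m,) float
    sigma_u2: float
    sigma_e2: float
    method: str


def _as_float_matrix(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if Z.ndim != 2:
        raise InvalidInputError("marker matrix must be 2-dimensional")
    if Z.shape[0] != y.size:
        raise InvalidInputError("marker matrix rows must match phenotype length")
    if not np.isfinite(y).all():
        raise InvalidInputError("phenotypes must be finite")
    return Z, y


# ---------------------------------------------------------------------------
# RR-BLUP
# ---------------------------------------------------------------------------


def fit_rrblup(
    marker_matrix: np.ndarray,
    entry_means: np.ndarray,
    method: str = "REML",
    ridge_lambda: float | None = None,
) -> ModelFit:
    """Ridge-regression BLUP of marker effects with (RE)ML variance ratio.

    The variance ratio ``lambda = sigma_e^2 / sigma_u^2`` is profiled out
    of the restricted (default) or full likelihood using one eigen-
    decomposition of the marker cross-product matrix; effects then solve
    the mixed-model equations at the estimated ratio.  Passing
    ``ridge_lambda`` skips estimation and solves at that fixed ratio.

    Zero phenotypic variance is a documented degenerate case: all
    effects zero and ``mu`` equal to the constant phenotype.
    """
    Z, y = _as_float_matrix(marker_matrix, entry_means)
    n, m = Z.shape
    if n < 3:
        raise InvalidInputError("need at least 3 observations")
    if method not in ("REML", "ML"):
        raise ConfigurationError("method must be 'REML' or 'ML'")

    if np.var(y) == 0.0:
        return ModelFit(float(y[0]), np.zeros(m), np.ones(m), 0.0, 0.0, "rrblup")

    G = Z @ Z.T

    if ridge_lambda is not None:
        lam = float(ridge_lambda)
        sigma_u2 = math.nan
    elif method == "REML":
        # Restricted likelihood over the n-1 contrasts orthogonal to the
        # intercept: Q[:, 1:] from the QR of the all-ones column is an
        # orthonormal basis of that space (zero eigenvalues of the
        # projected cross-product are kept -- they are residual-only
        # directions, not artifacts).
        Q, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
        K = Q[:, 1:]
        w, U = np.linalg.eigh(K.T @ G @ K)
        w = np.clip(w, 0.0, None)
        eta = (K @ U).T @ y
        k = w.size

        def neg_restricted_ll(log_lam: float) -> float:
            denom = w + math.exp(log_lam)
            s2 = float(np.mean(eta**2 / denom))
            return 0.5 * (k * math.log(s2) + float(np.log(denom).sum()))

        res = optimize.minimize_scalar(
            neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = math.exp(res.x)
        sigma_u2 = float(np.mean(eta**2 / (w + lam)))
    else:  # ML
        w, U = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        eta = U.T @ y
        xi = U.T @ np.ones(n)

        def neg_full_ll(log_lam: float) -> float:
            denom = w + math.exp(log_lam)
            beta = float((xi * eta / denom).sum() / (xi * xi / denom).sum())
            resid = eta - xi * beta
            s2 = float(np.mean(resid**2 / denom))
            return 0.5 * (n * math.log(s2) + float(np.log(denom).sum()))

        res = optimize.minimize_scalar(
            neg_full_ll, bounds=(-12.0, 12.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = math.exp(res.x)
        denom = w + lam
        beta = float((xi * eta / denom).sum() / (xi * xi / denom).sum())
        sigma_u2 = float(np.mean((eta - xi * beta) ** 2 / denom))

    # Mixed-model solve at the chosen ratio.
    V = G + lam * np.eye(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(Vinv_y.sum() / Vinv_1.sum())
    u = Z.T @ np.linalg.solve(V, y - mu)
    if ridge_lambda is not None:
        # Residual-based plug-in so the fit object is fully populated.
        resid = y - mu - Z @ u
        sigma_e2 = float(resid @ resid / max(n - 1, 1))
        sigma_u2 = sigma_e2 / lam if lam > 0 else math.nan
    else:
        sigma_e2 = lam * sigma_u2
    return ModelFit(mu, u, np.ones(m), float(sigma_u2), float(sigma_e2), "rrblup")


# ---------------------------------------------------------------------------
# BayesC-pi
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BayesCPiConfig:
    """Chain settings and prior hyperparameters for BayesC-pi.

    The marker-variance prior is scaled-inverse-chi-square with ``nu_u``
    degrees of freedom and scale ``S_u^2 = (nu_u - 2) sigma_tilde_u2 / nu_u``,
    where ``sigma_tilde_u2`` (the variance of the effect of one randomly
    sampled locus) is derived from the phenotypic variance of line means:
    ``sigma_tilde_u2 = var(y) / (m (1 - pi) mean_var(z))``, evaluated at
    the current pi and floored at ``(1 - pi) >= 1/m``.  The residual
    variance carries a flat prior.  ``fixed_*`` fields freeze the
    corresponding parameter for diagnostic runs (e.g. the RR-BLUP
    equivalence check with all markers included and variances held).
    """

    n_iter: int = 3000
    burn_in: int = 1000
    nu_u: float = 4.0
    fixed_pi: float | None = None
    fixed_sigma_u2: float | None = None
    fixed_sigma_e2: float | None = None
    include_all: bool = False

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ConfigurationError("n_iter must exceed burn_in")
        if self.nu_u <= 2:
            raise ConfigurationError("nu_u must be > 2")


def fit_bayescpi(
    marker_matrix: np.ndarray,
    entry_means: np.ndarray,
    config: BayesCPiConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ModelFit:
    """Gibbs sampler for BayesC-pi; returns posterior-mean effects.

    Per sweep the update order is: intercept; each locus in index order
    (inclusion indicator and effect jointly, from the marginal odds of
    the single-locus model); the shared effect variance from its
    conjugate scaled-inverse-chi-square posterior over the currently
    included markers; the residual variance; and pi from its Beta
    posterior under a Uniform(0, 1) prior.  Reported effects are the
    posterior means of ``d_j u_j`` over post-burn-in samples and
    ``inclusion`` holds posterior inclusion probabilities.
    """
    config = BayesCPiConfig() if config is None else config
    rng = np.random.default_rng() if rng is None else rng
    Z, y = _as_float_matrix(marker_matrix, entry_means)
    n, m = Z.shape
    if n < 3:
        raise InvalidInputError("need at least 3 observations")

    zz = (Z**2).sum(axis=0)
    var_y = float(np.var(y, ddof=1))
    mean_marker_var = float(np.var(Z, axis=0, ddof=1).mean())
    if mean_marker_var == 0.0:
        mean_marker_var = 1.0  # monomorphic panel; scale is immaterial

    def scale_su2(pi_now: float) -> float:
        incl = max(1.0 - pi_now, 1.0 / m)
        sigma_tilde = var_y / (m * incl * mean_marker_var) if var_y > 0 else 1e-8
        return (config.nu_u - 2.0) / config.nu_u * sigma_tilde

    pi = 0.5 if config.fixed_pi is None else float(config.fixed_pi)
    sigma_e2 = var_y / 2.0 if var_y > 0 else 1e-8
    if config.fixed_sigma_e2 is not None:
        sigma_e2 = float(config.fixed_sigma_e2)
    sigma_u2 = config.nu_u / (config.nu_u - 2.0) * scale_su2(pi)
    if config.fixed_sigma_u2 is not None:
        sigma_u2 = float(config.fixed_sigma_u2)

    mu = float(y.mean())
    u = np.zeros(m)
    delta = np.zeros(m, dtype=bool)
    if config.include_all:
        delta[:] = True
    resid = y - mu

    kept = 0
    eff_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    su2_sum = 0.0
    se2_sum = 0.0

    for it in range(config.n_iter):
        # intercept
        resid += mu
        mu = float(rng.normal(resid.mean(), math.sqrt(sigma_e2 / n)))
        resid -= mu

        log_odds_incl = None
        if not config.include_all:
            if pi >= 1.0:
                log_odds_incl = -np.inf
            elif pi <= 0.0:
                log_odds_incl = np.inf
            else:
                log_odds_incl = math.log1p(-pi) - math.log(pi)

        for j in range(m):
            zj = Z[:, j]
            if delta[j] and u[j] != 0.0:
                resid += zj * u[j]
            rj = float(zj @ resid)
            cj = zz[j] + sigma_e2 / sigma_u2
            if config.include_all:
                take = True
            elif log_odds_incl == -np.inf:
                take = False
            elif log_odds_incl == np.inf:
                take = True
            else:
                # log Bayes factor of the single-locus model vs the null
                log_bf = 0.5 * (
                    math.log(sigma_e2) - math.log(sigma_u2) - math.log(cj)
                ) + rj * rj / (2.0 * sigma_e2 * cj)
                p_incl = 1.0 / (1.0 + math.exp(-(log_odds_incl + log_bf))) if (
                    log_odds_incl + log_bf
                ) > -700 else 0.0
                take = bool(rng.random() < p_incl)
            if take:
                u[j] = float(rng.normal(rj / cj, math.sqrt(sigma_e2 / cj)))
                resid -= zj * u[j]
                delta[j] = True
            else:
                u[j] = 0.0
                delta[j] = False

        k_incl = int(delta.sum())
        if config.fixed_sigma_u2 is None:
            su2_scale = scale_su2(pi)
            ss = float(u[delta] @ u[delta]) + config.nu_u * su2_scale
            sigma_u2 = ss / float(rng.chisquare(config.nu_u + k_incl))
        if config.fixed_sigma_e2 is None:
            df = max(n - 2, 1)
            sigma_e2 = float(resid @ resid) / float(rng.chisquare(df))
            sigma_e2 = max(sigma_e2, 1e-12)
        if config.fixed_pi is None:
            pi = float(rng.beta(m - k_incl + 1, k_incl + 1))

        if it >= config.burn_in:
            kept += 1
            eff_sum += u  # u is zero wherever delta is False
            incl_sum += delta
            mu_sum += mu
            su2_sum += sigma_u2
            se2_sum += sigma_e2

    return ModelFit(
        mu_sum / kept,
        eff_sum / kept,
        incl_sum / kept,
        su2_sum / kept,
        se2_sum / kept,
        "bayescpi",
    )


# ---------------------------------------------------------------------------
# Forward-backward OLS
# ---------------------------------------------------------------------------


def _sweep(A: np.ndarray, j: int) -> None:
    """In-place symmetric sweep of ``A`` on pivot ``j`` (self-inverse)."""
    d = A[j, j]
    col = A[:, j].copy()
    row = A[j, :].copy()
    A -= np.outer(col, row) / d
    A[j, :] = row / d
    A[:, j] = col / d
    A[j, j] = -1.0 / d


def fit_ols_stepwise(
    marker_matrix: np.ndarray,
    entry_means: np.ndarray,
    alpha: float = 0.20,
) -> ModelFit:
    """Forward-backward stepwise multiple regression on marker codes.

    Forward step: every excluded marker is tested by the partial t-test
    of its coefficient when added to the current model; the smallest-p
    candidate enters if p <= alpha (ties break to the lowest marker
    index).  After each entry, backward elimination removes any included
    marker whose refit p-value exceeds alpha (worst first).  Iterates to
    convergence with the model size capped at n - 2 so at least one
    residual degree of freedom remains.  Final coefficients are plain
    least squares on the selected subset; an empty model is a valid fit.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    Z, y = _as_float_matrix(marker_matrix, entry_means)
    n, m = Z.shape
    if n < 4:
        raise InvalidInputError("need at least 4 observations")

    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    yc = y - y.mean()

    # Augmented centered cross-product matrix; sweeping the pivot of an
    # included marker updates all candidate statistics in O(m^2).
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = Zc.T @ Zc
    A[:m, m] = Zc.T @ yc
    A[m, :m] = A[:m, m]
    A[m, m] = float(yc @ yc)
    diag0 = np.diag(A).copy()
    tol = 1e-10

    in_model = np.zeros(m, dtype=bool)
    k = 0
    cap = n - 2

    def backward() -> None:
        nonlocal k
        while k > 0:
            rss = A[m, m]
            df = n - k - 1
            idx = np.flatnonzero(in_model)
            b = A[idx, m]
            inv_diag = -A[idx, idx]  # swept diagonal = -(X'X)^-1 element
            sigma2 = rss / df if df > 0 else np.inf
            with np.errstate(divide="ignore", invalid="ignore"):
                t2 = b * b / (sigma2 * inv_diag)
            p = stats.f.sf(t2, 1, df)
            worst = int(np.nanargmax(p))
            if p[worst] > alpha:
                _sweep(A, idx[worst])
                in_model[idx[worst]] = False
                k -= 1
            else:
                break

    for _ in range(2 * m + 10):  # convergence guard; each pass adds a marker
        if k >= cap:
            break
        rss = A[m, m]
        df_new = n - k - 2
        if df_new < 1 or rss <= 0:
            break
        cand = ~in_model
        s_jj = np.where(cand, np.diag(A)[:m], np.nan)
        s_jy = A[:m, m]
        with np.errstate(divide="ignore", invalid="ignore"):
            red = np.where(s_jj > tol * np.maximum(diag0[:m], 1.0), s_jy**2 / s_jj, np.nan)
            t2 = red / ((rss - red) / df_new)
        p = np.full(m, np.inf)
        valid = np.isfinite(red)
        perfect = valid & (rss - red <= 0)  # candidate absorbs all residual SS
        p[valid] = stats.f.sf(np.clip(np.nan_to_num(t2[valid], posinf=1e300), 0, None),
                              1, df_new)
        p[perfect] = 0.0
        p[~cand] = np.inf
        best = int(p.argmin())
        if not np.isfinite(p[best]) or p[best] > alpha:
            break
        _sweep(A, best)
        in_model[best] = True
        k += 1
        backward()

    effects = np.zeros(m)
    idx = np.flatnonzero(in_model)
    if idx.size:
        X = np.column_stack([np.ones(n), Z[:, idx]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = float(coef[0])
        effects[idx] = coef[1:]
        resid = y - X @ coef
        df = max(n - idx.size - 1, 1)
        sigma_e2 = float(resid @ resid) / df
    else:
        mu = float(y.mean())
        sigma_e2 = float(yc @ yc) / max(n - 1, 1)
    return ModelFit(mu, effects, in_model.astype(float), math.nan, sigma_e2, "ols")


# ---------------------------------------------------------------------------
# Prediction and accuracy
# ---------------------------------------------------------------------------


def predict(model_fit: ModelFit, marker_matrix: np.ndarray) -> np.ndarray:
    """GEBVs: sum over markers of genotype code times estimated effect."""
    Z = np.asarray(marker_matrix, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != model_fit.effects.size:
        raise InvalidInputError("marker matrix columns must match effects length")
    return Z @ model_fit.effects


def accuracy(gebv: np.ndarray, true_values: np.ndarray) -> float:
    """Pearson correlation between GEBVs and true genetic values.

    Returns NaN (the undefined-accuracy signal) when either vector has
    zero variance, e.g. for an empty OLS model.
    """
    g = np.asarray(gebv, dtype=np.float64).ravel()
    a = np.asarray(true_values, dtype=np.float64).ravel()
    if g.size != a.size or g.size < 3:
        raise InvalidInputError("vectors must have equal length >= 3")
    if np.var(g) == 0.0 or np.var(a) == 0.0:
        return math.nan
    return float(np.corrcoef(g, a)[0, 1])
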