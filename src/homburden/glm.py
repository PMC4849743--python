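"""Covariate-adjusted logistic association and residual-permutation testing.

The logistic fitter is a lean Newton/IRLS implementation (gradient tolerance
1e-8) so that permutation loops refitting thousands of models stay fast; it
is validated against statsmodels in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import MISSING, GenotypeMatrix


@dataclass
class GlmResult:
    coef: float
    se: float
    wald_p: float
    perm_p: float = math.nan
    n_perm: int = 0
    seed: int | None = None
    covariates: list = field(default_factory=list)
    converged: bool = True
    separation: bool = False


class CollinearityError(ValueError):
    pass


def _check_design(X: np.ndarray, names: list) -> None:
    const = [names[j] for j in range(1, X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        raise ValueError(f"zero-variance regressor(s): {', '.join(const)}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the smallest collinear suffix for the error message
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                bad.append(names[j])
        raise CollinearityError(f"collinear design columns: {', '.join(bad) or 'unknown'}")


def fit_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> dict:
    """Maximum-likelihood logistic regression via Newton iterations.

    *X* must already include the intercept column.  Returns coefficient,
    standard error, Wald z and p arrays plus convergence/separation flags.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        xtwx = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (near-separation)
        norm = np.max(np.abs(step))
        if norm > 50:
            step *= 50 / norm
        beta = beta + step
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    # perfect separation: the fitted index splits the classes exactly
    ones, zeros = eta[y == 1], eta[y == 0]
    separation = bool(
        ones.size and zeros.size and ones.min() > zeros.max() - 1e-10
    ) or (not converged and bool(np.max(np.abs(beta)) > 30))
    try:
        cov = np.linalg.inv((X * w[:, None]).T @ X)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        separation = True
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {
        "beta": beta,
        "se": se,
        "z": z,
        "p": p,
        "converged": converged,
        "separation": separation,
    }


def logistic_glm(
    status: np.ndarray,
    f_measure: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list | None = None,
) -> GlmResult:
    """Logistic regression of case status on an inbreeding measure.

    *covariates* (optional, n x q) enter additively; the returned result
    describes the f_measure coefficient.  Complete-case exclusion is applied
    to rows with non-finite values.
    """
    status = np.asarray(status, dtype=float)
    f_measure = np.asarray(f_measure, dtype=float)
    cols = [np.ones_like(f_measure)]
    names = ["intercept"]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != f_measure.size:
            covariates = covariates.T
        q = covariates.shape[1]
        names += list(covariate_names) if covariate_names else [f"cov{j + 1}" for j in range(q)]
        cols += [covariates[:, j] for j in range(q)]
    names.append("f_measure")
    cols.append(f_measure)
    X = np.column_stack(cols)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(status)
    X, yv = X[ok], status[ok]
    _check_design(X, names)
    fit = fit_logistic(X, yv)
    j = len(names) - 1
    wald_p = float(fit["p"][j]) if not fit["separation"] else math.nan
    return GlmResult(
        coef=float(fit["beta"][j]),
        se=float(fit["se"][j]),
        wald_p=wald_p,
        covariates=names[1:-1],
        converged=fit["converged"],
        separation=fit["separation"],
    )


def perm_regressor_residuals(
    status: np.ndarray,
    f_measure: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GlmResult:
    """Permutation-of-regressor-residuals test for the f_measure effect.

    The residuals r of the linear regression of f_measure on the covariates
    replace f_measure in the GLM; the Wald p of that fit is the observed
    statistic.  Each permutation shuffles r, refits, and the reported
    ``perm_p = (1 + #{permuted p <= observed p}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    status = np.asarray(status, dtype=float)
    f_measure = np.asarray(f_measure, dtype=float)
    if covariates is None:
        Z = np.ones((f_measure.size, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != f_measure.size:
            covariates = covariates.T
        Z = np.column_stack([np.ones(f_measure.size), covariates])
    ok = np.isfinite(Z).all(axis=1) & np.isfinite(f_measure) & np.isfinite(status)
    Z, f, yv = Z[ok], f_measure[ok], status[ok]
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise CollinearityError("covariate matrix is singular")
    coef, *_ = np.linalg.lstsq(Z, f, rcond=None)
    r = f - Z @ coef

    def wald_p_of(res_vec: np.ndarray) -> float:
        X = np.column_stack([Z, res_vec])
        fit = fit_logistic(X, yv)
        return float(fit["p"][-1])

    p_obs = wald_p_of(r)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if wald_p_of(rng.permutation(r)) <= p_obs:
            count += 1
    glm = logistic_glm(yv, f, None if covariates is None else Z[:, 1:])
    return GlmResult(
        coef=glm.coef,
        se=glm.se,
        wald_p=p_obs,
        perm_p=(1 + count) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        covariates=glm.covariates,
        converged=glm.converged,
        separation=glm.separation,
    )


def genotype_pca(
    gm: GenotypeMatrix,
    k: int = 10,
    marker_index: np.ndarray | None = None,
) -> np.ndarray:
    """Top-k principal-component scores of the standardized genotype matrix.

    Columns are standardized as (x - 2p)/sqrt(2p(1-p)); missing entries are
    set to 0 after centering.  Scores carry a deterministic sign convention:
    the largest-magnitude loading of each component is positive.  Optionally
    restrict to *marker_index* (e.g. LD-pruned tags).
    """
    if k >= gm.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    p = gm.freqs
    eligible = np.isfinite(p) & (p > 0) & (p < 1)
    if marker_index is not None:
        chosen = np.zeros(gm.n_markers, dtype=bool)
        chosen[marker_index] = True
        eligible &= chosen
    idx = np.where(eligible)[0]
    calls = gm.calls[:, idx].astype(float)
    miss = gm.calls[:, idx] == MISSING
    pj = p[idx]
    z = (calls - 2.0 * pj) / np.sqrt(2.0 * pj * (1.0 - pj))
    z[miss] = 0.0
    z -= z.mean(axis=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for comp in range(min(k, vt.shape[0])):
        jmax = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, jmax] < 0:
            scores[:, comp] *= -1.0
    return scores


def build_covariates(
    gm: GenotypeMatrix,
    pcs: np.ndarray | None = None,
    use_sex: bool = True,
    use_missing: bool = True,
) -> tuple:
    """Assemble the standard covariate matrix (sex, PCs, missing rate)."""
    cols, names = [], []
    if use_sex:
        cols.append(np.array([1.0 if s.sex == "female" else 0.0 for s in gm.samples]))
        names.append("sex")
    if pcs is not None:
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            names.append(f"PC{j + 1}")
    if use_missing:
        cols.append(np.array([s.missing_rate for s in gm.samples]))
        names.append("missing_rate")
    if not cols:
        return None, []
    return np.column_stack(cols), names
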