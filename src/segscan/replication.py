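"""Replication statistics: case-control logistic LRT and kinship GLS.

Case-control replication regresses disease status on genotype counts
with nuisance covariates and tests the genotype term with a 1-df
likelihood-ratio chi-square. Quantitative replication models the
(transformed) trait as

    y ~ N(alpha + beta * g, 2 * sigma^2 * phi)

where phi is the genealogical kinship matrix (diagonal 1/2,
off-diagonal the pairwise kinship coefficient), so the residual covariance
follows relatedness: the effect and its Wald interval come from
generalized least squares with sigma^2 profiled out by maximum
likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import solve_triangular

from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CaseControlResult",
    "GLSResult",
    "CompleteSeparationError",
    "SingularKinshipError",
    "logistic_lrt",
    "gls_assoc",
]


class CompleteSeparationError(RuntimeError):
    """Genotype separates cases from controls perfectly.

    The odds ratio is unbounded; report the result as a bound or use a
    penalized likelihood.
    """


class SingularKinshipError(np.linalg.LinAlgError):
    """2*phi is numerically singular even after ridge jitter."""


@dataclass
class CaseControlResult:
    beta: float
    se: float
    odds_ratio: float
    lrt_stat: float
    p_value: float
    n: int
    n_cases: int


@dataclass
class GLSResult:
    beta: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    sigma2: float
    n: int


def logistic_lrt(
    y, g, covariates: pd.DataFrame | None = None
) -> CaseControlResult:
    """1-df likelihood-ratio test of the genotype term in logistic regression.

    ``y`` is 0/1 disease status, ``g`` genotype counts in {0, 1, 2},
    ``covariates`` an optional numeric design (no constant). The LRT
    statistic 2 log(L_full / L_reduced) is referred to chi-square(1).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.ndim != 1 or g.shape != y.shape:
        raise ValueError("y and g must be 1-d arrays of equal length")
    if np.unique(g).size < 2:
        raise ValueError("genotype has no variation")
    if np.unique(y).size < 2:
        raise ValueError("disease status has no variation")
    n = len(y)
    if covariates is not None:
        X0 = sm.add_constant(
            np.asarray(covariates, dtype=float), has_constant="add"
        )
    else:
        X0 = np.ones((n, 1))
    X1 = np.column_stack([X0, g])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X1).fit(disp=0, maxiter=200)
            reduced = sm.Logit(y, X0).fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as exc:
        # singular Hessian from a diverging genotype coefficient
        raise CompleteSeparationError(
            "genotype perfectly separates cases from controls; the MLE "
            "diverges — report the effect as a bound"
        ) from exc
    beta = float(full.params[-1])
    if not np.isfinite(full.llf) or abs(beta) > 30:
        raise CompleteSeparationError(
            "genotype perfectly separates cases from controls; the MLE "
            "diverges — report the effect as a bound"
        )
    lrt = 2.0 * (full.llf - reduced.llf)
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return CaseControlResult(
        beta=beta,
        se=float(full.bse[-1]),
        odds_ratio=float(np.exp(beta)),
        lrt_stat=float(lrt),
        p_value=p,
        n=n,
        n_cases=int(y.sum()),
    )


def _whitener(K: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        logger.warning(
            "2*phi not positive definite; adding %.1e ridge to diagonal", ridge
        )
        try:
            return np.linalg.cholesky(K + ridge * np.eye(K.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise SingularKinshipError(
                "2*phi is singular even after ridge jitter; check for "
                "duplicated individuals (identical kinship rows)"
            ) from exc


def gls_assoc(
    y,
    g,
    phi: KinshipMatrix | np.ndarray,
    covariate_design: np.ndarray | pd.DataFrame | None = None,
    reml: bool = False,
) -> GLSResult:
    """Kinship-aware association of a quantitative trait with genotype.

    Fits y = alpha + beta*g (+ covariates) with residual covariance
    2*sigma^2*phi. ``sigma^2`` is profiled by maximum likelihood
    (``reml=True`` divides by n - p instead of n); inference on beta is
    a two-sided Wald test with a normal 95% interval.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.allclose(g, g[0]):
        raise ValueError("genotype has no variation")
    K = phi.phi if isinstance(phi, KinshipMatrix) else np.asarray(phi, dtype=float)
    K = 2.0 * K
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("phi dimension does not match y")
    cols = [np.ones(n), g]
    if covariate_design is not None:
        cov = np.atleast_2d(np.asarray(covariate_design, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    p = X.shape[1]

    L = _whitener(K)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    resid = yw - Xw @ coef
    dof = n - p if reml else n
    sigma2 = float(resid @ resid) / dof
    cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
    beta = float(coef[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    z = beta / se
    pval = float(2.0 * stats.norm.sf(abs(z)))
    ci = (beta - 1.959963984540054 * se, beta + 1.959963984540054 * se)
    return GLSResult(
        beta=beta, se=se, ci95=ci, p_value=pval, sigma2=sigma2, n=n
    )
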