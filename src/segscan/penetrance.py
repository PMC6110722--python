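"""Baseline disease risk and the dominant penetrance model.

The baseline model is an ordinary logistic regression of affection status
on nuisance covariates, giving each individual a log-odds ``f_i``. A
carried risk variant shifts that log-odds additively:

    logit P(affected | g, x) = f + beta * g,   g in {0, 1}.

``beta`` is the genetic effect estimated downstream from pedigree
segregation; here we only provide the baseline fit and the penetrance
evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineRisk",
    "PenetranceModel",
    "PerfectSeparationError",
    "DegenerateOutcomeError",
    "build_design",
    "fit_baseline",
    "penetrance",
    "read_phenotype_table",
]


class PerfectSeparationError(RuntimeError):
    """Covariates separate cases from controls perfectly.

    The logistic MLE diverges; consider dropping the offending covariate
    or using a penalized (e.g. Firth) fit outside this package.
    """


class DegenerateOutcomeError(ValueError):
    """All individuals share one affection status; no model is fittable."""


def build_design(
    covariates: pd.DataFrame, schema: dict[str, str] | None = None
) -> pd.DataFrame:
    """Encode a covariate table into a numeric design matrix.

    ``schema`` maps column name -> one of ``binary``, ``linear``,
    ``standardize`` (linear term centred/scaled on the fitting sample) or
    ``categorical`` (one-hot, first level dropped). Columns absent from
    the schema default to ``categorical`` for object/categorical dtypes
    and ``standardize`` for numeric ones.
    """
    schema = schema or {}
    parts = []
    for col in covariates.columns:
        kind = schema.get(col)
        if kind is None:
            kind = (
                "categorical"
                if covariates[col].dtype == object
                or isinstance(covariates[col].dtype, pd.CategoricalDtype)
                else "standardize"
            )
        s = covariates[col]
        if kind == "categorical":
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        elif kind == "binary" or kind == "linear":
            parts.append(s.astype(float).to_frame(col))
        elif kind == "standardize":
            v = s.astype(float)
            sd = v.std(ddof=0)
            parts.append(((v - v.mean()) / (sd if sd > 0 else 1.0)).to_frame(col))
        else:
            raise ValueError(f"unknown encoding {kind!r} for column {col!r}")
    if not parts:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(parts, axis=1)


@dataclass
class BaselineRisk:
    """Per-individual baseline log-odds ``f_i`` with the fitted coefficients."""

    f: pd.Series
    coefficients: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=float)
    )
    schema: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __getitem__(self, iid) -> float:
        return float(self.f.loc[iid])

    @classmethod
    def from_logodds(cls, f: pd.Series | dict) -> "BaselineRisk":
        """Wrap externally supplied per-individual log-odds."""
        return cls(f=pd.Series(f, dtype=float))

    @classmethod
    def constant(cls, prevalence: float, ids) -> "BaselineRisk":
        """Intercept-only baseline at a given prevalence."""
        return cls(f=pd.Series(logit(prevalence), index=list(ids)))


@dataclass
class PenetranceModel:
    baseline: BaselineRisk
    beta: float

    def penetrance(self, iid, g: int) -> float:
        return penetrance(self.baseline[iid], self.beta, g)


def fit_baseline(
    affection: pd.Series,
    covariates: pd.DataFrame | None = None,
    schema: dict[str, str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> BaselineRisk:
    """Fit the baseline logistic model and return f_i for every individual.

    ``affection`` holds True/False with NaN/None for unknown status;
    unknown individuals are excluded from the fit but still receive an
    ``f_i`` when their covariates are complete. Rows with missing
    covariates are dropped (count logged).
    """
    affection = pd.Series(affection)
    if covariates is None:
        covariates = pd.DataFrame(index=affection.index)
    design = build_design(covariates.loc[affection.index], schema)
    complete = ~design.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d rows with incomplete covariates", n_dropped)
    design = design.loc[complete]

    known = affection.loc[design.index].notna()
    y = affection.loc[design.index][known].astype(float)
    if len(y) == 0 or y.nunique() < 2:
        raise DegenerateOutcomeError(
            "need at least one affected and one unaffected individual"
        )
    X = sm.add_constant(design.loc[y.index], has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(tol=tol, maxiter=maxiter)
    fitted_p = np.asarray(res.fittedvalues)
    if (
        not np.all(np.isfinite(res.params))
        or np.abs(res.params).max() > 30
        or fitted_p.min() < 1e-12
        or fitted_p.max() > 1 - 1e-12
    ):
        raise PerfectSeparationError(
            "logistic MLE diverged (perfect separation); consider removing "
            "the separating covariate or a penalized fit"
        )
    X_all = sm.add_constant(design, has_constant="add")[X.columns]
    f_all = pd.Series(
        X_all.to_numpy(dtype=float) @ res.params.to_numpy(), index=design.index
    )
    return BaselineRisk(
        f=f_all, coefficients=res.params, schema=schema or {}, n_dropped=n_dropped
    )


def penetrance(f: float, beta: float, g: int) -> float:
    """P(affected | g) = expit(f + beta*g) under dominant carrier coding."""
    if g not in (0, 1):
        raise ValueError("dominant coding requires g in {0, 1}")
    return float(expit(f + beta * g))


def read_phenotype_table(path, id_column: str = "id") -> pd.DataFrame:
    """Read a TSV of per-individual phenotypes/covariates indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    return df.set_index(id_column)
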