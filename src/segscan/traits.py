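"""Quantitative-trait preprocessing for carrier-vs-control comparisons.

The pipeline used for the cognitive and morphometry tables: rank-based
inverse-normal transformation, covariate adjustment fitted on controls
only, shifting/scaling so controls have mean 0 and SD 1, and the
percent-deficit arithmetic for volumetric headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitPipelineSpec",
    "inverse_normal",
    "adjust_and_standardize",
    "percent_deficit",
    "bonferroni_threshold",
]


@dataclass
class TraitPipelineSpec:
    """Per-trait processing recipe.

    ``higher_is_impaired`` flips the sign so that, after processing,
    larger scores always indicate greater impairment. Adjustment
    covariates are fitted on controls only; intracranial volume is used
    to adjust volumes and surface areas but never thickness, and never
    itself.
    """

    trait: str
    covariates: list = field(default_factory=list)
    higher_is_impaired: bool = True


def inverse_normal(values) -> np.ndarray | pd.Series:
    """Rank-based inverse-normal (Blom) transform.

    Maps ranks through Phi^-1((r - 3/8) / (n + 1/4)); ties get average
    ranks, missing values stay missing, and rank order is preserved.
    """
    is_series = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    x = arr[mask]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks undefined")
    r = stats.rankdata(x, method="average")
    out[mask] = stats.norm.ppf((r - 0.375) / (x.size + 0.25))
    if is_series:
        return pd.Series(out, index=values.index, name=values.name)
    return out


def adjust_and_standardize(
    values: pd.Series,
    covariates: pd.DataFrame | None,
    control_ids,
    higher_is_impaired: bool = False,
) -> pd.Series:
    """Residualize on covariates fitted on controls, then control-standardize.

    The linear adjustment is estimated from controls only and applied to
    everyone; scores are then shifted and scaled so controls have mean 0
    and SD 1. With ``higher_is_impaired`` the sign is flipped so larger
    processed scores mean greater impairment.
    """
    values = pd.Series(values, dtype=float)
    control_ids = [i for i in control_ids if i in values.index]
    if not set(control_ids) <= set(values.index):
        raise ValueError("controls must be a subset of samples")
    if covariates is not None and len(covariates.columns):
        X = covariates.loc[values.index].astype(float)
        Xc = X.loc[control_ids]
        if Xc.isna().any().any():
            raise ValueError("controls have incomplete covariates")
        n_params = X.shape[1] + 1
        if len(control_ids) < n_params:
            raise ValueError(
                f"{len(control_ids)} controls cannot identify {n_params} "
                "adjustment parameters"
            )
        A = np.column_stack([np.ones(len(control_ids)), Xc.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, values.loc[control_ids].to_numpy(), rcond=None)
        fitted_all = (
            np.column_stack([np.ones(len(values)), X.to_numpy()]) @ coef
        )
        resid = values - fitted_all
    else:
        if len(control_ids) < 1:
            raise ValueError("need at least one control")
        resid = values - values.loc[control_ids].mean()
    mu = resid.loc[control_ids].mean()
    sd = resid.loc[control_ids].std(ddof=1)
    if not sd > 0:
        raise ValueError("control scores are constant; cannot standardize")
    z = (resid - mu) / sd
    return -z if higher_is_impaired else z


def percent_deficit(
    carrier_mean: float, control_mean: float, rounded: bool = True
):
    """100 * (1 - carrier/control); negative means carriers are larger.

    Reported rounded to the nearest integer percent by default.
    """
    if not control_mean > 0:
        raise ValueError("control mean must be positive")
    pct = 100.0 * (1.0 - carrier_mean / control_mean)
    return int(round(pct)) if rounded else pct


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
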