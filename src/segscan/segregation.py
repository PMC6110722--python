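"""Pedigree likelihood under the penetrance model, MLE of beta, and LLR.

The likelihood of the observed affection statuses (and any observed
carrier genotypes) is summed over latent genotype configurations by
peeling — variable elimination over the parent-child factor graph with
binary carrier states — which matches brute-force enumeration exactly
while staying linear-ish in pedigree size for tree-like pedigrees.

Transmission is dominant and rare: a carrier parent transmits carrier
status with probability 1/2, two noncarrier parents produce noncarriers
(no de novo events inside the pedigree; a de novo origin is modelled by
making the mutation-origin individual a founder), and double
transmission collapses to g = 1.

The log-likelihood ratio LLR = log L(beta_hat) - log L(0) is the
segregation evidence: affected carriers push it up, unaffected carriers
push it down, and noncarriers contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .pedigree import Pedigree
from .penetrance import BaselineRisk

__all__ = [
    "FounderModel",
    "SegregationResult",
    "MendelianInconsistencyError",
    "pedigree_loglik",
    "fit_beta",
    "llr_observed",
    "fit_beta_observed",
    "read_carrier_tsv",
]

# transmission table T[g_father, g_mother, g_child]
_TRANSMISSION = np.zeros((2, 2, 2))
_TRANSMISSION[0, 0] = [1.0, 0.0]
_TRANSMISSION[0, 1] = [0.5, 0.5]
_TRANSMISSION[1, 0] = [0.5, 0.5]
_TRANSMISSION[1, 1] = [0.25, 0.75]


class MendelianInconsistencyError(ValueError):
    """Observed genotypes are impossible under dominant rare transmission."""


@dataclass
class FounderModel:
    """Prior on founder carrier states.

    ``iid-founders``: each founder carries independently with probability
    ``carrier_prior``. ``single-introduction`` (default for rare-variant
    work): condition on exactly one founder carrier, uniform over
    founders — the variant enters the pedigree exactly once.
    """

    carrier_prior: float = 1e-4
    mode: str = "single-introduction"

    def __post_init__(self):
        if not 0.0 <= self.carrier_prior <= 1.0:
            raise ValueError("carrier_prior must be in [0, 1]")
        if self.mode not in ("single-introduction", "iid-founders"):
            raise ValueError(f"unknown founder model mode {self.mode!r}")


@dataclass
class SegregationResult:
    beta_hat: float
    llr: float
    beta_se: float | None = None
    degenerate: bool = False
    at_bound: bool = False
    loglik_trace: list = field(default_factory=list)


def _resolve_f(baseline, ids) -> dict[str, float]:
    if isinstance(baseline, BaselineRisk):
        return {i: baseline[i] for i in ids}
    return {i: float(baseline[i]) for i in ids}


def _penetrance_factor(f: float, affection: bool, beta: float) -> np.ndarray:
    """P(A | g) for g = 0, 1; None affection contributes no factor."""
    x = np.array([f, f + beta])
    p = expit(x)
    return p if affection else 1.0 - p


def _multiply_factors(factors):
    """Multiply factors given as (vars tuple, table) with binary axes."""
    all_vars = []
    for fvars, _ in factors:
        for v in fvars:
            if v not in all_vars:
                all_vars.append(v)
    out = np.ones((2,) * len(all_vars))
    for fvars, table in factors:
        # transpose table axes into ascending joint positions, then insert
        # singleton axes so numpy broadcasting does the alignment
        target = [all_vars.index(v) for v in fvars]
        t_perm = np.transpose(table, axes=np.argsort(target))
        shape = [1] * len(all_vars)
        for pos in target:
            shape[pos] = 2
        out = out * t_perm.reshape(shape)
    return tuple(all_vars), out


def _eliminate(factors: list, elim_order: Sequence[int]) -> float:
    """Sum out variables in order; return the log of the total mass.

    Returns -inf when the observations have zero probability.
    """
    log_scale = 0.0
    factors = list(factors)
    for v in elim_order:
        touching = [f for f in factors if v in f[0]]
        rest = [f for f in factors if v not in f[0]]
        if not touching:
            continue
        joint_vars, joint = _multiply_factors(touching)
        axis = joint_vars.index(v)
        marg = joint.sum(axis=axis)
        new_vars = tuple(u for u in joint_vars if u != v)
        m = marg.max() if marg.size else float(marg)
        if not m > 0.0:
            return -np.inf
        log_scale += np.log(m)
        rest.append((new_vars, marg / m))
        factors = rest
    total = 1.0
    for fvars, table in factors:
        total *= float(np.asarray(table).sum()) if fvars else float(table)
    if not total > 0.0:
        return -np.inf
    return log_scale + np.log(total)


def _build_factors(
    ped: Pedigree,
    f: Mapping[str, float],
    beta: float,
    founder_clamp: Mapping[str, int] | None,
    carrier_prior: float | None,
):
    idx = {iid: i for i, iid in enumerate(ped.order)}
    factors = []
    for iid in ped.order:
        ind = ped[iid]
        v = idx[iid]
        if ind.is_founder:
            if founder_clamp is not None:
                g0 = founder_clamp[iid]
                prior = np.array([1.0 - g0, float(g0)])
            else:
                prior = np.array([1.0 - carrier_prior, carrier_prior])
            factors.append(((v,), prior))
        else:
            fa, mo = idx[ind.father_id], idx[ind.mother_id]
            factors.append(((fa, mo, v), _TRANSMISSION.copy()))
        if ind.affection is not None:
            factors.append(
                ((v,), _penetrance_factor(f[iid], ind.affection, beta))
            )
        if ind.genotype is not None:
            obs = np.zeros(2)
            obs[ind.genotype] = 1.0
            factors.append(((v,), obs))
    return factors, idx


def pedigree_loglik(
    ped: Pedigree,
    baseline,
    beta: float,
    founder_model: FounderModel | None = None,
) -> float:
    """log P(affections, observed genotypes | covariates, beta) by peeling.

    Latent genotypes are summed out by eliminating individuals in
    reverse topological order (leaves first). Individuals of unknown
    affection contribute no penetrance term. Raises
    :class:`MendelianInconsistencyError` when the observed genotypes have
    probability zero under the transmission model.
    """
    founder_model = founder_model or FounderModel()
    f = _resolve_f(baseline, ped.order)
    elim = [len(ped.order) - 1 - i for i in range(len(ped.order))]

    if founder_model.mode == "iid-founders":
        factors, idx = _build_factors(
            ped, f, beta, None, founder_model.carrier_prior
        )
        ll = _eliminate(factors, elim)
    else:
        # condition on exactly one founder introduction, uniform over founders
        founders = ped.founders
        per_founder = []
        for origin in founders:
            clamp = {fid: int(fid == origin) for fid in founders}
            factors, idx = _build_factors(ped, f, beta, clamp, None)
            per_founder.append(_eliminate(factors, elim))
        per_founder = np.array(per_founder)
        if np.all(np.isneginf(per_founder)):
            ll = -np.inf
        else:
            m = per_founder.max()
            ll = m + np.log(np.mean(np.exp(per_founder - m)))
    if np.isneginf(ll):
        raise MendelianInconsistencyError(
            "observed genotypes have zero probability under the dominant "
            "rare-variant transmission model"
        )
    return float(ll)


def llr_observed(f, g, affected, beta_hat: float) -> float:
    """Closed-form LLR over a fully genotyped set of individuals.

    ``affected`` may contain None/NaN for unknown status (excluded).
    Affected carriers contribute log sigma(f+beta) - log sigma(f) >= 0
    (for beta >= 0); unaffected carriers contribute
    log(1-sigma(f+beta)) - log(1-sigma(f)) <= 0; noncarrier terms vanish.
    """
    if not np.isfinite(beta_hat):
        raise ValueError("beta_hat must be finite")
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    aff = np.asarray(
        [None if a is None else bool(a) for a in np.ravel(affected)], dtype=object
    )
    known = np.array([a is not None for a in aff])
    f, g = f[known], g[known]
    a = np.array([bool(x) for x in aff[known]])
    up = log_expit(f + beta_hat * g) - log_expit(f)
    down = log_expit(-(f + beta_hat * g)) - log_expit(-f)
    return float(np.sum(np.where(a, up, down)))


def fit_beta_observed(
    f: np.ndarray,
    carriers: np.ndarray,
    affected: np.ndarray,
    bounds: tuple[float, float] = (-10.0, 10.0),
    iters: int = 80,
):
    """Vectorized per-marker MLE of beta when all genotypes are observed.

    ``carriers`` is an (M, N) boolean matrix over M markers and N
    individuals; ``f`` the per-individual baseline log-odds; ``affected``
    a boolean array (individuals of unknown status must be removed by
    the caller). The per-marker log-likelihood in beta is concave, so
    the root of its derivative is found by bisection, clamped to
    ``bounds``. Returns ``(beta_hat, llr)`` arrays of length M.
    """
    f = np.asarray(f, dtype=float)
    carriers = np.atleast_2d(np.asarray(carriers, dtype=bool))
    aff = np.asarray(affected, dtype=bool)
    A = carriers & aff[None, :]
    U = carriers & ~aff[None, :]

    def deriv(beta):
        p = expit(f[None, :] + beta[:, None])
        return (A * (1.0 - p)).sum(axis=1) - (U * p).sum(axis=1)

    m = carriers.shape[0]
    lo = np.full(m, bounds[0])
    hi = np.full(m, bounds[1])
    informative = A.any(axis=1) | U.any(axis=1)
    d_lo = deriv(lo)
    d_hi = deriv(hi)
    beta = np.zeros(m)
    at_lo = informative & (d_lo <= 0)
    at_hi = informative & (d_hi >= 0)
    interior = informative & ~at_lo & ~at_hi
    beta[at_lo] = bounds[0]
    beta[at_hi] = bounds[1]
    blo = np.where(interior, bounds[0], 0.0)
    bhi = np.where(interior, bounds[1], 0.0)
    for _ in range(iters):
        mid = 0.5 * (blo + bhi)
        pos = deriv(mid) > 0
        blo = np.where(pos, mid, blo)
        bhi = np.where(pos, bhi, mid)
    beta[interior] = (0.5 * (blo + bhi))[interior]

    fb = f[None, :] + beta[:, None]
    llr = (A * (log_expit(fb) - log_expit(f)[None, :])).sum(axis=1) + (
        U * (log_expit(-fb) - log_expit(-f)[None, :])
    ).sum(axis=1)
    llr = np.maximum(llr, 0.0)
    return beta, llr


def fit_beta(
    peds,
    baseline,
    founder_model: FounderModel | None = None,
    bounds: tuple[float, float] = (-10.0, 10.0),
    extra_observed: tuple | None = None,
) -> SegregationResult:
    """Maximize the (joint) pedigree likelihood over the genetic effect beta.

    ``peds`` may be one :class:`~segscan.pedigree.Pedigree` or a sequence;
    log-likelihoods add across pedigrees (shared beta). ``extra_observed``
    optionally supplies ``(f, g, affected)`` arrays for fully genotyped
    individuals outside the pedigrees (cohort carriers); their affection
    terms enter the objective, their genotype probability being constant
    in beta. Optimization is quasi-Newton (L-BFGS-B) with central
    finite-difference gradients inside ``bounds``; a flat likelihood
    returns beta_hat = 0, llr = 0 with ``degenerate=True``.
    """
    founder_model = founder_model or FounderModel()
    if isinstance(peds, Pedigree):
        peds = [peds]
    trace: list[tuple[float, float]] = []

    def loglik(beta: float) -> float:
        ll = sum(pedigree_loglik(p, baseline, beta, founder_model) for p in peds)
        if extra_observed is not None:
            ef, eg, ea = extra_observed
            ef = np.asarray(ef, dtype=float)
            eg = np.asarray(eg, dtype=float)
            ea = np.asarray(ea, dtype=bool)
            x = ef + beta * eg
            ll += float(
                np.sum(np.where(ea, log_expit(x), log_expit(-x)))
            )
        trace.append((float(beta), ll))
        return ll

    ll0 = loglik(0.0)
    res = minimize(
        lambda b: -loglik(b[0]),
        x0=np.array([0.0]),
        method="L-BFGS-B",
        bounds=[bounds],
        options={"eps": 1e-6, "maxiter": 200},
    )
    beta_hat = float(res.x[0])
    llr = -float(res.fun) - ll0
    if llr < 1e-9:
        probes = [loglik(b) for b in (bounds[0], -1.0, 1.0, bounds[1])]
        degenerate = max(abs(p - ll0) for p in probes) < 1e-10
        return SegregationResult(
            beta_hat=0.0,
            llr=0.0,
            degenerate=degenerate,
            loglik_trace=trace,
        )
    at_bound = (
        abs(beta_hat - bounds[0]) < 1e-6 or abs(beta_hat - bounds[1]) < 1e-6
    )
    se = None
    if not at_bound:
        h = 1e-4
        d2 = (loglik(beta_hat + h) - 2 * (ll0 + llr) + loglik(beta_hat - h)) / h**2
        if d2 < 0:
            se = float(1.0 / np.sqrt(-d2))
    return SegregationResult(
        beta_hat=beta_hat,
        llr=float(llr),
        beta_se=se,
        at_bound=at_bound,
        loglik_trace=trace,
    )


def read_carrier_tsv(path) -> dict[str, int]:
    """Read a two-column id/carrier TSV into {id: 0 or 1}."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col, g_col = df.columns[:2]
    return {str(r[id_col]): int(r[g_col]) for _, r in df.iterrows()}
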