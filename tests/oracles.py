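"""Independent brute-force oracles used to check the fast implementations.

These deliberately share no code with the package: likelihoods are
enumerated configuration by configuration, kinship is estimated by
Monte-Carlo allele dropping, and MLEs come from dense grid search.
"""

import itertools

import numpy as np
from scipy.special import expit


def _transmission_prob(g_child, g_father, g_mother):
    p_carrier = 1.0 - (1.0 - 0.5 * g_father) * (1.0 - 0.5 * g_mother)
    return p_carrier if g_child == 1 else 1.0 - p_carrier


def brute_force_loglik(ped, f, beta, founder_model):
    """Exhaustive sum over all 2^n genotype configurations."""
    ids = list(ped.order)
    founders = ped.founders
    total = 0.0
    for g in itertools.product([0, 1], repeat=len(ids)):
        gd = dict(zip(ids, g))
        if any(
            ped[i].genotype is not None and ped[i].genotype != gd[i] for i in ids
        ):
            continue
        if founder_model.mode == "iid-founders":
            q = founder_model.carrier_prior
            pg = 1.0
            for fid in founders:
                pg *= q if gd[fid] else 1.0 - q
        else:  # exactly one founder introduction, uniform over founders
            if sum(gd[fid] for fid in founders) != 1:
                continue
            pg = 1.0 / len(founders)
        for i in ids:
            ind = ped[i]
            if not ind.is_founder:
                pg *= _transmission_prob(
                    gd[i], gd[ind.father_id], gd[ind.mother_id]
                )
        pa = 1.0
        for i in ids:
            ind = ped[i]
            if ind.affection is None:
                continue
            p = expit(f[i] + beta * gd[i])
            pa *= p if ind.affection else 1.0 - p
        total += pg * pa
    return np.log(total) if total > 0 else -np.inf


def gene_drop_kinship(ped, id_a, id_b, n_drops, seed):
    """Monte-Carlo kinship: drop two labelled alleles per founder and
    estimate P(random allele of a is IBD to random allele of b)."""
    rng = np.random.default_rng(seed)
    order = list(ped.order)
    label = 0
    alleles = {}
    pat = {}
    mat = {}
    for iid in order:
        ind = ped[iid]
        if ind.is_founder:
            pat[iid] = np.full(n_drops, 2 * label)
            mat[iid] = np.full(n_drops, 2 * label + 1)
            label += 1
        else:
            pick_f = rng.integers(0, 2, n_drops).astype(bool)
            pick_m = rng.integers(0, 2, n_drops).astype(bool)
            pat[iid] = np.where(pick_f, pat[ind.father_id], mat[ind.father_id])
            mat[iid] = np.where(pick_m, pat[ind.mother_id], mat[ind.mother_id])
    ibd = np.zeros(n_drops)
    for xa in (pat[id_a], mat[id_a]):
        for xb in (pat[id_b], mat[id_b]):
            ibd += (xa == xb).astype(float)
    est = ibd.mean() / 4.0
    se = np.std(ibd / 4.0, ddof=1) / np.sqrt(n_drops)
    return est, se


def grid_search_beta(loglik, lo=-10.0, hi=10.0, step=1e-3):
    """Dense grid MLE of a 1-d log-likelihood."""
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.array([loglik(b) for b in grid])
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])
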