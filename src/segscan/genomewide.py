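"""Empirical genome-wide significance by gene-drop null simulation.

Affection statuses and covariates stay fixed at their observed values;
what is resimulated is the segregation of rare coding variants: founder
carrier states are drawn from a frequency spectrum (standing in for
sampling founder genotypes from a sequenced cohort pool), dropped
through the pedigree under Mendelian dominant transmission, and every
simulated marker is scored exactly like the observed one. The
genome-wide P-value of an observed top score is the fraction of
simulated genome scans whose maximum score reaches or exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree
from .penetrance import BaselineRisk
from .scoring import LOF, MODERATE, ImpactWeights
from .segregation import fit_beta_observed

__all__ = [
    "MarkerClass",
    "FounderPool",
    "NullScanResult",
    "gene_drop",
    "gene_drop_matrix",
    "simulate_null_scan",
]


@dataclass
class MarkerClass:
    """One stratum of the simulated marker spectrum."""

    impact: str
    carrier_freq: float
    proportion: float


def _default_spectrum():
    # class mix mirrors the exp(-2.96) LoF:moderate rate ratio behind the
    # score offset; carrier frequency matches the rare-variant search
    # space (single-digit carriers per ten thousand)
    w = float(np.exp(-2.96))
    return [
        MarkerClass(MODERATE, 1e-4, 1.0 / (1.0 + w)),
        MarkerClass(LOF, 1e-4, w / (1.0 + w)),
    ]


@dataclass
class FounderPool:
    """Frequency spectrum used to seed founder carrier states per marker.

    Stands in for sampling founder genotypes from a whole-genome
    sequenced cohort outside the pedigree; the carrier frequency per
    marker class is the pool's carrier rate.
    """

    spectrum: list = field(default_factory=_default_spectrum)

    def __post_init__(self):
        if not self.spectrum:
            raise ValueError("founder pool spectrum is empty")
        total = sum(mc.proportion for mc in self.spectrum)
        if not np.isclose(total, 1.0):
            raise ValueError("marker class proportions must sum to 1")
        for mc in self.spectrum:
            if not 0.0 <= mc.carrier_freq <= 1.0:
                raise ValueError("carrier_freq must be in [0, 1]")


@dataclass
class NullScanResult:
    n_sims: int
    max_scores: np.ndarray
    observed_score: float
    p_genomewide: float
    seed: int
    significant: bool
    add_one_correction: bool = False


def gene_drop(ped: Pedigree, founder_carriers, seed) -> dict[str, int]:
    """Drop one variant through the pedigree; returns {id: 0/1}.

    Each carrier parent transmits with probability 1/2; double
    transmission collapses to carrier (dominant coding). ``seed`` may be
    an integer or a ready ``numpy.random.Generator``.
    """
    rng = (
        np.random.default_rng(seed)
        if isinstance(seed, (int, np.integer))
        else seed
    )
    founder_carriers = set(founder_carriers)
    founders = set(ped.founders)
    bad = founder_carriers - founders
    if bad:
        raise ValueError(f"non-founders in founder_carriers: {sorted(bad)}")
    g: dict[str, int] = {}
    for iid in ped.order:
        ind = ped[iid]
        if ind.is_founder:
            g[iid] = int(iid in founder_carriers)
        else:
            inherited = False
            for pid in (ind.father_id, ind.mother_id):
                if g[pid] == 1 and rng.random() < 0.5:
                    inherited = True
            g[iid] = int(inherited)
    return g


def gene_drop_matrix(ped: Pedigree, founder_carriers: np.ndarray, rng) -> np.ndarray:
    """Vectorized gene drop of M independent markers.

    ``founder_carriers`` is an (M, F) 0/1 array over the pedigree's
    founders in ``ped.founders`` order; returns an (M, N) 0/1 array over
    ``ped.order``.
    """
    founder_carriers = np.atleast_2d(np.asarray(founder_carriers, dtype=np.int8))
    m = founder_carriers.shape[0]
    order = ped.order
    col = {iid: i for i, iid in enumerate(order)}
    g = np.zeros((m, len(order)), dtype=np.int8)
    f_idx = {fid: i for i, fid in enumerate(ped.founders)}
    for iid in order:
        ind = ped[iid]
        j = col[iid]
        if ind.is_founder:
            g[:, j] = founder_carriers[:, f_idx[iid]]
        else:
            tf = (rng.random(m) < 0.5) & (g[:, col[ind.father_id]] == 1)
            tm = (rng.random(m) < 0.5) & (g[:, col[ind.mother_id]] == 1)
            g[:, j] = (tf | tm).astype(np.int8)
    return g


def simulate_null_scan(
    ped: Pedigree,
    baseline,
    weights: ImpactWeights | None = None,
    pool: FounderPool | None = None,
    n_variants: int = 20000,
    n_sims: int = 1000,
    seed: int = 0,
    observed_score: float = np.inf,
    beta_bounds: tuple[float, float] = (-10.0, 10.0),
    add_one_correction: bool = False,
    batch_size: int = 50_000,
) -> NullScanResult:
    """Simulate null genome scans and count exceedances of the observed score.

    Per simulation: each of ``n_variants`` markers gets an impact class
    and a founder carrier configuration drawn from the pool spectrum, is
    gene-dropped through the pedigree, scored (per-marker MLE of beta on
    the fully simulated genotypes, plus the impact penalty), and the
    maximum score is recorded. ``p_genomewide`` is the plain exceedance
    fraction; ``add_one_correction`` switches to (r+1)/(n+1).

    Markers are processed in flat batches across simulations, and the
    per-marker MLE is evaluated once per distinct carrier pattern over
    the individuals of known affection (many simulated markers repeat
    patterns, especially uninformative ones).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    weights = weights or ImpactWeights()
    pool = pool or FounderPool()
    rng = np.random.default_rng(seed)

    order = ped.order
    known = np.array([ped[i].affection is not None for i in order])
    if isinstance(baseline, BaselineRisk):
        f = np.array([baseline[i] for i in order])
    else:
        f = np.array([float(baseline[i]) for i in order])
    aff = np.array([bool(ped[i].affection) for i in order])
    f_known, aff_known = f[known], aff[known]
    n_founders = len(ped.founders)

    props = np.array([mc.proportion for mc in pool.spectrum])
    freqs = np.array([mc.carrier_freq for mc in pool.spectrum])
    penalties = np.array([weights.penalty(mc.impact) for mc in pool.spectrum])

    max_scores = np.full(n_sims, -np.inf)
    total = n_sims * n_variants
    done = 0
    while done < total:
        m = min(batch_size, total - done)
        sim_idx = (done + np.arange(m)) // n_variants
        cls = rng.choice(len(pool.spectrum), size=m, p=props)
        founder_g = (
            rng.random((m, n_founders)) < freqs[cls][:, None]
        ).astype(np.int8)
        # markers with no carrier founder never produce LLR; they still
        # contribute their impact penalty as a floor
        np.maximum.at(max_scores, sim_idx, penalties[cls])
        informative = np.flatnonzero(founder_g.any(axis=1))
        if informative.size:
            g = gene_drop_matrix(ped, founder_g[informative], rng)
            patterns = g[:, known]
            uniq, inverse = np.unique(patterns, axis=0, return_inverse=True)
            _, llr_uniq = fit_beta_observed(
                f_known, uniq == 1, aff_known, bounds=beta_bounds
            )
            scores = llr_uniq[inverse] + penalties[cls[informative]]
            np.maximum.at(max_scores, sim_idx[informative], scores)
        done += m

    r = int(np.sum(max_scores >= observed_score))
    if add_one_correction:
        p = (r + 1) / (n_sims + 1)
    else:
        p = r / n_sims
    return NullScanResult(
        n_sims=n_sims,
        max_scores=max_scores,
        observed_score=float(observed_score),
        p_genomewide=float(p),
        seed=int(seed),
        significant=bool(p < 0.05),
        add_one_correction=add_one_correction,
    )
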