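"""Synthetic cohorts with known ground truth.

Emulates the data the family-based scan and its replication statistics
consume: a multi-generation analysis pedigree with a rare dominant
variant introduced in one founder, affection statuses drawn from the
logistic penetrance model with covariates, an unrelated sequenced
"outside pool" with rare carriers, and quantitative traits with
covariance 2*sigma^2*phi given by genealogical kinship. Every piece is
written in the same plain-text formats the readers consume (PED, VCF,
TSV) with the generating parameters saved alongside.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genomewide import gene_drop
from .pedigree import (
    FEMALE,
    MALE,
    Individual,
    KinshipMatrix,
    Pedigree,
    compute_kinship,
    write_ped,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_pedigree",
    "generate_families",
    "simulate_covariates",
    "baseline_logodds",
    "simulate_affections",
    "simulate_quant_trait",
    "generate_cohort",
]

_COUNTIES = [f"county{i}" for i in range(1, 9)]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for a synthetic cohort.

    Defaults mirror the study conditions the package targets: a
    ~4-generation discovery-family-sized pedigree carrying a rare
    dominant variant introduced in one founder, a baseline prevalence of
    2% with sex/birth-year effects on the logit scale, a strongly
    penetrant genetic effect (beta = 3 log-odds), a quantitative trait
    effect of -1.6 control SDs, and an outside pool with a carrier
    frequency of 1 in 10,000.
    """

    generations: int = 4
    founder_couples: int = 1
    mean_sibship: float = 2.5
    max_sibship: int = 5
    mate_prob: float = 0.6
    beta: float = 3.0
    prevalence: float = 0.02
    sex_effect: float = 0.3
    birth_year_effect: float = -0.2
    trait_alpha: float = 0.0
    trait_beta: float = -1.6
    trait_sigma2: float = 1.0
    pool_size: int = 2000
    pool_carrier_freq: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        for name in ("prevalence", "mate_prob", "pool_carrier_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations < 1 or self.founder_couples < 1:
            raise ValueError("impossible topology parameters")
        if self.trait_sigma2 < 0:
            raise ValueError("trait_sigma2 must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class SyntheticCohort:
    """A generated pedigree + pool with all latent truth exposed.

    ``phi_pedigree`` holds the dense kinship of the analysis pedigree;
    pool members are unrelated (kinship 0, diagonal 1/2). Use
    :meth:`kinship_for` to materialize the matrix for any analysis
    subset without ever forming the full cohort matrix.
    """

    ped: Pedigree
    phi_pedigree: KinshipMatrix
    genotypes: pd.Series
    affection: pd.Series
    covariates: pd.DataFrame
    trait: pd.Series
    f: pd.Series
    config: SimulationConfig
    origin_founder: str
    files: dict = field(default_factory=dict)

    @property
    def pool_ids(self) -> list[str]:
        return [i for i in self.genotypes.index if i not in self.ped.individuals]

    def kinship_for(self, ids) -> KinshipMatrix:
        ids = list(ids)
        phi = 0.5 * np.eye(len(ids))
        pos = {iid: i for i, iid in enumerate(ids)}
        inside = [i for i in ids if i in self.ped.individuals]
        for a in inside:
            for b in inside:
                if a != b:
                    phi[pos[a], pos[b]] = self.phi_pedigree.loc(a, b)
        return KinshipMatrix(ids, phi)


def generate_pedigree(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    prefix: str = "I",
) -> Pedigree:
    """Grow a multi-sibship pedigree founders-down; deterministic per seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    inds: list[Individual] = []
    current: list[Individual] = []
    for _ in range(config.founder_couples):
        fa = Individual(id=new_id(), sex=MALE, family_id="FAM1")
        mo = Individual(id=new_id(), sex=FEMALE, family_id="FAM1")
        inds += [fa, mo]
        current += [fa, mo]
    couples = [(inds[2 * i], inds[2 * i + 1]) for i in range(config.founder_couples)]

    for _gen in range(1, config.generations):
        next_gen: list[Individual] = []
        next_couples = []
        for fa, mo in couples:
            k = min(1 + rng.poisson(max(config.mean_sibship - 1.0, 0.0)),
                    config.max_sibship)
            for _ in range(k):
                child = Individual(
                    id=new_id(),
                    father_id=fa.id,
                    mother_id=mo.id,
                    sex=MALE if rng.random() < 0.5 else FEMALE,
                    family_id="FAM1",
                )
                inds.append(child)
                next_gen.append(child)
        # lineage members marry in founder spouses (not in the last
        # generation, which has no children to parent)
        for member in next_gen if _gen < config.generations - 1 else []:
            if rng.random() < config.mate_prob:
                spouse = Individual(
                    id=new_id(),
                    sex=FEMALE if member.sex == MALE else MALE,
                    family_id="FAM1",
                )
                inds.append(spouse)
                pair = (
                    (member, spouse) if member.sex == MALE else (spouse, member)
                )
                next_couples.append(pair)
        couples = next_couples
        if not couples:
            break
    return Pedigree(inds)


def generate_families(
    config: SimulationConfig, n_families: int, seed: int | None = None
) -> Pedigree:
    """Several disjoint families in one pedigree (ids ``F{k}_I{j}``).

    Useful for replication-scale cohorts: the kinship matrix is block
    diagonal, families share no ancestry.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    inds: list[Individual] = []
    for k in range(n_families):
        fam = generate_pedigree(config, rng, prefix=f"F{k}_I")
        for iid in fam.order:
            ind = fam[iid]
            ind.family_id = f"FAM{k + 1}"
            inds.append(ind)
    return Pedigree(inds)


def simulate_covariates(
    ids, rng: np.random.Generator, generation: dict[str, int] | None = None
) -> pd.DataFrame:
    """Sex, birth year (60-year window), county (8 levels), lifetime overlap."""
    ids = list(ids)
    n = len(ids)
    if generation:
        base = np.array([1930 + 22 * (generation.get(i, 1) - 1) for i in ids])
        birth = base + rng.integers(-5, 6, size=n)
    else:
        birth = rng.integers(1930, 1990, size=n)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "birth_year": birth.astype(float),
            "county": rng.choice(_COUNTIES, size=n),
            "overlap": (rng.random(n) < 0.9).astype(int),
        },
        index=ids,
    )


def baseline_logodds(config: SimulationConfig, covariates: pd.DataFrame) -> pd.Series:
    """True baseline f_i implied by the config's covariate effects."""
    z_birth = (covariates["birth_year"] - covariates["birth_year"].mean()) / 30.0
    f = (
        logit(config.prevalence)
        + config.sex_effect * covariates["sex"].astype(float)
        + config.birth_year_effect * z_birth
    )
    return pd.Series(np.asarray(f, dtype=float), index=covariates.index)


def simulate_affections(ped_or_ids, f, beta: float, genotypes, rng) -> pd.Series:
    """Bernoulli affection draws from the penetrance expit(f + beta*g)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ids = list(ped_or_ids.order) if isinstance(ped_or_ids, Pedigree) else list(ped_or_ids)
    fv = np.array([float(f[i]) for i in ids])
    gv = np.array([float(genotypes[i]) for i in ids])
    p = expit(fv + beta * gv)
    return pd.Series(rng.random(len(ids)) < p, index=ids)


def simulate_quant_trait(
    phi: KinshipMatrix | np.ndarray,
    alpha: float,
    beta_trait: float,
    sigma2: float,
    genotypes,
    rng,
) -> np.ndarray:
    """One draw of y ~ N(alpha + beta*g, 2*sigma^2*phi)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    K = phi.phi if isinstance(phi, KinshipMatrix) else np.asarray(phi, dtype=float)
    cov = 2.0 * sigma2 * K
    g = np.asarray(genotypes, dtype=float)
    mean = alpha + beta_trait * g
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(g)))
        return mean + L @ rng.standard_normal(len(g))
    except np.linalg.LinAlgError:
        warnings.warn("2*sigma^2*phi not PD; clipping eigenvalues at 0")
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return mean + (V * np.sqrt(w)) @ rng.standard_normal(len(g))


def _write_vcf(path, samples, variants):
    """Minimal single-contig VCF with GT calls and an IMPACT INFO tag.

    ``variants`` is a list of dicts with contig/pos/ref/alt/impact and a
    ``carriers`` set of sample ids.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({v["contig"] for v in variants})
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=250000000>\n")
        fh.write(
            '##INFO=<ID=IMPACT,Number=1,Type=String,'
            'Description="Coding impact class">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            gts = ["0/1" if s in v["carriers"] else "0/0" for s in samples]
            fh.write(
                f"{v['contig']}\t{v['pos']}\t{v.get('id', '.')}\t{v['ref']}\t"
                f"{v['alt']}\t.\tPASS\tIMPACT={v['impact']}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def generate_cohort(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SyntheticCohort:
    """Generate the full fixture set: pedigree, pool, phenotypes, files.

    The causal LoF variant is introduced in the first founder of the
    analysis pedigree and gene-dropped; outside-pool carriers occur at
    ``pool_carrier_freq``. A benign moderate-impact variant segregating
    in the pool only is included so variant readers and the scan always
    see more than one record. When ``outdir`` is given, writes
    cohort.ped, cohort.vcf, phenotypes.tsv, covariates.tsv, carriers.tsv
    (causal-variant carrier status, the replication input) and
    truth.json.
    """
    rng = np.random.default_rng(config.seed)
    ped = generate_pedigree(config, rng)

    # pedigree genotypes: single introduction through the first founder
    origin = ped.founders[0]
    ped_g = gene_drop(ped, {origin}, rng)

    pool_ids = [f"P{i + 1}" for i in range(config.pool_size)]
    pool_g = (rng.random(config.pool_size) < config.pool_carrier_freq).astype(int)

    all_ids = list(ped.order) + pool_ids
    genotypes = pd.Series(
        [ped_g[i] for i in ped.order] + list(pool_g), index=all_ids
    )

    # generation index for birth-year structure inside the pedigree
    gen_index: dict[str, int] = {}
    for iid in ped.order:
        ind = ped[iid]
        if ind.is_founder:
            gen_index[iid] = 1
        else:
            gen_index[iid] = (
                max(gen_index[ind.father_id], gen_index[ind.mother_id]) + 1
            )
    for iid in ped.nonfounders:  # married-in founders sit with their co-parent
        for pid in (ped[iid].father_id, ped[iid].mother_id):
            if ped[pid].is_founder:
                gen_index[pid] = max(gen_index[pid], gen_index[iid] - 1)
    covariates = simulate_covariates(all_ids, rng, generation=gen_index)
    for iid in ped.order:  # pedigree sexes are structural, keep them
        covariates.loc[iid, "sex"] = int(ped[iid].sex == MALE)

    f = baseline_logodds(config, covariates)
    affection = simulate_affections(all_ids, f, config.beta, genotypes, rng)
    ped.set_affections({i: bool(affection[i]) for i in ped.order})
    ped.set_genotypes({i: int(genotypes[i]) for i in ped.order})

    phi_ped = compute_kinship(ped)
    # blockwise trait draw: dense kinship inside the pedigree, iid pool
    # (phi diagonal 1/2 makes the marginal variance 2*sigma^2*0.5)
    trait_ped = simulate_quant_trait(
        phi_ped,
        config.trait_alpha,
        config.trait_beta,
        config.trait_sigma2,
        genotypes[ped.order].to_numpy(),
        rng,
    )
    trait_pool = (
        config.trait_alpha
        + config.trait_beta * pool_g
        + np.sqrt(config.trait_sigma2) * rng.standard_normal(config.pool_size)
    )
    trait = pd.Series(
        np.concatenate([trait_ped, trait_pool]), index=all_ids
    )

    cohort = SyntheticCohort(
        ped=ped,
        phi_pedigree=phi_ped,
        genotypes=genotypes,
        affection=affection,
        covariates=covariates,
        trait=trait,
        f=f,
        config=config,
        origin_founder=origin,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ped_path = outdir / "cohort.ped"
        write_ped(ped, ped_path)
        vcf_path = outdir / "cohort.vcf"
        benign_carriers = set(
            rng.choice(pool_ids, size=max(1, int(0.001 * config.pool_size)),
                       replace=False)
        )
        _write_vcf(
            vcf_path,
            all_ids,
            [
                {
                    "contig": "5",
                    "pos": 72107200,
                    "id": "causal_fs",
                    "ref": "AG",
                    "alt": "A",
                    "impact": "LoF",
                    "carriers": {i for i in all_ids if genotypes[i] == 1},
                },
                {
                    "contig": "7",
                    "pos": 123456,
                    "id": "benign_mis",
                    "ref": "C",
                    "alt": "T",
                    "impact": "moderate",
                    "carriers": benign_carriers,
                },
            ],
        )
        pheno = pd.DataFrame(
            {
                "affection": affection.astype(int),
                "trait": trait,
            },
            index=pd.Index(all_ids, name="id"),
        )
        pheno_path = outdir / "phenotypes.tsv"
        pheno.to_csv(pheno_path, sep="\t")
        covar_path = outdir / "covariates.tsv"
        covariates.rename_axis("id").to_csv(covar_path, sep="\t")
        carriers_path = outdir / "carriers.tsv"
        genotypes.rename("carrier").rename_axis("id").to_csv(
            carriers_path, sep="\t"
        )
        truth_path = outdir / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "config": dataclasses.asdict(config),
                    "origin_founder": origin,
                    "n_pedigree": len(ped),
                    "n_pedigree_carriers": int(
                        sum(ped_g[i] for i in ped.order)
                    ),
                    "n_pool_carriers": int(pool_g.sum()),
                },
                indent=2,
            )
        )
        cohort.files = {
            "ped": str(ped_path),
            "vcf": str(vcf_path),
            "phenotypes": str(pheno_path),
            "covariates": str(covar_path),
            "carriers": str(carriers_path),
            "truth": str(truth_path),
        }
    return cohort
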