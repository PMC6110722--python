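"""Pedigree representation, validation, and genealogical kinship.

A pedigree is a directed acyclic parent->child graph over individuals.
Affection status and dominant carrier genotypes (0/1) hang off each
individual; the kinship matrix ``phi`` used downstream as the GLS
covariance kernel has ``phi_ii = 1/2`` and ``phi_ij = k_ij``, the
genealogical kinship coefficient, so that ``2 * phi`` is the numerator
relationship matrix (positive semi-definite by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "PedigreeCycleError",
    "MissingParentError",
    "SexInconsistencyError",
    "load_pedigree",
    "parse_ped",
    "write_ped",
    "compute_kinship",
]

MALE, FEMALE, UNKNOWN = "male", "female", "unknown"
AFFECTED, UNAFFECTED = True, False

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_AFFECTION_CODES = {"2": AFFECTED, "1": UNAFFECTED, "0": None, "-9": None}


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class PedigreeCycleError(PedigreeError):
    """An individual is (transitively) its own ancestor."""


class MissingParentError(PedigreeError):
    """A referenced parent id has no record in the pedigree."""


class SexInconsistencyError(PedigreeError):
    """A father is recorded female, or a mother male."""


@dataclass
class Individual:
    """One pedigree member.

    ``affection`` is True (affected), False (unaffected) or None (unknown;
    excluded from all likelihood sums). ``genotype`` is dominant carrier
    coding: 1 = carries at least one copy, 0 = noncarrier, None = not
    sequenced/latent.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    affection: bool | None = None
    genotype: int | None = None
    covariates: dict = field(default_factory=dict)
    sequenced: bool = False
    family_id: str = "0"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated collection of individuals with topological ordering."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self._validate()
        self.order: list[str] = self._topological_order()

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def __iter__(self):
        return iter(self.order)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.order if self.individuals[i].is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self.order if not self.individuals[i].is_founder]

    def children_of(self, iid: str) -> list[str]:
        return [
            c.id
            for c in self.individuals.values()
            if iid in (c.father_id, c.mother_id)
        ]

    def _validate(self) -> None:
        for ind in self.individuals.values():
            # a non-founder must have both parents on record
            if (ind.father_id is None) != (ind.mother_id is None):
                raise MissingParentError(
                    f"{ind.id!r} has exactly one parent recorded; "
                    "non-founders need both"
                )
            for pid, role, want in (
                (ind.father_id, "father", MALE),
                (ind.mother_id, "mother", FEMALE),
            ):
                if pid is None:
                    continue
                parent = self.individuals.get(pid)
                if parent is None:
                    raise MissingParentError(
                        f"{role} {pid!r} of {ind.id!r} has no record"
                    )
                if parent.sex not in (want, UNKNOWN):
                    raise SexInconsistencyError(
                        f"{role} {pid!r} of {ind.id!r} is recorded {parent.sex}"
                    )

    def _topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        try:
            # lexicographic tie-break keeps the order deterministic
            return list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise PedigreeCycleError(
                "pedigree graph contains a cycle (an individual is its own "
                "ancestor)"
            ) from exc

    def set_genotypes(self, carriers: Mapping[str, int]) -> None:
        """Mark observed carrier statuses; ids absent stay latent."""
        for iid, g in carriers.items():
            if iid not in self.individuals:
                raise KeyError(f"unknown individual {iid!r}")
            if g not in (0, 1):
                raise ValueError("dominant coding requires genotype 0 or 1")
            self.individuals[iid].genotype = int(g)
            self.individuals[iid].sequenced = True

    def set_affections(self, statuses: Mapping[str, bool | None]) -> None:
        for iid, a in statuses.items():
            self.individuals[iid].affection = a


@dataclass
class KinshipMatrix:
    """Kinship matrix: diagonal 1/2, off-diagonal the kinship coefficient.

    ``2 * phi`` is the numerator relationship matrix; the GLS residual
    covariance downstream is ``2 * sigma^2 * phi``. Off-diagonals lie in
    [0, 1/4] for non-inbred pedigrees (1/4 = parent-offspring or full
    sibs, 1/16 = first cousins).
    """

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match id count")
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.phi[self._index[i], self._index[j]])

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self._index[i] for i in ids]
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def parse_ped(lines: Iterable[str]) -> Pedigree:
    """Parse 6-column PED/FAM text (family, id, father, mother, sex, phenotype).

    ``0`` encodes a missing parent; sex codes are 1=male, 2=female,
    0=unknown; phenotype 2=affected, 1=unaffected, 0/-9=unknown. The
    phenotype column is optional (affection may come from a phenotype
    table instead).
    """
    inds = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            raise PedigreeError(
                f"line {ln}: expected >=5 whitespace-delimited columns, "
                f"got {len(fields)}"
            )
        fam, iid, fid, mid, sex = fields[:5]
        pheno = fields[5] if len(fields) > 5 else "0"
        if sex not in _SEX_CODES:
            raise PedigreeError(f"line {ln}: bad sex code {sex!r}")
        if pheno not in _AFFECTION_CODES:
            raise PedigreeError(f"line {ln}: bad phenotype code {pheno!r}")
        inds.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_CODES[sex],
                affection=_AFFECTION_CODES[pheno],
                family_id=fam,
            )
        )
    return Pedigree(inds)


def load_pedigree(source) -> Pedigree:
    """Load a pedigree from a PED/FAM path or open text handle."""
    if hasattr(source, "read"):
        return parse_ped(source.read().splitlines())
    with open(source) as fh:
        return parse_ped(fh.read().splitlines())


def write_ped(ped: Pedigree, path) -> None:
    sex_out = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
    aff_out = {AFFECTED: "2", UNAFFECTED: "1", None: "0"}
    with open(path, "w") as fh:
        for iid in ped.order:
            ind = ped[iid]
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_out[ind.sex],
                        aff_out[ind.affection],
                    ]
                )
                + "\n"
            )


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Genealogical kinship via the standard recurrence.

    Processing individuals founders-first: for j with parents (f, m),
    ``k_ij = (k_if + k_im) / 2`` for any earlier i, and
    ``k_jj = (1 + k_fm) / 2``. Founders are assumed unrelated and
    non-inbred. The diagonal of the returned matrix is forced to 1/2
    exactly (inbreeding shows up only off-diagonal); a warning is
    emitted when any mating pair is related, since the forced diagonal
    then understates the variance of inbred individuals.
    """
    ids = list(ped.order)
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    k = np.zeros((n, n))
    inbred_matings = False
    for j, jid in enumerate(ids):
        ind = ped[jid]
        if ind.is_founder:
            k[j, j] = 0.5
            continue
        fi, mi = idx[ind.father_id], idx[ind.mother_id]
        if k[fi, mi] > 0:
            inbred_matings = True
        k[j, j] = 0.5 * (1.0 + k[fi, mi])
        # only pairs with already-placed i: topological order guarantees
        # both parents of j precede j, so k[i, parent] is final
        for i in range(j):
            kij = 0.5 * (k[i, fi] + k[i, mi])
            k[i, j] = k[j, i] = kij
    if inbred_matings:
        warnings.warn(
            "pedigree contains related matings; phi diagonal is forced to "
            "1/2 and does not reflect inbreeding",
            stacklevel=2,
        )
    phi = k.copy()
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(ids, phi)
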