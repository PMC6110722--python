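import numpy as np
import pytest

from segscan.pedigree import FEMALE, MALE, Individual, Pedigree

TRIO_PED = """\
FAM1 dad 0 0 1 1
FAM1 mum 0 0 2 1
FAM1 kid dad mum 1 2
"""

# three-generation, 14-member pedigree shaped like a discovery family:
# two founder couples on top, six gen-2 children, two cross-marriages
# producing four grandchildren
FAM1_LIKE_PED = """\
FAM1 f1 0 0 1 1
FAM1 f2 0 0 2 1
FAM1 f3 0 0 1 1
FAM1 f4 0 0 2 2
FAM1 a1 f1 f2 1 1
FAM1 a2 f1 f2 2 2
FAM1 a3 f1 f2 1 1
FAM1 b1 f3 f4 2 2
FAM1 b2 f3 f4 1 1
FAM1 b3 f3 f4 2 1
FAM1 k1 a1 b1 1 2
FAM1 k2 a1 b1 2 1
FAM1 k3 b2 a2 1 2
FAM1 k4 b2 a2 2 2
"""


@pytest.fixture
def trio_lines():
    return TRIO_PED.splitlines()


@pytest.fixture
def fam1_lines():
    return FAM1_LIKE_PED.splitlines()


def random_pedigree(rng, n, p_founder=0.35, p_genotyped=0.0, p_affection_known=0.8):
    """Random valid pedigree of exactly n members for property tests.

    New members become founders with probability ``p_founder`` (always
    when no couple is available) or children of a random existing
    male/female pair otherwise.
    """
    inds = [
        Individual(id="m0", sex=MALE),
        Individual(id="m1", sex=FEMALE),
    ]
    for i in range(2, n):
        males = [x.id for x in inds if x.sex == MALE]
        females = [x.id for x in inds if x.sex == FEMALE]
        sex = MALE if rng.random() < 0.5 else FEMALE
        if rng.random() < p_founder or not (males and females):
            inds.append(Individual(id=f"m{i}", sex=sex))
        else:
            inds.append(
                Individual(
                    id=f"m{i}",
                    father_id=str(rng.choice(males)),
                    mother_id=str(rng.choice(females)),
                    sex=sex,
                )
            )
    for ind in inds:
        if rng.random() < p_affection_known:
            ind.affection = bool(rng.random() < 0.4)
        if rng.random() < p_genotyped:
            ind.genotype = int(rng.random() < 0.3)
    return Pedigree(inds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
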