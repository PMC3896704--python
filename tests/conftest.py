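import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from pedibd.pedigree import AFFECTED, FEMALE, MALE, Individual, Pedigree

DATA = Path(__file__).parent / "data"


def make_trio(child_aff=True):
    return Pedigree(
        "TRIO",
        [
            Individual("dad", "TRIO", sex=MALE),
            Individual("mom", "TRIO", sex=FEMALE),
            Individual(
                "kid", "TRIO", "dad", "mom", MALE,
                AFFECTED if child_aff else "unaffected",
            ),
        ],
    )


def make_sib_pair(n_affected_sibs=2):
    members = [
        Individual("dad", "SIBS", sex=MALE),
        Individual("mom", "SIBS", sex=FEMALE),
    ]
    for i in range(n_affected_sibs):
        members.append(
            Individual(f"s{i + 1}", "SIBS", "dad", "mom", MALE, AFFECTED)
        )
    return Pedigree("SIBS", members)


def make_cousin_pair(sexes=("male", "male"), linking=("female", "female")):
    """First-cousin pair; the linking parents' sexes are configurable."""
    members = [
        Individual("gf", "CSN", sex=MALE),
        Individual("gm", "CSN", sex=FEMALE),
    ]
    for i, (link_sex, child_sex) in enumerate(zip(linking, sexes), start=1):
        link, spouse = f"p{i}", f"sp{i}"
        spouse_sex = MALE if link_sex == FEMALE else FEMALE
        members.append(Individual(link, "CSN", "gf", "gm", link_sex))
        members.append(Individual(spouse, "CSN", sex=spouse_sex))
        father = spouse if link_sex == FEMALE else link
        mother = link if link_sex == FEMALE else spouse
        members.append(
            Individual(f"c{i}", "CSN", father, mother, child_sex, AFFECTED)
        )
    return Pedigree("CSN", members)


@pytest.fixture
def trio():
    return make_trio()


@pytest.fixture
def sib_pair():
    return make_sib_pair()


@pytest.fixture
def cousin_pair():
    return make_cousin_pair()
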