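import numpy as np
import pytest

import crispri_specificity as cs


SPACER20 = "ACGTACGTACGTACGTACGT"


@pytest.fixture
def exact_genome() -> cs.Genome:
    """Genome containing exactly one perfect protospacer + TGG PAM."""
    return cs.Genome({"chr1": "AAAA" + SPACER20 + "TGG" + "AAAA"})


@pytest.fixture
def spacer() -> cs.Spacer:
    return cs.Spacer(guide_id="sg1", sequence=SPACER20)


@pytest.fixture(scope="session")
def study() -> cs.Study:
    """The standard synthetic study (20 kb genome, 1000-gene universe)."""
    return cs.make_study(rng_seed=7)


def random_genome(rng: np.random.Generator, length: int,
                  n_frac: float = 0.0) -> cs.Genome:
    p = [(1 - n_frac) / 4] * 4 + [n_frac]
    return cs.Genome(
        {"chr1": "".join(rng.choice(list("ACGTN"), size=length, p=p))}
    )


def random_spacer(rng: np.random.Generator, length: int = 20) -> cs.Spacer:
    return cs.Spacer(
        guide_id="sg", sequence="".join(rng.choice(list("ACGT"), size=length))
    )
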