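import numpy as np
import pytest

from mitobreaks import synth
from mitobreaks.genome import CircularGenome


@pytest.fixture(scope="session")
def mito_truth():
    """Study-scale synthetic genome with planted quadruplexes and motifs."""
    return synth.generate_genome(
        seed=101,
        plant=[
            (4_100, "GGGTGGGTGGGTGGG"),
            (8_200, "CCCTCCCTCCCTCCC"),
            (12_400, "GGGAGGGAGGGAGGGAGGGAGGG"),
            (15_500, "CCCCACCCC"),
        ],
    )


@pytest.fixture(scope="session")
def mito_breakpoints(mito_truth):
    return synth.generate_breakpoints(mito_truth, 1_508, 0.5, 10, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_genome(length, rng, freqs=(0.25, 0.25, 0.25, 0.25)):
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=length, p=list(freqs)))
    return CircularGenome(id="rand", sequence=seq)
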