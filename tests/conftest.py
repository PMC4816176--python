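import numpy as np
import pytest
from hypothesis import settings

from diffgrn.boolnet import ACTIVATION, INHIBITION, SignedNetwork
from diffgrn.preprocess import PhenotypePattern

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def core_network() -> SignedNetwork:
    """The published core control network: one negative autoregulation on
    RUNX1 plus two mutual-activation loops (RUNX1-FOSL2, ASCL1-SOX2)."""
    return SignedNetwork(
        ["RUNX1", "FOSL2", "ASCL1", "SOX2"],
        [("RUNX1", "RUNX1", INHIBITION),
         ("RUNX1", "FOSL2", ACTIVATION),
         ("FOSL2", "RUNX1", ACTIVATION),
         ("ASCL1", "SOX2", ACTIVATION),
         ("SOX2", "ASCL1", ACTIVATION)])


@pytest.fixture
def all_on_pattern(core_network) -> PhenotypePattern:
    return PhenotypePattern("A", {g: True for g in core_network.genes})


def random_signed_network(rng: np.random.Generator, n: int,
                          density: float = 0.3,
                          frac_inh: float = 0.3) -> SignedNetwork:
    genes = [f"g{i}" for i in range(n)]
    edges = []
    for s in genes:
        for t in genes:
            if rng.random() < density:
                sign = INHIBITION if rng.random() < frac_inh else ACTIVATION
                edges.append((s, t, sign))
    return SignedNetwork(genes, edges)
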