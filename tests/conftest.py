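import numpy as np
import pandas as pd
import pytest

from adatscan import build_adat_codon_model, simulate_bundle
from adatscan.inosine import TrnaPileup


@pytest.fixture(scope="session")
def model():
    return build_adat_codon_model()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact but complete simulated study shared across tests."""
    return simulate_bundle(seed=7, n_genes=120, length_codons=120, n_responders=3)


def make_wobble_pileup(i_fraction: float, depth: int, rng: np.random.Generator,
                       family_id: str = "Ser-AGA", error_rate: float = 0.001) -> TrnaPileup:
    """Independent binomial oracle for a position-34 pileup: G ~ Binom(depth, i)."""
    g = rng.binomial(depth, i_fraction)
    rest = depth - g
    c = rng.binomial(rest, error_rate)
    t = rng.binomial(rest - c, error_rate)
    a = rest - c - t
    return TrnaPileup(
        family_id,
        pd.DataFrame(
            [{"sprinzl_pos": 34, "ref_base": "A",
              "count_A": a, "count_C": c, "count_G": g, "count_T": t}]
        ),
    )
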