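import numpy as np
import pytest

import cublink as cl
from cublink.genetic_code import CODON_INDEX


@pytest.fixture(scope="session")
def code():
    return cl.STANDARD_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def counts_from(pairs: dict[str, int]) -> np.ndarray:
    """64-codon count vector from a {codon: count} dict."""
    x = np.zeros(64, dtype=np.int64)
    for codon, n in pairs.items():
        x[CODON_INDEX[codon]] = n
    return x


def uniform_counts(code, per_codon: int = 1) -> np.ndarray:
    """Every sense codon used ``per_codon`` times (uniform synonymous usage)."""
    x = np.zeros(64, dtype=np.int64)
    for c in code.sense_codons:
        x[CODON_INDEX[c]] = per_codon
    return x


def single_codon_counts(code, per_family: int = 10) -> np.ndarray:
    """First codon of every family used exclusively (maximal bias)."""
    x = np.zeros(64, dtype=np.int64)
    for codons in code.families.values():
        x[CODON_INDEX[codons[0]]] = per_family
    return x


@pytest.fixture(scope="session")
def organism_pair():
    """Small synthetic organism pair reused across screen/adaptation tests."""
    plant, bact = cl.plant_like_model(), cl.bacterium_like_model()
    query, truth = cl.generate_cds_set(
        plant, 300, partner_model=bact, n_planted=60, lam=0.9, id_prefix="A", seed=21
    )
    partner, _ = cl.generate_cds_set(bact, 300, id_prefix="B", seed=22)
    return {
        "query": query,
        "partner": partner,
        "truth": truth,
        "query_counts": cl.count_codons(query),
        "partner_counts": cl.count_codons(partner),
    }
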