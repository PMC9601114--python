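import numpy as np
import pytest

from cubkit import CodingSequence, GeneratorSpec, generate_genes
from cubkit.genetic_code import AA_TO_CODONS, DEGENERATE_AAS, DEGENERATE_CODONS


def make_cds(name: str, *codons: str) -> CodingSequence:
    """Assemble a CDS from sense codons, adding start and stop."""
    return CodingSequence(id=name, seq="ATG" + "".join(codons) + "TAA")


@pytest.fixture(scope="session")
def small_gene_set() -> list[CodingSequence]:
    """50 moderately biased synthetic genes shared across tests."""
    spec = GeneratorSpec(n_genes=50, length_codons=(150, 400), seed=42)
    return generate_genes(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)


def random_cds(rng: np.random.Generator, n_codons: int, name: str = "rand") -> CodingSequence:
    """A random valid CDS: uniform amino acids, uniform synonymous codons."""
    codons = []
    for _ in range(n_codons):
        aa = DEGENERATE_AAS[rng.integers(len(DEGENERATE_AAS))]
        syn = AA_TO_CODONS[aa]
        codons.append(syn[rng.integers(len(syn))])
    return make_cds(name, *codons)


__all__ = ["make_cds", "random_cds", "DEGENERATE_CODONS"]
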