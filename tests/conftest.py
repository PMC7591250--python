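import numpy as np
import pytest

from phzquant.catalog import ReferenceCatalog, ReferenceProtein
from phzquant.simulate import SimulatorConfig, make_synthetic_references

AA20 = "ARNDCQEGHILKMFPSTWYV"

# one codon per amino acid, for deterministic reverse translation in tests
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def reverse_translate(peptide: str) -> str:
    return "".join(_CODON[a] for a in peptide)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(rng: np.random.Generator, seq: str, divergence: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            out[i] = AA20[int(rng.integers(0, 20))]
    return "".join(out)


@pytest.fixture(scope="session")
def tiny_catalog() -> ReferenceCatalog:
    """Hand-sized catalog: 25 markers, 5 phz families, phdA/podA."""
    rng = np.random.default_rng(7)
    prots = []
    for i in range(25):
        prots.append(
            ReferenceProtein(
                protein_id=f"m{i:02d}",
                family=f"marker_{i + 1:02d}",
                category="marker",
                species="marker_reference",
                order="NA",
                genus="NA",
                sequence=random_protein(rng, int(rng.integers(150, 300))),
            )
        )
    for fam in ("phzA_B", "phzD", "phzE", "phzF", "phzG"):
        prots.append(
            ReferenceProtein(
                protein_id=f"{fam}|spA",
                family=fam,
                category="trait_biosynthesis",
                species="Pseudomonas_testi",
                order="Pseudomonadales",
                genus="Pseudomonas",
                sequence=random_protein(rng, 200),
            )
        )
    for fam in ("phdA", "podA"):
        prots.append(
            ReferenceProtein(
                protein_id=f"{fam}|spX",
                family=fam,
                category="trait_degradation",
                species="Mycobacterium_testi",
                order="Mycobacteriales",
                genus="Mycobacterium",
                sequence=random_protein(rng, 250),
            )
        )
    return ReferenceCatalog(prots)


@pytest.fixture(scope="session")
def small_refs():
    """Seeded synthetic references at reduced background size."""
    cfg = SimulatorConfig(n_background=6, genome_length=60_000)
    return make_synthetic_references(11, cfg)
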