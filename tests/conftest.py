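import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phisigns.simulate import generate_phage_set


@pytest.fixture(scope="session")
def planted_set(tmp_path_factory):
    """The standard 4-genome / 6-family set at 60% amino-acid identity."""
    out = tmp_path_factory.mktemp("planted")
    return generate_phage_set(n_genomes=4, n_families=6, aa_identity=0.6,
                              genome_len=40000, gene_len_aa=300, seed=42, out_dir=out)


@pytest.fixture(scope="session")
def conserved_family():
    """One 3-genome family conserved enough for primer design."""
    pset = generate_phage_set(n_genomes=3, n_families=1, aa_identity=0.9,
                              genome_len=2000, gene_len_aa=100, seed=7)
    return pset.family_genes("F1")


def random_iupac(rng: random.Random, length: int, degenerate_frac: float = 0.3) -> str:
    plain = "ACGT"
    mixed = "RYSWKMBDHVN"
    return "".join(rng.choice(mixed) if rng.random() < degenerate_frac else rng.choice(plain)
                   for _ in range(length))
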