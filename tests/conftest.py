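import numpy as np
import pytest

from riboblock import Block, FamilySpec, PlantedBlock, generate_family
from riboblock.examples import EXAMPLE_BLOCK_MOTIFS, EXAMPLE_SEQUENCE


@pytest.fixture(scope="session")
def example_sequence() -> str:
    return EXAMPLE_SEQUENCE


@pytest.fixture(scope="session")
def example_motifs() -> list[str]:
    return EXAMPLE_BLOCK_MOTIFS


def demo_block(motif: str, location: int = 1, family: str = "demo",
               prevalence: float = 1.0) -> Block:
    return Block(family=family, motif=motif, canonical_location=location,
                 prevalence=prevalence)


@pytest.fixture(scope="session")
def small_family():
    """30 members, length ~100, three planted motifs, no jitter."""
    spec = FamilySpec(
        name="toy", n_members=30, mean_length=100, length_sd=4,
        planted=(
            PlantedBlock("GAAAG", 10, 1.0, 0),
            PlantedBlock("CCUUACG", 40, 1.0, 0),
            PlantedBlock("UGGAU", 75, 1.0, 0),
        ),
    )
    return spec, generate_family(spec, seed=11)


def write_fasta_text(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")
    return path
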