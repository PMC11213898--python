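import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from natminer import (GenomeRecord, Record, SeqRecordSet, generate_genome,
                      implant_locus, make_nat_protein)


@pytest.fixture(scope="session")
def nat_protein() -> str:
    return make_nat_protein(seed=1)


@pytest.fixture(scope="session")
def reference_set(nat_protein) -> SeqRecordSet:
    return SeqRecordSet(
        [Record("NATref", "survey reference", nat_protein)],
        alphabet="protein",
    )


@pytest.fixture()
def small_genome() -> GenomeRecord:
    return generate_genome(20_000, gc=0.5, seed=42)


@pytest.fixture()
def genome_with_intact_locus(small_genome, nat_protein):
    genome, entry = implant_locus(
        small_genome, nat_protein, position=5000, strand="+",
        lesion="none", seed=3, locus_id="intact1",
    )
    return genome, entry
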