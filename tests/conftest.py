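import numpy as np
import pytest

from phipred.io_formats import (
    BACTERIUM,
    PHAGE,
    DDITable,
    InteractionRecord,
    ProteinRecord,
    Proteome,
)


@pytest.fixture
def tiny_ddi_table() -> DDITable:
    table = DDITable()
    table.add("PF00001", "PF00002", 0.5)
    table.add("PF00003", "PF00003", 1.0)
    table.add("PF00002", "PF00004", 0.25)
    return table


def make_proteome(org_id: str, kind: str, sequences: list[str]) -> Proteome:
    return Proteome(
        org_id,
        kind,
        [
            ProteinRecord(f"{org_id}_p{i}", org_id, seq)
            for i, seq in enumerate(sequences)
        ],
    )


@pytest.fixture
def tiny_phage() -> Proteome:
    return make_proteome("P1", PHAGE, ["MAGKK", "WYVTT"])


@pytest.fixture
def tiny_bacterium() -> Proteome:
    return make_proteome("B1", BACTERIUM, ["AAAA", "CDEF", "GHIK"])


def random_proteome(
    rng: np.random.Generator, org_id: str, kind: str, n_proteins: int,
    min_len: int = 5, max_len: int = 20,
) -> Proteome:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    seqs = [
        "".join(aa[i] for i in rng.integers(0, 20, size=rng.integers(min_len, max_len)))
        for _ in range(n_proteins)
    ]
    return make_proteome(org_id, kind, seqs)


def positive(phage_id: str, bacterium_id: str, species: str, family: str) -> InteractionRecord:
    return InteractionRecord(phage_id, bacterium_id, species, family, "positive")
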