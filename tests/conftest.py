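from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cutforge import CodonCountTable, Compartment, canonical_codon_order

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(
    counts: dict[str, int] | None = None,
    vector=None,
    entity_key: str = "test",
    compartment: Compartment = Compartment.GENOMIC,
    n_cds: int = 1,
    **kwargs,
) -> CodonCountTable:
    if vector is not None:
        counts = {c: int(v) for c, v in zip(canonical_codon_order(), vector)}
    return CodonCountTable(
        counts=counts or {},
        entity_key=entity_key,
        compartment=compartment,
        n_cds=n_cds,
        **kwargs,
    )


def random_table(rng: np.random.Generator, n_codons: int = 5000, alpha: float = 1.0):
    """Multinomial codon counts with Dirichlet-distributed usage weights."""
    p = rng.dirichlet(np.full(64, alpha))
    vec = rng.multinomial(n_codons, p)
    return make_table(vector=vec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def uniform_table() -> CodonCountTable:
    return make_table({c: 1000 for c in canonical_codon_order()}, entity_key="uniform")
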