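"""Codon counting and count-table arithmetic.

A sequence is read in non-overlapping triplets from position 0.  Triplets
containing any character outside ``ACGT`` (N, IUPAC ambiguity letters,
gaps) are skipped individually -- the rest of the feature still counts --
and a trailing partial triplet is dropped.  Tables are pure integer data
and merge exactly, so aggregation is associative and commutative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genbank_io import CdsRecord, Compartment
from .genetic_codes import canonical_codon_order

__all__ = [
    "MIXED_TABLE",
    "CodonCountTable",
    "count_codons",
    "count_sequence",
    "merge_tables",
    "frequencies_per_1000",
]

_UNAMBIGUOUS = frozenset("ACGT")

#: Sentinel for a merged table whose inputs disagreed on the translation table.
MIXED_TABLE: None = None


@dataclass
class CodonCountTable:
    """64 non-negative integer codon counts plus provenance metadata.

    ``translation_table`` is ``None`` (:data:`MIXED_TABLE`) when a merge
    combined tables annotated with different genetic codes.
    """

    counts: dict[str, int]
    entity_key: str
    compartment: Compartment = Compartment.GENOMIC
    n_cds: int = 0
    grouping: str = "cds"
    translation_table: int | None = 1
    taxid: int | None = None

    def __post_init__(self) -> None:
        order = canonical_codon_order()
        full = {c: int(self.counts.get(c, 0)) for c in order}
        if set(self.counts) - set(order):
            bad = sorted(set(self.counts) - set(order))
            raise ValueError(f"non-codon keys in counts: {bad}")
        if any(v < 0 for v in full.values()):
            raise ValueError("negative codon count")
        self.counts = full

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def vector(self) -> np.ndarray:
        """Counts as an int64 vector in canonical codon order."""
        return np.array(
            [self.counts[c] for c in canonical_codon_order()], dtype=np.int64
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonCountTable):
            return NotImplemented
        return (
            self.counts == other.counts
            and self.entity_key == other.entity_key
            and self.compartment == other.compartment
            and self.n_cds == other.n_cds
            and self.grouping == other.grouping
        )


def count_sequence(
    sequence: str,
    entity_key: str = "",
    compartment: Compartment = Compartment.GENOMIC,
    translation_table: int | None = 1,
    taxid: int | None = None,
) -> CodonCountTable:
    """Count codons of a raw in-frame sequence (ambiguous triplets skipped)."""
    counts: dict[str, int] = {}
    seq = sequence.upper()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if set(codon) <= _UNAMBIGUOUS:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(
        counts=counts,
        entity_key=entity_key,
        compartment=compartment,
        n_cds=1,
        grouping="cds",
        translation_table=translation_table,
        taxid=taxid,
    )


def count_codons(cds: CdsRecord) -> CodonCountTable:
    """Per-CDS codon count table.

    Raises
    ------
    ValueError
        If the record was excluded upstream; excluded CDSs carry no
        countable sequence by contract.
    """
    if cds.excluded:
        raise ValueError(
            f"cannot count excluded CDS {cds.entity_key} "
            f"(reason: {cds.exclusion_reason.value})"
        )
    return count_sequence(
        cds.sequence,
        entity_key=cds.entity_key,
        compartment=cds.compartment,
        translation_table=cds.translation_table,
        taxid=cds.taxid,
    )


def merge_tables(
    tables: Sequence[CodonCountTable],
    entity_key: str,
    grouping: str,
    compartment: Compartment | None = None,
) -> CodonCountTable:
    """Sum count tables elementwise.

    All inputs must share one compartment (organellar tables never fold
    into genomic ones); merging an empty list yields the all-zero identity
    table, whose compartment defaults to genomic unless given.
    """
    if not tables:
        return CodonCountTable(
            counts={},
            entity_key=entity_key,
            compartment=compartment or Compartment.GENOMIC,
            n_cds=0,
            grouping=grouping,
            translation_table=None,
        )
    compartments = {t.compartment for t in tables}
    if len(compartments) > 1:
        raise ValueError(
            "refusing to merge tables across compartments: "
            + ", ".join(sorted(c.value for c in compartments))
        )
    if compartment is not None and compartment not in compartments:
        raise ValueError(
            f"tables are {next(iter(compartments)).value}, expected {compartment.value}"
        )
    counts: dict[str, int] = {}
    for t in tables:
        for codon, n in t.counts.items():
            if n:
                counts[codon] = counts.get(codon, 0) + n
    transl = {t.translation_table for t in tables}
    taxids = {t.taxid for t in tables}
    return CodonCountTable(
        counts=counts,
        entity_key=entity_key,
        compartment=next(iter(compartments)),
        n_cds=sum(t.n_cds for t in tables),
        grouping=grouping,
        translation_table=transl.pop() if len(transl) == 1 else MIXED_TABLE,
        taxid=taxids.pop() if len(taxids) == 1 else None,
    )


def frequencies_per_1000(table: CodonCountTable) -> np.ndarray:
    """Codon frequencies per 1000 codons, in canonical codon order.

    The all-zero table maps to the all-zero vector (convention; avoids a
    0/0 special case for empty clade merges).
    """
    vec = table.vector().astype(float)
    total = vec.sum()
    if total == 0:
        return np.zeros(64)
    return vec / total * 1000.0
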