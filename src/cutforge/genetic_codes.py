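"""NCBI genetic (translation) tables and synonymous-codon degeneracy families.

The effective-number-of-codons statistic needs, for any translation table,
the partition of the 64 codons into synonymous families -- optionally with
the stop codons forming a family of their own.  Table definitions come from
the NCBI set embedded in Biopython (a static transcription of NCBI's
``gc.prt``), so no network access is ever required.

Tables 27, 28 and 31 assign some codons as both stop and sense depending on
context; they admit no unambiguous 64-codon partition and are rejected as
unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STOP_SYMBOL",
    "SUPPORTED_TABLE_IDS",
    "GeneticCode",
    "DegeneracyFamilies",
    "UnsupportedGeneticCodeError",
    "load_genetic_code",
    "degeneracy_families",
    "canonical_codon_order",
]

#: Symbol used for the stop "amino acid" in codon-to-symbol mappings.
STOP_SYMBOL = "*"

# Tables whose stop/sense assignment is context-dependent (a codon appears
# both in the sense table and in the stop list) cannot be partitioned.
_CONTEXT_DEPENDENT_TABLES = frozenset({27, 28, 31})

#: All NCBI translation tables this package supports.
SUPPORTED_TABLE_IDS: tuple[int, ...] = tuple(
    tid
    for tid in sorted(_BioCodonTable.unambiguous_dna_by_id)
    if tid not in _CONTEXT_DEPENDENT_TABLES
)


class UnsupportedGeneticCodeError(ValueError):
    """Raised for translation-table ids outside the supported NCBI set."""


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI translation table as a full 64-codon mapping.

    ``codon_to_symbol`` maps every unambiguous DNA codon (alphabet ACGT) to
    a one-letter amino-acid symbol, with :data:`STOP_SYMBOL` for stops.
    """

    table_id: int
    name: str
    codon_to_symbol: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.codon_to_symbol) != set(canonical_codon_order()):
            raise ValueError("codon_to_symbol must cover exactly the 64 ACGT codons")
        if STOP_SYMBOL not in self.codon_to_symbol.values():
            raise ValueError(f"table {self.table_id} has no stop codon")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(
            c for c, s in self.codon_to_symbol.items() if s == STOP_SYMBOL
        )


@dataclass(frozen=True)
class DegeneracyFamilies:
    """Partition of codons into synonymous families for one genetic code.

    Each family is a ``(symbol, frozenset-of-codons)`` pair; the family's
    degeneracy is the size of its codon set.  With ``include_stops`` the stop
    codons form one family like any amino acid; without, they are omitted
    (the classic Wright partition of the 61 sense codons).
    """

    table_id: int
    include_stops: bool
    families: tuple[tuple[str, frozenset[str]], ...]

    @property
    def codons(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.families:
            out |= members
        return frozenset(out)

    @property
    def degeneracy_of(self) -> dict[str, int]:
        """Codon -> degeneracy of its family."""
        return {c: len(members) for _, members in self.families for c in members}

    def class_sizes(self) -> dict[int, int]:
        """Degeneracy k -> number of k-fold families (Wright's m_k)."""
        sizes: dict[int, int] = {}
        for _, members in self.families:
            k = len(members)
            sizes[k] = sizes.get(k, 0) + 1
        return sizes


@lru_cache(maxsize=None)
def canonical_codon_order() -> tuple[str, ...]:
    """The 64 codons in NCBI's printed-table order (T < C < A < G per position)."""
    return tuple("".join(b) for b in product("TCAG", repeat=3))


@lru_cache(maxsize=None)
def load_genetic_code(table_id: int) -> GeneticCode:
    """Load the full 64-codon mapping for an NCBI translation table.

    Raises
    ------
    UnsupportedGeneticCodeError
        If ``table_id`` is not a supported NCBI table.  There is never a
        silent fallback to the standard code.
    """
    if table_id not in SUPPORTED_TABLE_IDS:
        raise UnsupportedGeneticCodeError(
            f"unsupported genetic code: transl_table={table_id!r} "
            f"(supported: {', '.join(map(str, SUPPORTED_TABLE_IDS))})"
        )
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(bio.forward_table)
    for stop in bio.stop_codons:
        mapping[stop] = STOP_SYMBOL
    return GeneticCode(
        table_id=table_id,
        name=bio.names[0] if bio.names else f"table {table_id}",
        codon_to_symbol=MappingProxyType(
            {c: mapping[c] for c in canonical_codon_order()}
        ),
    )


def degeneracy_families(
    code: GeneticCode, include_stops: bool = True
) -> DegeneracyFamilies:
    """Group codons into synonymous families under ``code``.

    Families are ordered by symbol (stops last) and each codon set is the
    complete synonym set for that symbol, so the families partition the 64
    codons (or the sense codons only, when stops are excluded).
    """
    by_symbol: dict[str, set[str]] = {}
    for codon in canonical_codon_order():
        symbol = code.codon_to_symbol[codon]
        if symbol == STOP_SYMBOL and not include_stops:
            continue
        by_symbol.setdefault(symbol, set()).add(codon)
    ordered = sorted(by_symbol, key=lambda s: (s == STOP_SYMBOL, s))
    return DegeneracyFamilies(
        table_id=code.table_id,
        include_stops=include_stops,
        families=tuple((s, frozenset(by_symbol[s])) for s in ordered),
    )
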