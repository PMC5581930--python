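"""Database organization and taxonomy-aware aggregation.

Per-CDS count tables are grouped into a :class:`CutDatabase` keyed by
``(entity_key, compartment)``.  The entity key follows the source archive's
semantics: *species* mode merges every submission of one organism under its
scientific name (GenBank behaviour), *assembly* mode keeps each assembly
accession separate (RefSeq behaviour).  Organellar compartments always get
their own tables; plasmid CDSs fold into the genomic table.

A taxonomy loaded from NCBI taxdump-dialect ``nodes.dmp``/``names.dmp``
files supports clade queries: *deep search* merges a node's own tables with
every descendant's, *shallow search* returns the node's own tables only.
Clade merges sum raw counts, never averages of frequencies, so total codon
counts are conserved.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from .counting import CodonCountTable, count_codons, merge_tables
from .genbank_io import CdsRecord, Compartment

logger = logging.getLogger(__name__)

__all__ = [
    "GroupingMode",
    "CutDatabase",
    "TaxonomyNode",
    "Taxonomy",
    "TaxonomyError",
    "NotFoundError",
    "GroupingModeError",
    "build_database",
    "load_taxonomy",
    "deep_search",
    "query",
]

#: Valid grouping modes for a database.
GroupingMode = str
_MODES = ("species", "assembly")


class NotFoundError(KeyError):
    """A query key matched nothing in the database or taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


class GroupingModeError(ValueError):
    """A query used key semantics invalid for the database's grouping mode."""


class TaxonomyError(ValueError):
    """Structurally invalid taxonomy (orphans, cycles, missing root)."""


@dataclass
class CutDatabase:
    """Keyed collection of codon usage tables with one grouping mode."""

    grouping_mode: GroupingMode
    tables: dict[tuple[str, Compartment], CodonCountTable] = field(
        default_factory=dict
    )
    per_cds: dict[tuple[str, Compartment], CodonCountTable] | None = None
    #: entity_key -> taxid, for taxonomy queries.
    entity_taxids: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grouping_mode not in _MODES:
            raise ValueError(
                f"grouping_mode must be one of {_MODES}, got {self.grouping_mode!r}"
            )

    @property
    def entity_keys(self) -> list[str]:
        return sorted({key for key, _ in self.tables})

    def taxid_index(self) -> dict[int, set[str]]:
        """taxid -> entity keys carrying it (several assemblies may share one)."""
        index: dict[int, set[str]] = {}
        for key, taxid in self.entity_taxids.items():
            index.setdefault(taxid, set()).add(key)
        return index


def build_database(
    records: Iterable[CdsRecord],
    grouping_mode: GroupingMode,
    keep_per_cds: bool = False,
) -> CutDatabase:
    """Aggregate included CDS records into per-entity, per-compartment tables.

    Excluded records are skipped silently (their bookkeeping happened at
    extraction).  Records missing the grouping key -- no organism name in
    species mode, no assembly accession in assembly mode -- are skipped
    with a warning, falling back to the record accession in assembly mode
    (a bare record outside any assembly is its own entry).
    """
    db = CutDatabase(grouping_mode=grouping_mode)
    buckets: dict[tuple[str, Compartment], list[CodonCountTable]] = {}
    for rec in records:
        if rec.excluded:
            continue
        if grouping_mode == "species":
            key = rec.organism
            if not key:
                logger.warning(
                    "CDS %s has no organism name; skipped in species mode",
                    rec.entity_key,
                )
                continue
        else:
            key = rec.assembly or rec.accession
        table = count_codons(rec)
        buckets.setdefault((key, rec.compartment), []).append(table)
        if rec.taxid is not None:
            db.entity_taxids.setdefault(key, rec.taxid)
        if keep_per_cds:
            if db.per_cds is None:
                db.per_cds = {}
            db.per_cds[(table.entity_key, rec.compartment)] = table
    for (key, compartment), tables in buckets.items():
        merged = merge_tables(
            tables, entity_key=key, grouping=grouping_mode, compartment=compartment
        )
        merged.taxid = db.entity_taxids.get(key)
        db.tables[(key, compartment)] = merged
    return db


@dataclass
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str
    children: list[int] = field(default_factory=list)

    @property
    def is_root(self) -> bool:
        return self.taxid == self.parent_taxid


class Taxonomy:
    """Navigable taxonomy tree with lookup by taxid and scientific name."""

    def __init__(self, nodes: Mapping[int, TaxonomyNode], root: int):
        self.nodes: dict[int, TaxonomyNode] = dict(nodes)
        self.root = root
        self._by_name: dict[str, list[int]] = {}
        for node in self.nodes.values():
            self._by_name.setdefault(node.scientific_name, []).append(node.taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __getitem__(self, taxid: int) -> TaxonomyNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise NotFoundError(f"taxid {taxid} not in taxonomy") from None

    def taxid_of(self, scientific_name: str) -> int:
        hits = self._by_name.get(scientific_name, [])
        if not hits:
            raise NotFoundError(f"no taxon named {scientific_name!r}")
        if len(hits) > 1:
            raise TaxonomyError(
                f"name {scientific_name!r} is ambiguous: taxids {sorted(hits)}"
            )
        return hits[0]

    def descendants(self, taxid: int) -> Iterator[int]:
        """All taxids strictly below ``taxid`` (pre-order)."""
        stack = list(self[taxid].children)
        while stack:
            tid = stack.pop()
            yield tid
            stack.extend(self.nodes[tid].children)


def _taxdump_fields(line: str) -> list[str]:
    # taxdump dialect: fields separated by "\t|\t", line terminated "\t|"
    return [f.strip() for f in line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")]


def load_taxonomy(
    nodes_stream: str | Path | IO[str],
    names_stream: str | Path | IO[str],
) -> Taxonomy:
    """Load an NCBI taxdump-dialect taxonomy (``nodes.dmp`` + ``names.dmp``).

    Only names of class "scientific name" are used.  Orphan parents, cycles
    or a missing/duplicated root fail the load, naming the offending taxids.
    """

    def _handle(src: str | Path | IO[str]) -> IO[str]:
        return src if hasattr(src, "read") else open(src)  # type: ignore[arg-type]

    nodes: dict[int, TaxonomyNode] = {}
    with _handle(nodes_stream) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _taxdump_fields(line)
            taxid, parent = int(fields[0]), int(fields[1])
            rank = fields[2] if len(fields) > 2 else ""
            nodes[taxid] = TaxonomyNode(
                taxid=taxid, parent_taxid=parent, rank=rank, scientific_name=""
            )
    with _handle(names_stream) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _taxdump_fields(line)
            taxid = int(fields[0])
            name, name_class = fields[1], fields[3] if len(fields) > 3 else ""
            if name_class == "scientific name" and taxid in nodes:
                nodes[taxid].scientific_name = name

    roots = [tid for tid, n in nodes.items() if n.is_root]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root node, found {sorted(roots)}")
    orphans = [
        tid for tid, n in nodes.items() if not n.is_root and n.parent_taxid not in nodes
    ]
    if orphans:
        raise TaxonomyError(f"orphan nodes (parent missing): {sorted(orphans)}")
    for node in nodes.values():
        if not node.is_root:
            nodes[node.parent_taxid].children.append(node.taxid)
    # cycle check: every node must reach the root
    root = roots[0]
    for tid in nodes:
        seen = set()
        cur = tid
        while cur != root:
            if cur in seen:
                raise TaxonomyError(f"cycle involving taxids {sorted(seen)}")
            seen.add(cur)
            cur = nodes[cur].parent_taxid
    return Taxonomy(nodes, root=root)


def deep_search(
    db: CutDatabase,
    taxonomy: Taxonomy,
    taxid: int,
    compartment: Compartment = Compartment.GENOMIC,
    deep: bool = True,
) -> CodonCountTable:
    """Merge the tables of a taxonomy node (and, when deep, its descendants).

    Shallow search (``deep=False``) keeps only entries assigned exactly to
    ``taxid`` -- e.g. *E. coli* submissions with no strain information --
    while deep search folds in every descendant strain and sub-species.
    A node with no tables anywhere below yields the empty table
    (``n_cds=0``) rather than an error.
    """
    node = taxonomy[taxid]  # raises NotFoundError for unknown taxids
    wanted = {taxid}
    if deep:
        wanted.update(taxonomy.descendants(taxid))
    index = db.taxid_index()
    keys = sorted(set().union(*(index.get(t, set()) for t in wanted)) if wanted else ())
    tables = [
        db.tables[(key, compartment)]
        for key in keys
        if (key, compartment) in db.tables
    ]
    label = node.scientific_name or f"taxid:{taxid}"
    merged = merge_tables(
        tables, entity_key=label, grouping="clade", compartment=compartment
    )
    merged.taxid = taxid
    return merged


def _suggest(key: str, candidates: Iterable[str]) -> str:
    near = difflib.get_close_matches(key, list(candidates), n=3, cutoff=0.6)
    return f" (did you mean: {', '.join(near)}?)" if near else ""


def query(
    db: CutDatabase,
    key: str | int,
    compartment: Compartment = Compartment.GENOMIC,
) -> CodonCountTable:
    """Exact-match retrieval by scientific name, taxid, or assembly accession.

    Assembly accessions are only meaningful in assembly mode; querying one
    against a species-mode database is a mode error, not a miss.  Integer
    (or all-digit) keys are treated as taxids.
    """
    if isinstance(key, int) or (isinstance(key, str) and key.isdigit()):
        taxid = int(key)
        hits = sorted(db.taxid_index().get(taxid, ()))
        hits = [k for k in hits if (k, compartment) in db.tables]
        if not hits:
            raise NotFoundError(f"no {compartment.value} table for taxid {taxid}")
        if len(hits) > 1:
            raise NotFoundError(
                f"taxid {taxid} is ambiguous here: entities {hits}; query one directly"
            )
        return db.tables[(hits[0], compartment)]
    looks_like_assembly = key.upper().startswith(("GCF_", "GCA_"))
    if looks_like_assembly and db.grouping_mode == "species":
        raise GroupingModeError(
            f"{key!r} is an assembly accession but this database is grouped "
            "by species; assembly queries need an assembly-mode database"
        )
    if (key, compartment) in db.tables:
        return db.tables[(key, compartment)]
    same_entity = [c.value for (k, c) in db.tables if k == key]
    if same_entity:
        raise NotFoundError(
            f"{key!r} has no {compartment.value} table "
            f"(available: {', '.join(sorted(same_entity))})"
        )
    raise NotFoundError(f"no entry {key!r}{_suggest(key, db.entity_keys)}")
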