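"""GenBank flat-file parsing and CDS extraction.

Records are read with Biopython's GenBank parser, one LOCUS..// chunk at a
time so that a single corrupt record is logged and skipped rather than
aborting the whole file.  Every CDS feature becomes a :class:`CdsRecord`,
either included (with its spliced, strand-resolved, frame-trimmed sequence)
or excluded with an explicit reason:

* ``pseudogene`` -- the feature carries a ``/pseudo`` or ``/pseudogene``
  qualifier;
* ``low_quality`` -- the product is annotated "LOW QUALITY PROTEIN" or an
  ``/exception`` qualifier marks the transcript as corrected relative to
  the genome (both RefSeq markers, individually toggleable);
* ``unextractable`` -- the location references another accession, falls
  outside the record sequence, or otherwise cannot be resolved.

Exclusions are data, not failures: downstream counting simply skips them.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqFeature import SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Compartment",
    "ExclusionReason",
    "SourceMeta",
    "CdsRecord",
    "ParsedEntry",
    "ExtractionConfig",
    "parse_flatfile",
    "extract_cds_records",
    "classify_compartment",
]


class Compartment(str, Enum):
    """Origin of a coding sequence ("DNA type").

    Plasmid CDSs stay ``genomic`` (same tRNA pool and genetic code as the
    chromosome); the plasmid flag is carried separately on the record.
    """

    GENOMIC = "genomic"
    MITOCHONDRIAL = "mitochondrial"
    CHLOROPLAST = "chloroplast"
    PLASTID = "plastid"
    LEUCOPLAST = "leucoplast"
    CHROMOPLAST = "chromoplast"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ExclusionReason(str, Enum):
    NONE = "none"
    PSEUDOGENE = "pseudogene"
    LOW_QUALITY = "low_quality"
    UNEXTRACTABLE = "unextractable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SourceMeta:
    """Record-level metadata shared by all CDS features of one record."""

    accession: str
    organism: str | None = None
    taxid: int | None = None
    division: str | None = None
    organelle: str | None = None
    is_plasmid: bool = False
    assembly: str | None = None


@dataclass
class CdsRecord:
    """One extracted coding sequence with provenance.

    ``sequence`` is already spliced, reverse-complemented when on the minus
    strand, and trimmed so position 0 is the first base of a codon
    (``codon_start`` applied).  Trailing partial codons are kept here and
    dropped at counting time.
    """

    sequence: str
    accession: str
    protein_id: str | None = None
    taxid: int | None = None
    organism: str | None = None
    translation_table: int = 1
    compartment: Compartment = Compartment.GENOMIC
    is_plasmid: bool = False
    assembly: str | None = None
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValueError("excluded flag inconsistent with exclusion_reason")

    @property
    def entity_key(self) -> str:
        """Per-CDS identifier: the protein id when present, else the record accession."""
        return self.protein_id or self.accession


@dataclass
class ParsedEntry:
    """One GenBank record: its source metadata plus the raw CDS features."""

    meta: SourceMeta
    record: SeqRecord
    cds_features: list[SeqFeature] = field(default_factory=list)


@dataclass(frozen=True)
class ExtractionConfig:
    """Toggles for the low-quality rule and division filtering.

    ``division_allowlist`` is metadata-level: records whose GenBank division
    tag is present and not listed are dropped at parse time.  ``None`` keeps
    every division.
    """

    low_quality_product_marker: bool = True
    low_quality_exception_qualifier: bool = True
    division_allowlist: frozenset[str] | None = None


_ORGANELLE_MAP = {
    "mitochondrion": Compartment.MITOCHONDRIAL,
    "mitochondria": Compartment.MITOCHONDRIAL,
    "chloroplast": Compartment.CHLOROPLAST,
    "plastid": Compartment.PLASTID,
    "leucoplast": Compartment.LEUCOPLAST,
    "chromoplast": Compartment.CHROMOPLAST,
}


def classify_compartment(meta: SourceMeta) -> tuple[Compartment, bool]:
    """Map a record's organelle qualifier onto a compartment.

    GenBank writes organelle sub-types as ``"plastid:chloroplast"``; the
    most specific component wins.  Unrecognized organelle strings fall back
    to genomic with a logged warning.  The plasmid qualifier never changes
    the compartment.
    """
    compartment = Compartment.GENOMIC
    if meta.organelle:
        parts = [p.strip().lower() for p in meta.organelle.split(":") if p.strip()]
        for part in reversed(parts):  # most specific sub-type last
            hit = _ORGANELLE_MAP.get(part)
            if hit is None:
                # tolerate prefixes like "plastid:..." wrapping known words
                hit = next(
                    (c for key, c in _ORGANELLE_MAP.items() if key in part), None
                )
            if hit is not None:
                compartment = hit
                break
        else:
            logger.warning(
                "record %s: unrecognized organelle %r, treating as genomic",
                meta.accession,
                meta.organelle,
            )
    return compartment, meta.is_plasmid


def _record_chunks(handle: IO[str]) -> Iterator[str]:
    """Split a flat file into LOCUS..// chunks without parsing them."""
    lines: list[str] = []
    for line in handle:
        lines.append(line)
        if line.startswith("//"):
            yield "".join(lines)
            lines = []
    if any(ln.strip() for ln in lines):
        yield "".join(lines)


def _parse_taxid(qualifiers: dict) -> int | None:
    for xref in qualifiers.get("db_xref", []):
        if xref.lower().startswith("taxon:"):
            try:
                taxid = int(xref.split(":", 1)[1])
            except ValueError:
                return None
            return taxid if taxid > 0 else None
    return None


def _source_meta(record: SeqRecord) -> SourceMeta:
    organism = record.annotations.get("organism") or None
    taxid = None
    organelle = None
    is_plasmid = False
    for feat in record.features:
        if feat.type == "source":
            q = feat.qualifiers
            organism = (q.get("organism") or [organism])[0]
            taxid = _parse_taxid(q)
            organelle = (q.get("organelle") or [None])[0]
            is_plasmid = "plasmid" in q
            break
    assembly = None
    for xref in record.dbxrefs:
        if xref.lower().startswith("assembly:"):
            assembly = xref.split(":", 1)[1].strip()
            break
    return SourceMeta(
        accession=record.id,
        organism=organism,
        taxid=taxid,
        division=record.annotations.get("data_file_division") or None,
        organelle=organelle,
        is_plasmid=is_plasmid,
        assembly=assembly,
    )


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_flatfile(
    source: str | Path | IO[str],
    config: ExtractionConfig | None = None,
) -> Iterator[ParsedEntry]:
    """Parse GenBank flat-file text into one :class:`ParsedEntry` per record.

    Records lacking CDS features still yield an entry (with zero features).
    A record Biopython cannot parse is logged with its LOCUS line and
    skipped; the surrounding file continues to parse.
    """
    config = config or ExtractionConfig()
    handle = _open_text(source)
    for chunk in _record_chunks(handle):
        try:
            record = SeqIO.read(StringIO(chunk), "genbank")
        except Exception as exc:  # noqa: BLE001 - per-record tolerance
            locus = chunk.splitlines()[0][:70] if chunk else "<empty>"
            logger.warning("skipping unparseable record (%s): %s", locus, exc)
            continue
        meta = _source_meta(record)
        if (
            config.division_allowlist is not None
            and meta.division is not None
            and meta.division not in config.division_allowlist
        ):
            logger.info(
                "record %s: division %s not in allow-list, skipped",
                meta.accession,
                meta.division,
            )
            continue
        cds = [f for f in record.features if f.type == "CDS"]
        yield ParsedEntry(meta=meta, record=record, cds_features=cds)


def _is_pseudo(qualifiers: dict) -> bool:
    return "pseudo" in qualifiers or "pseudogene" in qualifiers


def _is_low_quality(qualifiers: dict, config: ExtractionConfig) -> bool:
    if config.low_quality_product_marker:
        for product in qualifiers.get("product", []):
            if product.upper().startswith("LOW QUALITY PROTEIN"):
                return True
    if config.low_quality_exception_qualifier and "exception" in qualifiers:
        return True
    return False


def _extract_sequence(feature: SeqFeature, record: SeqRecord) -> str | None:
    """Resolve a CDS location against its own record; None if impossible."""
    loc = feature.location
    if loc is None:
        return None
    for part in loc.parts:
        if getattr(part, "ref", None):  # points at another accession
            return None
        if int(part.end) > len(record.seq) or int(part.start) < 0:
            return None
    try:
        return str(loc.extract(record.seq)).upper()
    except Exception:  # noqa: BLE001 - any resolution failure is an exclusion
        return None


def extract_cds_records(
    entry: ParsedEntry,
    config: ExtractionConfig | None = None,
) -> list[CdsRecord]:
    """Apply the inclusion/exclusion rules to every CDS feature of a record.

    Count conservation holds: one :class:`CdsRecord` per CDS feature, with
    exclusions represented in-band rather than dropped.
    """
    config = config or ExtractionConfig()
    compartment, is_plasmid = classify_compartment(entry.meta)
    out: list[CdsRecord] = []
    for feature in entry.cds_features:
        q = feature.qualifiers
        protein_id = (q.get("protein_id") or [None])[0]
        try:
            table = int((q.get("transl_table") or ["1"])[0])
        except ValueError:
            table = 1
        common = dict(
            accession=entry.meta.accession,
            protein_id=protein_id,
            taxid=entry.meta.taxid,
            organism=entry.meta.organism,
            translation_table=table,
            compartment=compartment,
            is_plasmid=is_plasmid,
            assembly=entry.meta.assembly,
        )
        if _is_pseudo(q):
            out.append(
                CdsRecord(
                    sequence="",
                    excluded=True,
                    exclusion_reason=ExclusionReason.PSEUDOGENE,
                    **common,
                )
            )
            continue
        if _is_low_quality(q, config):
            out.append(
                CdsRecord(
                    sequence="",
                    excluded=True,
                    exclusion_reason=ExclusionReason.LOW_QUALITY,
                    **common,
                )
            )
            continue
        seq = _extract_sequence(feature, entry.record)
        if seq is None:
            out.append(
                CdsRecord(
                    sequence="",
                    excluded=True,
                    exclusion_reason=ExclusionReason.UNEXTRACTABLE,
                    **common,
                )
            )
            continue
        if "transl_except" in q:
            logger.info(
                "record %s CDS %s: transl_except ignored for codon counting",
                entry.meta.accession,
                protein_id or feature.location,
            )
        try:
            codon_start = int((q.get("codon_start") or ["1"])[0])
        except ValueError:
            codon_start = 1
        if codon_start in (2, 3):
            seq = seq[codon_start - 1 :]
        out.append(CdsRecord(sequence=seq, **common))
    return out


def extract_all(
    sources: Iterable[str | Path | IO[str]] | str | Path | IO[str],
    config: ExtractionConfig | None = None,
) -> Iterator[CdsRecord]:
    """Convenience: parse one or more flat files and yield every CdsRecord."""
    if isinstance(sources, (str, Path)) or hasattr(sources, "read"):
        sources = [sources]  # type: ignore[list-item]
    for source in sources:  # type: ignore[union-attr]
        for entry in parse_flatfile(source, config):
            yield from extract_cds_records(entry, config)
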