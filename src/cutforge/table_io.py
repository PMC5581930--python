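"""Readers and writers for codon-usage text formats.

Two dialects:

* **CUT text block** -- the per-organism plain-text table (codon, frequency
  per 1000, raw count; 64 lines in canonical NCBI codon order).  This is the
  paste-compatible format downstream codon tools accept.
* **Bulk TSV** -- one row per table, 5 metadata columns plus the 64 count
  columns, with a versioned format line on top so future dialects stay
  parseable.

Writers are pure functions of their inputs: no timestamps, fixed sort
order, LF line endings, UTF-8 -- identical input yields byte-identical
output.  Frequencies are printed at 2 decimals for display; the integer
counts are authoritative on re-read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .aggregation import CutDatabase
from .bias_stats import GcProfile, enc_all_codes, gc_profile
from .counting import CodonCountTable, frequencies_per_1000
from .genbank_io import Compartment
from .genetic_codes import canonical_codon_order

__all__ = [
    "CutFormatError",
    "write_cut_text",
    "read_cut_text",
    "write_bulk_tsv",
    "read_bulk_tsv",
    "CompareReport",
    "compare_report",
]

_BULK_MAGIC = "#cutforge-bulk"
_BULK_VERSION = "v1"
_META_COLUMNS = ("entity_key", "taxid", "compartment", "n_cds", "n_codons")


class CutFormatError(ValueError):
    """Malformed codon-usage file; the message carries the line number."""


def write_cut_text(table: CodonCountTable) -> str:
    """Render one table as a plain-text codon usage block."""
    freqs = frequencies_per_1000(table)
    lines = [
        f"# entity\t{table.entity_key}",
        f"# compartment\t{table.compartment.value}",
        f"# n_cds\t{table.n_cds}",
        f"# n_codons\t{table.n_codons}",
        "# transl_table\t"
        + ("mixed" if table.translation_table is None else str(table.translation_table)),
    ]
    for codon, freq in zip(canonical_codon_order(), freqs):
        lines.append(f"{codon}\t{freq:.2f}\t{table.counts[codon]}")
    return "\n".join(lines) + "\n"


def read_cut_text(text: str) -> CodonCountTable:
    """Parse a CUT text block; counts are recovered exactly, frequencies ignored."""
    header: dict[str, str] = {}
    counts: dict[str, int] = {}
    body_lines = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t", 1)
            if len(parts) == 2:
                header[parts[0].strip()] = parts[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise CutFormatError(f"line {lineno}: expected 3 tab-separated fields")
        codon, _freq, count = fields
        if codon not in canonical_codon_order():
            raise CutFormatError(f"line {lineno}: {codon!r} is not a codon")
        if codon in counts:
            raise CutFormatError(f"line {lineno}: duplicate codon {codon}")
        try:
            n = int(count)
        except ValueError:
            raise CutFormatError(
                f"line {lineno}: count {count!r} is not an integer"
            ) from None
        if n < 0:
            raise CutFormatError(f"line {lineno}: negative count")
        counts[codon] = n
        body_lines += 1
    if body_lines != 64:
        raise CutFormatError(f"expected 64 codon lines, found {body_lines}")
    transl_raw = header.get("transl_table", "1")
    return CodonCountTable(
        counts=counts,
        entity_key=header.get("entity", ""),
        compartment=Compartment(header.get("compartment", "genomic")),
        n_cds=int(header.get("n_cds", "0")),
        grouping=header.get("grouping", "species"),
        translation_table=None if transl_raw == "mixed" else int(transl_raw),
    )


def _bulk_rows(
    tables: Iterable[CodonCountTable],
) -> Iterable[str]:
    order = canonical_codon_order()
    for t in sorted(tables, key=lambda t: (t.entity_key, t.compartment.value)):
        meta = [
            t.entity_key,
            "" if t.taxid is None else str(t.taxid),
            t.compartment.value,
            str(t.n_cds),
            str(t.n_codons),
        ]
        yield "\t".join(meta + [str(t.counts[c]) for c in order])


def write_bulk_tsv(
    db: CutDatabase,
    dest: str | Path | IO[str],
    per_cds: bool = False,
) -> None:
    """Write a whole database as one tabular text file.

    ``per_cds=True`` dumps the per-CDS tables instead of the per-entity
    ones (the database must have been built with ``keep_per_cds``).  Rows
    are sorted by entity key then compartment for determinism.
    """
    if per_cds:
        if db.per_cds is None:
            raise ValueError("database was built without per-CDS tables")
        tables = db.per_cds.values()
        grouping = "cds"
    else:
        tables = db.tables.values()
        grouping = db.grouping_mode
    lines = [
        f"{_BULK_MAGIC}\t{_BULK_VERSION}\tgrouping={grouping}",
        "\t".join(_META_COLUMNS + canonical_codon_order()),
    ]
    lines.extend(_bulk_rows(tables))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)  # type: ignore[union-attr]
    else:
        Path(dest).write_text(text, encoding="utf-8")


def read_bulk_tsv(source: str | Path | IO[str]) -> CutDatabase:
    """Read a bulk TSV dump back into a :class:`CutDatabase`.

    A per-CDS dump loads as an assembly-mode database whose tables carry
    ``grouping="cds"``.
    """
    text = (
        source.read()  # type: ignore[union-attr]
        if hasattr(source, "read")
        else Path(source).read_text(encoding="utf-8")
    )
    lines = text.splitlines()
    if not lines or not lines[0].startswith(_BULK_MAGIC):
        raise CutFormatError("line 1: missing bulk format line")
    fields = lines[0].split("\t")
    if len(fields) < 3 or fields[1] != _BULK_VERSION:
        raise CutFormatError(f"line 1: unsupported bulk dialect {lines[0]!r}")
    grouping = fields[2].removeprefix("grouping=")
    if len(lines) < 2:
        raise CutFormatError("line 2: missing column header")
    order = canonical_codon_order()
    expected_header = "\t".join(_META_COLUMNS + order)
    if lines[1] != expected_header:
        raise CutFormatError("line 2: column header does not match dialect v1")
    mode = grouping if grouping in ("species", "assembly") else "assembly"
    db = CutDatabase(grouping_mode=mode)
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(_META_COLUMNS) + 64:
            raise CutFormatError(
                f"line {lineno}: expected {len(_META_COLUMNS) + 64} columns, "
                f"got {len(cols)}"
            )
        key, taxid_s, comp_s, n_cds_s, n_codons_s = cols[:5]
        try:
            counts = {c: int(v) for c, v in zip(order, cols[5:])}
            n_cds = int(n_cds_s)
            n_codons = int(n_codons_s)
            taxid = int(taxid_s) if taxid_s else None
        except ValueError:
            raise CutFormatError(f"line {lineno}: non-integer count field") from None
        table = CodonCountTable(
            counts=counts,
            entity_key=key,
            compartment=Compartment(comp_s),
            n_cds=n_cds,
            grouping=grouping,
            taxid=taxid,
        )
        if table.n_codons != n_codons:
            raise CutFormatError(
                f"line {lineno}: n_codons column ({n_codons}) does not match "
                f"count sum ({table.n_codons})"
            )
        slot = (key, table.compartment)
        if slot in db.tables:
            raise CutFormatError(f"line {lineno}: duplicate entry {slot}")
        db.tables[slot] = table
        if taxid is not None:
            db.entity_taxids.setdefault(key, taxid)
    return db


@dataclass
class CompareReport:
    """Aligned multi-query comparison: frequencies, GC profiles, ENc table."""

    #: 64 x n frequency-per-1000 matrix, rows in canonical codon order.
    frequency_matrix: pd.DataFrame
    #: one GcProfile per query, keyed like the matrix columns.
    gc_profiles: dict[str, GcProfile]
    #: rows = translation table ids, columns = queries; NaN where a code failed.
    enc_table: pd.DataFrame

    def to_tsv(self) -> str:
        """Deterministic TSV bundle (three sections) for files or stdout."""
        gc_rows = pd.DataFrame(
            {
                key: [p.gc_overall, *p.gc_pos]
                for key, p in self.gc_profiles.items()
            },
            index=["gc_overall", "gc_pos1", "gc_pos2", "gc_pos3"],
        )
        sections = [
            "## codon frequencies per 1000",
            self.frequency_matrix.to_csv(sep="\t", float_format="%.2f").rstrip("\n"),
            "## GC profile",
            gc_rows.to_csv(sep="\t", float_format="%.4f").rstrip("\n"),
            "## ENc per genetic code",
            self.enc_table.to_csv(sep="\t", float_format="%.2f").rstrip("\n"),
        ]
        return "\n".join(sections) + "\n"


def compare_report(
    tables: Sequence[CodonCountTable],
    include_stops: bool = True,
) -> CompareReport:
    """Build the multi-query comparison bundle for >= 1 tables.

    Columns are labelled ``entity_key`` (disambiguated with the compartment
    when one key appears twice).  ENc is evaluated under every supported
    genetic code per query; inestimable combinations are left blank.
    """
    if not tables:
        raise ValueError("compare_report needs at least one table")
    labels: list[str] = []
    seen: set[str] = set()
    for t in tables:
        label = t.entity_key
        if label in seen:
            label = f"{label} ({t.compartment.value})"
        seen.add(label)
        labels.append(label)
    order = canonical_codon_order()
    freq = pd.DataFrame(
        {lab: frequencies_per_1000(t) for lab, t in zip(labels, tables)},
        index=list(order),
    )
    gc = {lab: gc_profile(t) for lab, t in zip(labels, tables)}
    enc_cols = {}
    for lab, t in zip(labels, tables):
        results, _failures = enc_all_codes(t, include_stops=include_stops)
        enc_cols[lab] = {tid: r.enc for tid, r in results.items()}
    enc_df = pd.DataFrame(enc_cols)
    enc_df.index.name = "transl_table"
    return CompareReport(frequency_matrix=freq, gc_profiles=gc, enc_table=enc_df)
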