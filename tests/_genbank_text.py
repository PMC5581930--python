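"""Hand-rolled GenBank flat-file text for parser tests.

Deliberately independent of the package's fixture generator (which writes
through Biopython): these templates are assembled by plain string
formatting, so parser tests cannot inherit a writer bug.
"""

from __future__ import annotations

_Q_INDENT = " " * 21


def _qualifier_lines(qualifiers: dict[str, object]) -> list[str]:
    lines = []
    for key, value in qualifiers.items():
        if value is None:
            lines.append(f"{_Q_INDENT}/{key}")
        elif isinstance(value, int):
            lines.append(f"{_Q_INDENT}/{key}={value}")
        else:
            lines.append(f'{_Q_INDENT}/{key}="{value}"')
    return lines


def _origin_lines(seq: str) -> list[str]:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return lines


def genbank_text(
    seq: str,
    cds_blocks: list[tuple[str, dict[str, object]]],
    organism: str = "Testus examplius",
    taxid: int | None = 77,
    organelle: str | None = None,
    plasmid: str | None = None,
    division: str = "BCT",
    accession: str = "TEST01",
    assembly: str | None = None,
) -> str:
    """One complete LOCUS..// record with a source feature and given CDSs."""
    src: dict[str, object] = {"organism": organism, "mol_type": "genomic DNA"}
    if taxid is not None:
        src["db_xref"] = f"taxon:{taxid}"
    if organelle is not None:
        src["organelle"] = organelle
    if plasmid is not None:
        src["plasmid"] = plasmid

    lines = [
        f"LOCUS       {accession}{len(seq):>{30 - len(accession)}} bp    DNA"
        f"     linear   {division} 01-JAN-2000",
        "DEFINITION  synthetic parser-test record.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
    ]
    if assembly is not None:
        lines.append(f"DBLINK      Assembly: {assembly}")
    lines += [
        "KEYWORDS    .",
        f"SOURCE      {organism}",
        f"  ORGANISM  {organism}",
        "            Bacteria.",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
        *_qualifier_lines(src),
    ]
    for location, qualifiers in cds_blocks:
        lines.append(f"     CDS             {location}")
        lines.extend(_qualifier_lines(qualifiers))
    lines.append("ORIGIN")
    lines.extend(_origin_lines(seq))
    lines.append("//")
    return "\n".join(lines) + "\n"
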