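"""Synthetic GenBank flat files with known ground truth.

Every pipeline stage is testable without downloads: the generator emits
GenBank records through Biopython's writer (so third-party parsers accept
them) while recording, by construction, exactly which codons it wrote and
which inclusion/exclusion rule applies to each CDS.  The resulting
:class:`TruthSidecar` is the oracle an end-to-end run is compared against.

Generated features exercise the annotation quirks the extractor must
handle: ``join`` locations (introns splitting codons at arbitrary bases),
minus-strand CDSs, ``codon_start`` 2/3 frame offsets, trailing partial
codons, injected IUPAC-ambiguous bases, ``/pseudo`` pseudogenes,
"LOW QUALITY PROTEIN" / ``/exception`` markers, locations referencing
foreign accessions, organelle qualifiers and plasmid replicons.

All randomness flows from one integer seed through a private NumPy
generator; the same spec and seed always reproduce the same file and
sidecar, byte for byte.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .counting import CodonCountTable
from .genbank_io import Compartment, ExclusionReason
from .genetic_codes import canonical_codon_order

__all__ = [
    "OrganismSpec",
    "GenomeSpec",
    "CdsTruth",
    "TruthSidecar",
    "synth_flatfile",
    "synth_taxonomy",
    "demo_spec",
]

_AMBIG_LETTERS = "NRYSWKMBDHV"

_ORGANELLE_QUALIFIER = {
    Compartment.MITOCHONDRIAL: "mitochondrion",
    Compartment.CHLOROPLAST: "plastid:chloroplast",
    Compartment.PLASTID: "plastid",
    Compartment.LEUCOPLAST: "plastid:leucoplast",
    Compartment.CHROMOPLAST: "plastid:chromoplast",
}


@dataclass
class OrganismSpec:
    """Generation parameters for one synthetic organism.

    Fractions are probabilities per CDS; ``ambiguous_rate`` is per codon.
    ``codon_weights`` are multinomial weights over the 64 codons in
    canonical order; ``None`` draws a moderately biased composition
    (Dirichlet, concentration 5) from the genome seed, mimicking the
    uneven synonymous usage of real genomes.
    """

    name: str
    taxid: int
    assembly: str | None = None
    n_cds: int = 50
    codon_weights: Sequence[float] | None = None
    compartment_weights: Mapping[Compartment, float] = field(
        default_factory=lambda: {Compartment.GENOMIC: 1.0}
    )
    plasmid_fraction: float = 0.0
    pseudogene_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    unextractable_fraction: float = 0.0
    ambiguous_rate: float = 0.0
    complement_fraction: float = 0.0
    join_fraction: float = 0.0
    codon_start_fraction: float = 0.0
    trailing_partial_fraction: float = 0.0
    translation_table: int = 1
    cds_len_range: tuple[int, int] = (20, 60)
    division: str = "BCT"
    parent_taxid: int | None = None
    rank: str = "species"

    def validate(self) -> None:
        for attr in (
            "plasmid_fraction",
            "pseudogene_fraction",
            "low_quality_fraction",
            "unextractable_fraction",
            "ambiguous_rate",
            "complement_fraction",
            "join_fraction",
            "codon_start_fraction",
            "trailing_partial_fraction",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if (
            self.pseudogene_fraction
            + self.low_quality_fraction
            + self.unextractable_fraction
        ) > 1.0:
            raise ValueError(f"{self.name}: exclusion fractions sum above 1")
        if self.n_cds < 0:
            raise ValueError(f"{self.name}: negative n_cds")
        if self.codon_weights is not None:
            w = np.asarray(self.codon_weights, dtype=float)
            if w.shape != (64,) or (w < 0).any() or w.sum() == 0:
                raise ValueError(
                    f"{self.name}: codon_weights must be 64 non-negative "
                    "values, not all zero"
                )
        lo, hi = self.cds_len_range
        if not 1 <= lo <= hi:
            raise ValueError(f"{self.name}: bad cds_len_range {self.cds_len_range}")
        if not sum(self.compartment_weights.values()) > 0:
            raise ValueError(f"{self.name}: compartment_weights sum to zero")


@dataclass
class GenomeSpec:
    """A reproducible multi-organism study: one seed, many organisms."""

    seed: int
    organisms: list[OrganismSpec]

    def validate(self) -> None:
        if not self.organisms:
            raise ValueError("GenomeSpec needs at least one organism")
        names = [o.name for o in self.organisms]
        taxids = [o.taxid for o in self.organisms]
        if len(set(names)) != len(names) or len(set(taxids)) != len(taxids):
            raise ValueError("organism names and taxids must be unique")
        for org in self.organisms:
            org.validate()


@dataclass
class CdsTruth:
    """Ground truth for one generated CDS feature."""

    record_accession: str
    protein_id: str
    organism: str
    assembly: str
    taxid: int
    compartment: Compartment
    is_plasmid: bool
    translation_table: int
    excluded: bool
    exclusion_reason: ExclusionReason
    counts: dict[str, int]  # post-exclusion, post-ambiguity expectation


@dataclass
class TruthSidecar:
    """Expected pipeline output, computed by construction at generation time."""

    rows: list[CdsTruth] = field(default_factory=list)

    def exclusion_tallies(self) -> dict[str, int]:
        tally = Counter(
            row.exclusion_reason.value for row in self.rows if row.excluded
        )
        return dict(tally)

    def expected_tables(
        self, grouping: str
    ) -> dict[tuple[str, Compartment], CodonCountTable]:
        """Expected per-entity tables under a grouping mode (species | assembly | cds)."""
        if grouping not in ("species", "assembly", "cds"):
            raise ValueError(f"unknown grouping {grouping!r}")
        buckets: dict[tuple[str, Compartment], list[CdsTruth]] = {}
        for row in self.rows:
            if row.excluded:
                continue
            key = {
                "species": row.organism,
                "assembly": row.assembly,
                "cds": row.protein_id,
            }[grouping]
            buckets.setdefault((key, row.compartment), []).append(row)
        out: dict[tuple[str, Compartment], CodonCountTable] = {}
        for (key, compartment), rows in buckets.items():
            counts: Counter[str] = Counter()
            for row in rows:
                counts.update(row.counts)
            tables = {row.translation_table for row in rows}
            taxids = {row.taxid for row in rows}
            out[(key, compartment)] = CodonCountTable(
                counts=dict(counts),
                entity_key=key,
                compartment=compartment,
                n_cds=len(rows),
                grouping=grouping,
                translation_table=tables.pop() if len(tables) == 1 else None,
                taxid=taxids.pop() if len(taxids) == 1 else None,
            )
        return out

    def to_tsv(self) -> str:
        order = canonical_codon_order()
        lines = [
            "\t".join(
                (
                    "record_accession",
                    "protein_id",
                    "organism",
                    "assembly",
                    "taxid",
                    "compartment",
                    "is_plasmid",
                    "transl_table",
                    "excluded",
                    "reason",
                )
                + order
            )
        ]
        for row in self.rows:
            lines.append(
                "\t".join(
                    [
                        row.record_accession,
                        row.protein_id,
                        row.organism,
                        row.assembly,
                        str(row.taxid),
                        row.compartment.value,
                        str(int(row.is_plasmid)),
                        str(row.translation_table),
                        str(int(row.excluded)),
                        row.exclusion_reason.value,
                    ]
                    + [str(row.counts.get(c, 0)) for c in order]
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TruthSidecar":
        order = canonical_codon_order()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        rows = []
        for line in lines[1:]:
            cols = line.split("\t")
            meta, counts = cols[:10], cols[10:]
            rows.append(
                CdsTruth(
                    record_accession=meta[0],
                    protein_id=meta[1],
                    organism=meta[2],
                    assembly=meta[3],
                    taxid=int(meta[4]),
                    compartment=Compartment(meta[5]),
                    is_plasmid=bool(int(meta[6])),
                    translation_table=int(meta[7]),
                    excluded=bool(int(meta[8])),
                    exclusion_reason=ExclusionReason(meta[9]),
                    counts={
                        c: int(v) for c, v in zip(order, counts) if int(v)
                    },
                )
            )
        return cls(rows=rows)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@dataclass
class _PlannedCds:
    feature_seq: str  # what extraction must yield before codon_start trimming
    codon_start: int
    qualifiers: dict[str, list[str]]
    truth: CdsTruth
    strand: int
    n_exons: int
    unextractable: bool


def _plan_cds(
    rng: np.random.Generator,
    org: OrganismSpec,
    weights: np.ndarray,
    protein_id: str,
    compartment: Compartment,
    is_plasmid: bool,
) -> _PlannedCds:
    order = canonical_codon_order()
    m = int(rng.integers(org.cds_len_range[0], org.cds_len_range[1] + 1))
    codons = [order[i] for i in rng.choice(64, size=m, p=weights)]

    u = rng.random()
    reason = ExclusionReason.NONE
    if u < org.pseudogene_fraction:
        reason = ExclusionReason.PSEUDOGENE
    elif u < org.pseudogene_fraction + org.low_quality_fraction:
        reason = ExclusionReason.LOW_QUALITY
    elif u < (
        org.pseudogene_fraction
        + org.low_quality_fraction
        + org.unextractable_fraction
    ):
        reason = ExclusionReason.UNEXTRACTABLE

    # ambiguity injection: pick codons, replace one base each with an IUPAC letter
    written: list[str] = []
    clean: Counter[str] = Counter()
    for codon in codons:
        if org.ambiguous_rate and rng.random() < org.ambiguous_rate:
            pos = int(rng.integers(0, 3))
            letter = _AMBIG_LETTERS[int(rng.integers(0, len(_AMBIG_LETTERS)))]
            written.append(codon[:pos] + letter + codon[pos + 1 :])
        else:
            written.append(codon)
            clean[codon] += 1

    codon_start = 1
    if org.codon_start_fraction and rng.random() < org.codon_start_fraction:
        codon_start = int(rng.integers(2, 4))
    pad = _random_bases(rng, codon_start - 1)
    tail = ""
    if org.trailing_partial_fraction and rng.random() < org.trailing_partial_fraction:
        tail = _random_bases(rng, int(rng.integers(1, 3)))
    feature_seq = pad + "".join(written) + tail

    strand = -1 if rng.random() < org.complement_fraction else 1
    n_exons = 1
    if org.join_fraction and rng.random() < org.join_fraction and len(feature_seq) > 6:
        n_exons = int(rng.integers(2, 4))

    qualifiers: dict[str, list[str]] = {
        "protein_id": [protein_id],
        "transl_table": [str(org.translation_table)],
        "codon_start": [str(codon_start)],
        "product": ["hypothetical protein"],
    }
    if reason is ExclusionReason.PSEUDOGENE:
        qualifiers["pseudo"] = [None]  # bare /pseudo qualifier
    elif reason is ExclusionReason.LOW_QUALITY:
        if rng.random() < 0.5:
            qualifiers["product"] = ["LOW QUALITY PROTEIN hypothetical protein"]
        else:
            qualifiers["exception"] = ["annotated by transcript or proteomic data"]

    excluded = reason is not ExclusionReason.NONE
    truth = CdsTruth(
        record_accession="",  # filled at record assembly
        protein_id=protein_id,
        organism=org.name,
        assembly=org.assembly or "",
        taxid=org.taxid,
        compartment=compartment,
        is_plasmid=is_plasmid,
        translation_table=org.translation_table,
        excluded=excluded,
        exclusion_reason=reason,
        counts={} if excluded else dict(clean),
    )
    return _PlannedCds(
        feature_seq=feature_seq,
        codon_start=codon_start,
        qualifiers=qualifiers,
        truth=truth,
        strand=strand,
        n_exons=n_exons,
        unextractable=reason is ExclusionReason.UNEXTRACTABLE,
    )


def _place_cds(
    rng: np.random.Generator,
    segments: list[str],
    offset: int,
    planned: _PlannedCds,
) -> tuple[SeqFeature, int]:
    """Append genome segments for one CDS and build its feature location."""
    if planned.unextractable:
        # location points at a foreign accession; no sequence is placed
        loc = SimpleLocation(
            0, len(planned.feature_seq), strand=planned.strand, ref="SYNEXT01"
        )
        return SeqFeature(loc, type="CDS", qualifiers=planned.qualifiers), offset

    fseq = planned.feature_seq
    if planned.n_exons > 1:
        cuts = sorted(
            int(c)
            for c in rng.choice(
                np.arange(1, len(fseq)), size=planned.n_exons - 1, replace=False
            )
        )
        exons = [
            fseq[a:b] for a, b in zip([0, *cuts], [*cuts, len(fseq)])
        ]
    else:
        exons = [fseq]

    spacer = _random_bases(rng, int(rng.integers(10, 31)))
    segments.append(spacer)
    offset += len(spacer)

    parts: list[SimpleLocation] = []
    if planned.strand == 1:
        for i, exon in enumerate(exons):
            if i:
                intron = _random_bases(rng, int(rng.integers(5, 41)))
                segments.append(intron)
                offset += len(intron)
            parts.append(SimpleLocation(offset, offset + len(exon), 1))
            segments.append(exon)
            offset += len(exon)
    else:
        # genome order holds reverse-complemented exons, last exon first
        for i, exon in enumerate(reversed(exons)):
            if i:
                intron = _random_bases(rng, int(rng.integers(5, 41)))
                segments.append(intron)
                offset += len(intron)
            parts.append(SimpleLocation(offset, offset + len(exon), -1))
            segments.append(reverse_complement(exon))
            offset += len(exon)
        parts.reverse()  # biological (extraction) order: first exon first
    loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
    return SeqFeature(loc, type="CDS", qualifiers=planned.qualifiers), offset


def _build_record(
    rng: np.random.Generator,
    org: OrganismSpec,
    accession: str,
    compartment: Compartment,
    is_plasmid: bool,
    planned: list[_PlannedCds],
) -> SeqRecord:
    segments: list[str] = []
    offset = 0
    features: list[SeqFeature] = []
    for p in planned:
        feat, offset = _place_cds(rng, segments, offset, p)
        features.append(feat)
        p.truth.record_accession = f"{accession}.1"
    tail = _random_bases(rng, int(rng.integers(10, 31)))
    segments.append(tail)
    seq = Seq("".join(segments))

    src_qualifiers: dict[str, list[str]] = {
        "organism": [org.name],
        "mol_type": ["genomic DNA"],
        "db_xref": [f"taxon:{org.taxid}"],
    }
    if compartment is not Compartment.GENOMIC:
        src_qualifiers["organelle"] = [_ORGANELLE_QUALIFIER[compartment]]
    if is_plasmid:
        src_qualifiers["plasmid"] = [f"p{accession}"]
    source = SeqFeature(SimpleLocation(0, len(seq), 1), type="source",
                        qualifiers=src_qualifiers)

    record = SeqRecord(
        seq,
        id=f"{accession}.1",
        name=accession,
        description=f"{org.name} synthetic {compartment.value} sequence",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"
    record.annotations["data_file_division"] = org.division
    record.annotations["organism"] = org.name
    record.annotations["source"] = org.name
    record.annotations["accessions"] = [accession]
    if org.assembly:
        record.dbxrefs = [f"Assembly:{org.assembly}"]
    record.features = [source, *features]

    # internal consistency: every placed location must extract to its
    # planned feature sequence (guards the generator, not the parser)
    for feat, p in zip(features, planned):
        if not p.unextractable:
            got = str(feat.location.extract(seq))
            if got != p.feature_seq:
                raise AssertionError(
                    f"fixture generator bug: {accession} extraction mismatch"
                )
    return record


def synth_flatfile(spec: GenomeSpec) -> tuple[str, TruthSidecar]:
    """Generate a GenBank flat file plus its ground-truth sidecar.

    One record per replicon: each organism gets a main genomic record,
    plus separate records for plasmids and for each organellar
    compartment that received CDSs.  Deterministic in ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sidecar = TruthSidecar()
    records: list[SeqRecord] = []

    for org_idx, org in enumerate(spec.organisms):
        if org.assembly is None:
            org = replace(org, assembly=f"GCF_{900000000 + org_idx:09d}.1")
        if org.codon_weights is None:
            weights = rng.dirichlet(np.full(64, 5.0))
        else:
            w = np.asarray(org.codon_weights, dtype=float)
            weights = w / w.sum()

        comps = list(org.compartment_weights)
        probs = np.array([org.compartment_weights[c] for c in comps], dtype=float)
        probs = probs / probs.sum()

        by_replicon: dict[tuple[Compartment, bool], list[_PlannedCds]] = {}
        for cds_idx in range(org.n_cds):
            compartment = comps[int(rng.choice(len(comps), p=probs))]
            is_plasmid = (
                compartment is Compartment.GENOMIC
                and org.plasmid_fraction > 0
                and rng.random() < org.plasmid_fraction
            )
            protein_id = f"SYP{org_idx:03d}{cds_idx:05d}.1"
            planned = _plan_cds(rng, org, weights, protein_id, compartment, is_plasmid)
            by_replicon.setdefault((compartment, is_plasmid), []).append(planned)

        for rep_idx, ((compartment, is_plasmid), planned) in enumerate(
            sorted(by_replicon.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))
        ):
            accession = f"SYN{org_idx:03d}{rep_idx:02d}"
            records.append(
                _build_record(rng, org, accession, compartment, is_plasmid, planned)
            )
            sidecar.rows.extend(p.truth for p in planned)

    buffer = io.StringIO()
    SeqIO.write(records, buffer, "genbank")
    return buffer.getvalue(), sidecar


def synth_taxonomy(
    spec: GenomeSpec | Iterable[tuple[int, int, str, str]],
    root_taxid: int = 1,
) -> tuple[str, str]:
    """Emit taxdump-dialect ``nodes.dmp`` / ``names.dmp`` text.

    Accepts either an explicit node list ``(taxid, parent_taxid, rank,
    scientific_name)`` or a :class:`GenomeSpec`, whose organisms become
    children of the root (or of ``parent_taxid`` when set, letting strain
    nodes hang under their species for deep-search scenarios).
    """
    if isinstance(spec, GenomeSpec):
        nodes = [(root_taxid, root_taxid, "no rank", "root")]
        for org in spec.organisms:
            nodes.append(
                (org.taxid, org.parent_taxid or root_taxid, org.rank, org.name)
            )
    else:
        nodes = list(spec)
    nodes_lines = [
        f"{taxid}\t|\t{parent}\t|\t{rank}\t|" for taxid, parent, rank, _ in nodes
    ]
    names_lines = [
        f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|"
        for taxid, _, _, name in nodes
    ]
    return "\n".join(nodes_lines) + "\n", "\n".join(names_lines) + "\n"


def demo_spec(
    seed: int,
    n_organisms: int = 5,
    n_cds: int = 200,
    noisy: bool = True,
) -> GenomeSpec:
    """A ready-made study spec with every annotation quirk switched on.

    Rates reflect the nuisance levels of real archival data at an
    exaggerated but testable scale: a few percent of CDSs excluded for
    each reason, occasional ambiguous bases, and a large minority of
    minus-strand, spliced, or frame-offset features.  ``noisy=False``
    strips all of that, leaving plain single-exon plus-strand CDSs.
    """
    organisms = []
    for i in range(n_organisms):
        noise = dict(
            plasmid_fraction=0.15,
            pseudogene_fraction=0.05,
            low_quality_fraction=0.05,
            unextractable_fraction=0.03,
            ambiguous_rate=0.02,
            complement_fraction=0.40,
            join_fraction=0.30,
            codon_start_fraction=0.15,
            trailing_partial_fraction=0.10,
            compartment_weights={
                Compartment.GENOMIC: 0.8,
                Compartment.MITOCHONDRIAL: 0.1,
                Compartment.CHLOROPLAST: 0.1,
            },
        ) if noisy else {}
        organisms.append(
            OrganismSpec(
                name=f"Synthetica organismus {i + 1}",
                taxid=1000 + i,
                n_cds=n_cds,
                translation_table=1,
                **noise,
            )
        )
    return GenomeSpec(seed=seed, organisms=organisms)
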