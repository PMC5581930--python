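# Methods

## Pipeline model

cutforge treats codon usage estimation as a four-stage pipeline:

1. **Parse** GenBank flat files record by record (each `LOCUS..//` chunk is
   parsed independently, so one corrupt record is logged and skipped
   without losing the file).
2. **Extract** every CDS feature into a `CdsRecord`: the location is
   resolved against its own record (splicing `join` parts, reverse-
   complementing minus-strand features), and the `codon_start` qualifier
   shifts the reading frame by dropping one or two leading bases.
   Exclusion is represented in-band with a reason rather than by dropping
   records, so counts are conserved and exclusion statistics are data.
3. **Count** codons in non-overlapping triplets from position 0. A triplet
   containing any character outside `ACGT` is skipped individually — the
   rest of the feature still counts — and a trailing partial triplet is
   dropped. Counting, not extraction, applies the truncation, so the
   extracted sequence remains a faithful copy of the annotation.
4. **Aggregate** per-CDS tables into a database keyed by
   `(entity, compartment)`. Species grouping merges all submissions of one
   organism under its scientific name; assembly grouping keeps each
   assembly accession separate. The two conventions mirror how archival
   (per-submission) and curated (per-assembly) collections are organized,
   and the same input produces identical grand totals either way.

### Exclusion rules

* **Pseudogenes**: any `/pseudo` or `/pseudogene` qualifier.
* **Low-quality transcripts** (a corrected base relative to the genome):
  a `/product` beginning `LOW QUALITY PROTEIN`, or the presence of an
  `/exception` qualifier. These are the two concrete annotation markers
  curated archives attach to corrected transcripts; either toggle can be
  disabled via `ExtractionConfig` since `/exception` also covers benign
  cases such as ribosomal slippage.
* **Unextractable features**: locations referencing another accession,
  or falling outside the record's own sequence.

`transl_except` qualifiers are ignored for counting (the codon is counted
as written) and logged. Division filtering is a metadata-level allow-list:
it selects records by their GenBank division tag but involves no download
policy.

### Compartments and plasmids

The `source` feature's `/organelle` qualifier maps case-insensitively onto
five organellar compartments (mitochondrial, chloroplast, plastid,
leucoplast, chromoplast; `plastid:chloroplast`-style subtypes resolve to
the most specific name). Everything else is genomic. Plasmids stay in the
genomic table — they share the cell's tRNA pool and genetic code — but the
flag is preserved per CDS. Organellar tables never merge with genomic
ones; attempting it is an error, not a warning.

### Taxonomy and deep search

`nodes.dmp`/`names.dmp` in the NCBI taxdump dialect load into a validated
tree (single root, no orphans, no cycles; only "scientific name" class
names are used). Deep search merges the queried node's own tables with
every descendant's; shallow search returns the node's own tables only.
Clade merges sum raw integer counts — never averages of frequencies — so
merging is associative, commutative, and conserves total codon counts;
`deep_search(root)` equals the element-wise sum of the whole database per
compartment, which the test suite asserts.

## ENc: genome-wide, stop-inclusive, per genetic code

The effective number of codons is computed once over a genome's pooled
coding sequences. For synonymous family $a$ with counts $n_i$, total
$n_a$, and fractions $p_i = n_i/n_a$:

$$\hat F_a = \frac{n_a \sum_i p_i^2 - 1}{n_a - 1}, \qquad n_a \ge 2$$

Families are grouped by degeneracy $k$; $\bar F_k$ is the mean of the
usable $\hat F_a$ in class $k$, and with $m_k$ the number of $k$-fold
families,

$$N_c = m_1 + \sum_{k \ge 2} \frac{m_k}{\bar F_k}.$$

Stop codons form one family like any amino acid, so for the standard code
the partition has 21 families (degeneracy multiset
$\{1^2, 2^9, 3^2, 4^5, 6^3\}$) and $N_c$ ranges from 21 (one codon per
family) to 64 (uniform usage). The classic 61-codon, 20-family variant is
exposed via `include_stops=False` for comparison with per-gene
implementations. Family structure is derived from the genetic code in use,
so the same machinery covers all 24 supported NCBI translation tables
(tables 27, 28 and 31 are rejected: they assign codons as stop or sense
depending on context and admit no unambiguous 64-codon partition).
`enc_all_codes` evaluates every table and records per-code failures
without failing globally, since archives often omit a genome's code.

Numerical conventions, chosen to keep the estimator defined on real,
sparse data:

* Families with $n_a < 2$, or with $\hat F_a \le 0$ (possible at tiny
  counts), are left out of their class mean but still counted in $m_k$.
* A class with no usable estimate is repaired by interpolating $\bar F_k$
  linearly in $k$ between the nearest defined classes — for the standard
  code's 3-fold class this reduces to $\bar F_3 = (\bar F_2 + \bar F_4)/2$
  — with the $k{=}1$ class anchoring the low end at $F = 1$ and edge
  classes taking the nearest defined value. Repaired classes are reported
  in the result (`repaired_classes`).
* If no class at all has a usable estimate the input is rejected as
  insufficient (`InsufficientDataError`).
* The estimator overshoots its ceiling slightly at low bias (uniform usage
  at 1000 counts/codon gives $64 + 43/999 \approx 64.04$); values above
  the partition size are clamped and flagged `capped`.

The implementation is verified against an independent, literal
transcription of the estimator (families derived separately from the NCBI
table data) on hundreds of random multinomial tables to $10^{-9}$.

## GC profile and RSCU

GC is computed from the count table — after ambiguous-codon filtering —
not from raw sequence, so the GC plot and the frequency table always
describe the same codon population. Position $j$'s GC is the
count-weighted fraction of counted codons with G or C at position $j$;
the overall value is exactly the mean of the three (each codon contributes
three bases, so this equals base-level GC of the counted codons).

RSCU follows the standard definition ($n_i k_a / n_a$ within each family,
stop family included); members of unused families report 0 rather than
NaN, a convention that keeps comparison matrices dense.

## The synthetic-data generator

`fixtures.synth_flatfile` writes GenBank records through Biopython's
writer — so the files are structurally valid for any parser — while
recording ground truth by construction: the generator knows every codon it
drew, which codons it corrupted with ambiguity letters, and which CDSs it
marked for exclusion. The sidecar is therefore an exact oracle, not an
approximation, and the end-to-end test demands table-for-table,
count-for-count equality.

Per organism the generator draws codons from a 64-way multinomial
(default weights: Dirichlet with concentration 5, giving the moderate,
genome-like bias of real coding sequences), splits CDSs across
compartments and plasmid replicons, and injects annotation quirks at
configurable rates. The default noisy study (`demo_spec`) uses 5% each
pseudogene and low-quality CDSs, 3% unextractable locations, 2% ambiguous
codons, 40% minus-strand features, 30% spliced (2–3 exon) locations, 15%
`codon_start` offsets, 10% trailing partial codons, 15% plasmid CDSs, and
an 80/10/10 genomic/mitochondrial/chloroplast compartment mix — nuisance
levels exaggerated well above archival reality so every code path is
exercised in a modest file. CDS lengths are uniform on 20–60 codons.

What the generator does *not* emulate: real gene models (no UTRs, no
biologically meaningful start/stop placement), sequence-level evolution,
between-gene heterogeneity of codon bias within an organism, and archive-
scale metadata variety (one taxid per organism, clean qualifier syntax).
Passing the end-to-end suite therefore demonstrates that the pipeline's
bookkeeping — extraction arithmetic, exclusion rules, grouping, merging —
is exact, not that the statistics are robust to annotation pathologies
beyond those modelled.

## Problem sizes and determinism

The end-to-end equivalence suite runs 50 independently seeded studies of
5 organisms x 200 CDSs (50,000 CDSs total, about 15 s); the ENc oracle
comparison uses 200 random tables of 50–50,000 codons; conservation laws
are checked on 100 random merge triples and a full synthetic study. All
randomness flows from explicit integer seeds through private NumPy
generators; writers emit no timestamps, and identical inputs produce
byte-identical files. The acceptance script derives all of its seeds from
the single `--seed` argument.

## Known limitations

* Low-quality detection rests on two annotation markers; transcripts
  corrected without either marker pass through.
* `transl_except` (e.g. selenocysteine recoding) is counted as written.
* Assembly grouping requires a `DBLINK Assembly:` cross-reference; records
  without one fall back to their own accession as the entity key.
* Name-based queries need exact scientific names (near-misses are
  suggested, not auto-resolved).
* ENc on very sparse tables depends on the documented repair rules; the
  `repaired_classes` and `capped` flags should be inspected before
  comparing such values across genomes.
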