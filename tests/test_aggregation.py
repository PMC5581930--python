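from io import StringIO

import pytest

from cutforge import (
    CdsRecord,
    Compartment,
    GroupingModeError,
    NotFoundError,
    TaxonomyError,
    build_database,
    deep_search,
    load_taxonomy,
    query,
    synth_taxonomy,
)


def cds(seq, organism="Species x", taxid=100, assembly="GCF_1", acc="R1", pid=None,
        compartment=Compartment.GENOMIC, **kwargs):
    return CdsRecord(
        sequence=seq,
        accession=acc,
        protein_id=pid,
        organism=organism,
        taxid=taxid,
        assembly=assembly,
        compartment=compartment,
        **kwargs,
    )


def small_taxonomy(nodes):
    nodes_text, names_text = synth_taxonomy(nodes)
    return load_taxonomy(StringIO(nodes_text), StringIO(names_text))


@pytest.fixture
def strain_world():
    """Species (taxid 10) with two strain children (11, 12) plus an outgroup."""
    taxonomy = small_taxonomy(
        [
            (1, 1, "no rank", "root"),
            (10, 1, "species", "Escherichia coli"),
            (11, 10, "strain", "Escherichia coli K-12"),
            (12, 10, "strain", "Escherichia coli O157"),
            (20, 1, "species", "Bacillus exampli"),
        ]
    )
    records = [
        cds("ATGTAA" * 5, organism="Escherichia coli", taxid=10, assembly="GCF_10"),
        cds("ATGGCC" * 5, organism="Escherichia coli K-12", taxid=11, assembly="GCF_11"),
        cds("GCCGCC" * 10, organism="Escherichia coli O157", taxid=12, assembly="GCF_12"),
        cds("TTTAAA" * 4, organism="Bacillus exampli", taxid=20, assembly="GCF_20"),
    ]
    return taxonomy, records


class TestBuildDatabase:
    def test_species_mode_merges_submissions_of_one_organism(self):
        records = [cds("ATGTAA", acc="R1") for _ in range(3)] + [
            cds("ATGTAA", acc="R2", assembly="GCF_2") for _ in range(2)
        ]
        db = build_database(records, "species")
        table = db.tables[("Species x", Compartment.GENOMIC)]
        assert table.n_cds == 5
        assert table.counts["ATG"] == 5

    def test_assembly_mode_keeps_assemblies_separate(self):
        records = [cds("ATGTAA", acc="R1") for _ in range(3)] + [
            cds("ATGTAA", acc="R2", assembly="GCF_2") for _ in range(2)
        ]
        db = build_database(records, "assembly")
        assert db.tables[("GCF_1", Compartment.GENOMIC)].n_cds == 3
        assert db.tables[("GCF_2", Compartment.GENOMIC)].n_cds == 2

    def test_compartments_get_separate_tables(self):
        records = [
            cds("ATGTAA"),
            cds("ATGTAA", compartment=Compartment.MITOCHONDRIAL),
        ]
        db = build_database(records, "species")
        assert set(db.tables) == {
            ("Species x", Compartment.GENOMIC),
            ("Species x", Compartment.MITOCHONDRIAL),
        }

    def test_plasmid_cds_folds_into_the_genomic_table(self):
        records = [cds("ATGTAA"), cds("CCCGGG", is_plasmid=True)]
        db = build_database(records, "species")
        table = db.tables[("Species x", Compartment.GENOMIC)]
        assert table.n_cds == 2 and table.counts["CCC"] == 1

    def test_excluded_records_do_not_contribute(self):
        from cutforge import ExclusionReason

        records = [
            cds("ATGTAA"),
            cds("", excluded=True, exclusion_reason=ExclusionReason.PSEUDOGENE),
        ]
        db = build_database(records, "species")
        assert db.tables[("Species x", Compartment.GENOMIC)].n_cds == 1

    def test_missing_organism_is_skipped_with_warning_in_species_mode(self, caplog):
        with caplog.at_level("WARNING"):
            db = build_database([cds("ATGTAA", organism=None)], "species")
        assert db.tables == {}
        assert "no organism name" in caplog.text

    def test_input_order_does_not_matter(self):
        records = [
            cds("ATGTAA"),
            cds("CCCTTT"),
            cds("ATGGCG", organism="Species y", taxid=101, assembly="GCF_2"),
        ]
        a = build_database(records, "species")
        b = build_database(records[::-1], "species")
        assert {k: t.counts for k, t in a.tables.items()} == {
            k: t.counts for k, t in b.tables.items()
        }


class TestLoadTaxonomy:
    def test_three_node_chain_structure(self):
        taxonomy = small_taxonomy(
            [
                (1, 1, "no rank", "root"),
                (5, 1, "genus", "Examplea"),
                (6, 5, "species", "Examplea synthetica"),
            ]
        )
        assert taxonomy[6].parent_taxid == 5
        assert taxonomy[5].children == [6]
        assert taxonomy.root == 1

    def test_name_lookup(self):
        taxonomy = small_taxonomy(
            [(1, 1, "no rank", "root"), (562, 1, "species", "Escherichia coli")]
        )
        assert taxonomy.taxid_of("Escherichia coli") == 562
        with pytest.raises(NotFoundError):
            taxonomy.taxid_of("No such organism")

    def test_cycle_is_a_load_error_naming_taxids(self):
        nodes = "1\t|\t1\t|\tno rank\t|\n2\t|\t3\t|\tx\t|\n3\t|\t2\t|\tx\t|\n"
        names = "1\t|\troot\t|\t\t|\tscientific name\t|\n"
        with pytest.raises(TaxonomyError, match="cycle"):
            load_taxonomy(StringIO(nodes), StringIO(names))

    def test_orphan_is_a_load_error(self):
        nodes = "1\t|\t1\t|\tno rank\t|\n2\t|\t99\t|\tx\t|\n"
        names = "1\t|\troot\t|\t\t|\tscientific name\t|\n"
        with pytest.raises(TaxonomyError, match="orphan"):
            load_taxonomy(StringIO(nodes), StringIO(names))

    def test_missing_root_is_a_load_error(self):
        nodes = "2\t|\t3\t|\tx\t|\n3\t|\t2\t|\tx\t|\n"
        names = ""
        with pytest.raises(TaxonomyError, match="root"):
            load_taxonomy(StringIO(nodes), StringIO(names))


class TestDeepSearch:
    def test_deep_search_merges_species_and_strains(self, strain_world):
        taxonomy, records = strain_world
        db = build_database(records, "species")
        merged = deep_search(db, taxonomy, 10, Compartment.GENOMIC)
        assert merged.n_codons == 10 + 10 + 20
        assert merged.grouping == "clade"
        assert merged.entity_key == "Escherichia coli"

    def test_shallow_search_returns_species_level_only(self, strain_world):
        taxonomy, records = strain_world
        db = build_database(records, "species")
        own = deep_search(db, taxonomy, 10, Compartment.GENOMIC, deep=False)
        assert own.n_codons == 10

    def test_leaf_node_deep_equals_shallow(self, strain_world):
        taxonomy, records = strain_world
        db = build_database(records, "species")
        deep = deep_search(db, taxonomy, 11, Compartment.GENOMIC, deep=True)
        shallow = deep_search(db, taxonomy, 11, Compartment.GENOMIC, deep=False)
        assert deep.counts == shallow.counts

    def test_unknown_taxid_is_not_found(self, strain_world):
        taxonomy, records = strain_world
        db = build_database(records, "species")
        with pytest.raises(NotFoundError, match="999"):
            deep_search(db, taxonomy, 999, Compartment.GENOMIC)

    def test_node_with_no_tables_yields_empty_table(self, strain_world):
        taxonomy, records = strain_world
        db = build_database([r for r in records if r.taxid != 20], "species")
        empty = deep_search(db, taxonomy, 20, Compartment.GENOMIC)
        assert empty.n_cds == 0 and empty.n_codons == 0

    def test_root_deep_search_conserves_all_counts(self, strain_world):
        taxonomy, records = strain_world
        db = build_database(records, "species")
        merged = deep_search(db, taxonomy, 1, Compartment.GENOMIC)
        total = sum(t.n_codons for t in db.tables.values())
        assert merged.n_codons == total


class TestQuery:
    def test_query_by_name(self, strain_world):
        _, records = strain_world
        db = build_database(records, "species")
        assert query(db, "Bacillus exampli").counts["TTT"] == 4

    def test_query_by_taxid(self, strain_world):
        _, records = strain_world
        db = build_database(records, "species")
        assert query(db, 20).entity_key == "Bacillus exampli"
        assert query(db, "20").entity_key == "Bacillus exampli"

    def test_assembly_query_in_species_mode_is_a_mode_error(self, strain_world):
        _, records = strain_world
        db = build_database(records, "species")
        with pytest.raises(GroupingModeError, match="assembly"):
            query(db, "GCF_000001405")

    def test_assembly_query_in_assembly_mode(self, strain_world):
        _, records = strain_world
        db = build_database(records, "assembly")
        assert query(db, "GCF_20").counts["AAA"] == 4

    def test_miss_suggests_near_matches(self, strain_world):
        _, records = strain_world
        db = build_database(records, "species")
        with pytest.raises(NotFoundError, match="did you mean"):
            query(db, "Bacilus exampli")

    def test_unrepresented_taxid_is_not_found(self, strain_world):
        _, records = strain_world
        db = build_database(records, "species")
        with pytest.raises(NotFoundError):
            query(db, 4242)
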