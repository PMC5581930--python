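from fractions import Fraction

import numpy as np
import pytest

from cutforge import (
    SUPPORTED_TABLE_IDS,
    InsufficientDataError,
    canonical_codon_order,
    degeneracy_families,
    enc,
    enc_all_codes,
    gc_profile,
    load_genetic_code,
    rscu,
)

from _wright_oracle import wright_enc
from conftest import make_table, random_table


def one_codon_per_family_table(include_stops=True, per_family=1000):
    fams = degeneracy_families(load_genetic_code(1), include_stops=True)
    counts = {}
    for symbol, members in fams.families:
        if symbol == "*" and not include_stops:
            continue
        counts[sorted(members)[0]] = per_family
    return make_table(counts, entity_key="max-bias")


class TestGcProfile:
    def test_single_codon(self):
        p = gc_profile(make_table({"ATG": 1}))
        assert p.gc_pos == (0.0, 0.0, 1.0)
        assert p.gc_overall == pytest.approx(1 / 3)

    def test_all_gc_codon(self):
        p = gc_profile(make_table({"GCG": 2}))
        assert p.gc_pos == (1.0, 1.0, 1.0) and p.gc_overall == 1.0

    def test_uniform_counts_are_half_gc_everywhere(self, uniform_table):
        p = gc_profile(uniform_table)
        assert p.gc_pos == (0.5, 0.5, 0.5) and p.gc_overall == 0.5

    def test_empty_table_is_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            gc_profile(make_table({}))

    def test_overall_is_mean_of_positions(self, rng):
        for _ in range(20):
            p = gc_profile(random_table(rng, n_codons=500))
            assert p.gc_overall == pytest.approx(sum(p.gc_pos) / 3, abs=1e-15)

    def test_matches_base_level_gc_of_concatenated_codons(self, rng):
        """Exact rational-arithmetic check on small tables."""
        for _ in range(10):
            table = random_table(rng, n_codons=60)
            concat = "".join(
                c * n for c, n in table.counts.items() if n
            )
            exact = Fraction(sum(b in "GC" for b in concat), len(concat))
            assert gc_profile(table).gc_overall == pytest.approx(
                float(exact), abs=1e-12
            )


class TestRscu:
    def codon_value(self, values, codon):
        return dict(zip(canonical_codon_order(), values))[codon]

    def test_twofold_family_arithmetic(self):
        values = rscu(make_table({"TTT": 3, "TTC": 1}), load_genetic_code(1))
        assert self.codon_value(values, "TTT") == pytest.approx(1.5)
        assert self.codon_value(values, "TTC") == pytest.approx(0.5)

    def test_uniform_usage_gives_rscu_one_everywhere(self, uniform_table):
        values = rscu(uniform_table, load_genetic_code(1))
        assert np.allclose(values, 1.0)

    def test_unused_families_are_zero(self):
        values = rscu(make_table({"TTT": 3}), load_genetic_code(1))
        assert self.codon_value(values, "ATG") == 0.0
        assert self.codon_value(values, "TAA") == 0.0

    def test_family_sums_equal_degeneracy(self, rng):
        code = load_genetic_code(1)
        fams = degeneracy_families(code, include_stops=True)
        for _ in range(20):
            table = random_table(rng)
            by_codon = dict(zip(canonical_codon_order(), rscu(table, code)))
            for _, members in fams.families:
                n_a = sum(table.counts[c] for c in members)
                if n_a:
                    assert sum(by_codon[c] for c in members) == pytest.approx(
                        len(members), abs=1e-9
                    )


class TestEnc:
    def test_uniform_table_caps_at_64(self, uniform_table):
        r = enc(uniform_table, load_genetic_code(1))
        assert r.enc == 64.0 and r.capped

    def test_uniform_raw_estimator_is_just_above_64(self, uniform_table):
        """At 1000 counts/codon the uncapped estimator is 64 + (64-21)/999.

        Closed form: per k-fold class F = 999/(1000k - 1), and summing
        m_k/F over the standard-code classes telescopes to 64 + 43/999.
        """
        expected_raw = 64 + (64 - 21) / 999
        assert 64.0 <= expected_raw <= 64.1
        r = enc(uniform_table, load_genetic_code(1))
        assert r.capped and r.enc == 64.0

    def test_one_codon_per_family_hits_the_family_count(self):
        r = enc(one_codon_per_family_table(), load_genetic_code(1))
        assert r.enc == pytest.approx(21.0, abs=1e-9)
        assert not r.capped

    def test_classic_wright_minimum_without_stops(self):
        r = enc(
            one_codon_per_family_table(include_stops=False),
            load_genetic_code(1),
            include_stops=False,
        )
        assert r.enc == pytest.approx(20.0, abs=1e-9)

    def test_empty_table_is_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            enc(make_table({}), load_genetic_code(1))

    def test_all_singleton_families_are_insufficient_data(self):
        # one count in each of two different families: no F-hat anywhere
        with pytest.raises(InsufficientDataError):
            enc(make_table({"TTT": 1, "ATG": 1}), load_genetic_code(1))

    def test_matches_independent_oracle_on_random_tables(self, rng):
        worst = 0.0
        for _ in range(200):
            table = random_table(rng, n_codons=int(rng.integers(100, 20000)))
            mine = enc(table, load_genetic_code(1)).enc
            ref = wright_enc(table.counts, table_id=1)
            worst = max(worst, abs(mine - ref))
        assert worst <= 1e-9

    def test_oracle_agreement_across_genetic_codes(self, rng):
        for table_id in SUPPORTED_TABLE_IDS:
            table = random_table(rng, n_codons=5000)
            mine = enc(table, load_genetic_code(table_id)).enc
            assert mine == pytest.approx(
                wright_enc(table.counts, table_id=table_id), abs=1e-9
            )

    def test_sparse_tables_trigger_identical_repair_rules(self, rng):
        """Very biased, tiny tables exercise missing-class interpolation."""
        for _ in range(100):
            table = random_table(rng, n_codons=int(rng.integers(4, 40)), alpha=0.05)
            try:
                mine = enc(table, load_genetic_code(1)).enc
            except (InsufficientDataError, ValueError):
                with pytest.raises(ValueError):
                    wright_enc(table.counts)
                continue
            assert mine == pytest.approx(wright_enc(table.counts), abs=1e-9)

    def test_extremes_bound_random_tables(self, rng, uniform_table):
        """Max bias is the minimum, uniform usage the maximum ENc."""
        n = one_codon_per_family_table().n_codons
        low = enc(one_codon_per_family_table(), load_genetic_code(1)).enc
        high = enc(
            make_table({c: n // 64 for c in canonical_codon_order()}),
            load_genetic_code(1),
        ).enc
        for _ in range(1000):
            r = enc(random_table(rng, n_codons=n), load_genetic_code(1)).enc
            assert low <= r + 1e-9
            assert r <= high + 1e-9


class TestEncAllCodes:
    def test_uniform_table_caps_under_every_code(self, uniform_table):
        results, failures = enc_all_codes(uniform_table)
        assert not failures
        assert set(results) == set(SUPPORTED_TABLE_IDS)
        for r in results.values():
            assert r.enc == 64.0 and r.capped

    def test_biased_genome_scores_lower_under_its_own_code(self):
        """A genome biased along standard-code families, checked per code
        against the brute-force oracle."""
        fams = degeneracy_families(load_genetic_code(1), include_stops=True)
        counts = {}
        for _, members in fams.families:
            ordered = sorted(members)
            counts[ordered[0]] = 2000  # one dominant codon per family
            for c in ordered[1:]:
                counts[c] = 10
        table = make_table(counts)
        results, _ = enc_all_codes(table)
        for table_id, r in results.items():
            assert r.enc == pytest.approx(
                wright_enc(table.counts, table_id=table_id), abs=1e-9
            )
        # regrouping the same counts under the vertebrate-mitochondrial code
        # splits the dominance pattern differently and reads as less biased
        assert results[1].enc < results[2].enc

    def test_per_code_failures_are_recorded_not_raised(self):
        table = make_table({"TTT": 1, "ATG": 1})
        results, failures = enc_all_codes(table)
        assert set(results) | set(failures) == set(SUPPORTED_TABLE_IDS)
        assert all(isinstance(msg, str) for msg in failures.values())
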