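"""Abundance table I/O, validation and singleton/unique filtering."""

import numpy as np
import pandas as pd
import pytest

from occnet.abundance import (
    AbundanceError,
    AbundanceTable,
    TaxonomyRecord,
    filter_low_abundance,
    read_abundance,
    read_matrix,
    write_matrix,
)

TSV_WITH_TAXONOMY = (
    "taxon_id\ttaxonomy\ts1\ts2\ts3\ts4\n"
    "otu1\tBacteria;Proteobacteria\t1\t2\t3\t4\n"
    "otu2\tBacteria;Cyanobacteria;Cyanophyceae\t5\t6\t7\t8\n"
    "otu3\tBacteria;Firmicutes\t0\t1\t0\t2\n"
)


@pytest.fixture
def tsv_file(tmp_path):
    p = tmp_path / "table.tsv"
    p.write_text(TSV_WITH_TAXONOMY)
    return p


class TestReadAbundance:
    def test_taxonomy_column_parsed(self, tsv_file):
        t = read_abundance(tsv_file, has_taxonomy=True)
        assert (t.n_taxa, t.n_samples) == (3, 4)
        assert t.taxonomy[1].startswith("Bacteria;Cyanobacteria")
        assert t.counts[0, 3] == 4

    def test_auto_detects_taxonomy_from_semicolons(self, tsv_file):
        auto = read_abundance(tsv_file, has_taxonomy="auto")
        assert auto.taxonomy is not None and auto.n_samples == 4

    def test_column_shift_contract(self, tmp_path):
        # the same file reads as 5 samples without the taxonomy flag and
        # 4 samples (plus taxonomy) with it
        p = tmp_path / "shift.tsv"
        p.write_text(
            "id\tc1\tc2\tc3\tc4\tc5\na\t1\t2\t3\t4\t5\nb\t6\t7\t8\t9\t0\n"
        )
        assert read_abundance(p, has_taxonomy=False).n_samples == 5
        with_tax = read_abundance(p, has_taxonomy=True)
        assert with_tax.n_samples == 4
        assert with_tax.taxonomy == ["1", "6"]

    def test_text_second_column_without_taxonomy_flag_is_a_parse_error(
        self, tsv_file
    ):
        with pytest.raises(AbundanceError, match="non-numeric"):
            read_abundance(tsv_file, has_taxonomy=False)

    def test_duplicate_taxon_ids_rejected_by_name(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,s1,s2\na,1,2\nb,3,4\na,5,6\n")
        with pytest.raises(AbundanceError, match="a"):
            read_abundance(p, has_taxonomy=False)

    def test_non_numeric_cell_reported_with_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,s1,s2\na,1,oops\nb,3,4\n")
        with pytest.raises(AbundanceError, match="oops.*'a'.*'s2'"):
            read_abundance(p, has_taxonomy=False)

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("id,s1,s2\n")
        with pytest.raises(AbundanceError, match="empty"):
            read_abundance(p, has_taxonomy=False)

    def test_roundtrip_preserves_integer_counts_exactly(self, tsv_file, tmp_path):
        t = read_abundance(tsv_file)
        out = tmp_path / "again.tsv"
        t.write(out)
        back = read_abundance(out)
        assert back.taxon_ids == t.taxon_ids
        assert back.sample_ids == t.sample_ids
        np.testing.assert_array_equal(back.counts, t.counts)


class TestFiltering:
    def _table(self, counts, ids=None):
        counts = np.asarray(counts, float)
        ids = ids or [f"t{i}" for i in range(len(counts))]
        samples = [f"s{j}" for j in range(counts.shape[1])]
        return AbundanceTable(ids, samples, counts)

    def test_singleton_below_five_total_removed(self):
        t = self._table([[1, 1, 1, 1], [9, 9, 9, 9], [8, 7, 1, 2]])
        kept, report = filter_low_abundance(t)
        assert kept.taxon_ids == ["t1", "t2"]
        assert report.loc[0, "reason"] == "singleton"

    def test_total_exactly_five_survives_the_strict_threshold(self):
        t = self._table([[3, 2, 0, 0], [9, 9, 9, 9], [6, 6, 6, 6]])
        kept, _ = filter_low_abundance(t)
        assert "t0" in kept.taxon_ids

    def test_unique_taxon_removed_despite_total(self):
        t = self._table([[5, 0, 0, 0], [9, 9, 9, 9], [6, 6, 6, 6]])
        kept, report = filter_low_abundance(t)
        assert kept.taxon_ids == ["t1", "t2"]
        assert list(report["reason"]) == ["unique"]

    def test_five_taxon_fixture_matches_hand_counts(self):
        # hand application: t0 singleton (total 4), t1 unique (6 in s0 only),
        # t2 singleton AND unique (total 3, 1 sample); t3, t4 survive
        t = self._table(
            [
                [1, 1, 1, 1],
                [6, 0, 0, 0],
                [0, 0, 3, 0],
                [5, 5, 5, 5],
                [2, 2, 2, 2],
            ]
        )
        kept, report = filter_low_abundance(t)
        assert kept.taxon_ids == ["t3", "t4"]
        assert len(report) == 3
        assert set(report["taxon_id"]) == {"t0", "t1", "t2"}

    def test_filtering_is_idempotent_and_preserves_surviving_counts(self):
        t = self._table([[1, 1, 1, 1], [9, 3, 9, 9], [8, 7, 1, 2]])
        once, _ = filter_low_abundance(t)
        twice, report2 = filter_low_abundance(once)
        assert twice.taxon_ids == once.taxon_ids
        assert report2.empty
        np.testing.assert_array_equal(
            once.counts, t.counts[[1, 2]]
        )
        assert once.sample_ids == t.sample_ids

    def test_all_removed_raises_advice(self):
        t = self._table([[1, 1, 0, 0], [2, 0, 0, 0]])
        with pytest.raises(AbundanceError, match="min_total"):
            filter_low_abundance(t)

    def test_relative_abundance_input_only_applies_unique_rule(self):
        counts = np.array([[0.6, 0.0, 0.0], [0.3, 0.5, 0.5], [0.1, 0.5, 0.5]])
        t = self._table(counts)
        with pytest.warns(UserWarning, match="relative-abundance"):
            kept, report = filter_low_abundance(t)
        # totals are all < 5 but only the unique taxon goes
        assert kept.taxon_ids == ["t1", "t2"]
        assert list(report["reason"]) == ["unique"]


class TestMatrixIO:
    def test_identity_round_trips(self, tmp_path):
        p = tmp_path / "m.csv"
        write_matrix(np.eye(2), p, labels=["a", "b"])
        assert len(p.read_text().strip().splitlines()) == 3
        back = read_matrix(p)
        np.testing.assert_array_equal(back.to_numpy(), np.eye(2))
        assert list(back.index) == ["a", "b"]

    def test_random_symmetric_round_trip_is_exact_to_1e12(self, tmp_path):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10, 10))
        m = (m + m.T) / 2
        p = tmp_path / "m.csv"
        labels = [f"x{i}" for i in range(10)]
        write_matrix(m, p, labels=labels)
        back = read_matrix(p).to_numpy()
        np.testing.assert_allclose(back, m, rtol=1e-12, atol=0)

    @pytest.mark.parametrize(
        "matrix,labels",
        [
            (np.zeros((2, 3)), ["a", "b"]),
            (np.zeros((2, 2)), ["a", "b", "c"]),
            (np.zeros((2, 2)), ["a", "a"]),
        ],
    )
    def test_bad_shapes_and_labels_rejected(self, tmp_path, matrix, labels):
        with pytest.raises(AbundanceError):
            write_matrix(matrix, tmp_path / "m.csv", labels=labels)


class TestTaxonomyRecord:
    def test_phylum_is_second_rank(self):
        rec = TaxonomyRecord(
            "Bacteria;Cyanobacteria;Cyanophyceae;Nostocales;Nostocaceae;Nostoc"
        )
        assert rec.phylum == "Cyanobacteria"
        assert rec.ranks[0] == "Bacteria"

    @pytest.mark.parametrize("raw", ["Bacteria", "", "Bacteria;"])
    def test_missing_phylum_is_na(self, raw):
        assert TaxonomyRecord(raw).phylum == "NA"

    def test_trailing_empty_ranks_preserved(self):
        assert TaxonomyRecord("Bacteria;Proteo;;").ranks == ["Bacteria", "Proteo", "", ""]
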