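import numpy as np
import pytest

from conet.counts import (
    CountTable,
    EmptyTableError,
    Lineage,
    filter_counts,
    group_taxa,
    read_biom,
    read_taxonomy_tsv,
    read_tsv,
    transform,
    write_biom,
    write_tsv,
)


class TestLineage:
    def test_parses_rank_prefixes_and_joins_nonempty(self):
        lin = Lineage.from_string("k__Bacteria; p__Firmicutes; c__Bacilli; o__; f__; g__; s__")
        assert lin.ranks[:3] == ("Bacteria", "Firmicutes", "Bacilli")
        assert str(lin) == "Bacteria;Firmicutes;Bacilli"
        assert lin.depth == 3

    def test_empty_ranks_only_as_suffix(self):
        with pytest.raises(ValueError, match="suffix"):
            Lineage(("Bacteria", "", "Bacilli", "", "", "", ""))

    def test_prefix_of_unresolved_rank_is_deepest_nonempty(self):
        lin = Lineage.from_string("Bacteria;Firmicutes;Bacilli")
        assert str(lin.prefix("genus")) == "Bacteria;Firmicutes;Bacilli"
        assert str(lin.prefix("phylum")) == "Bacteria;Firmicutes"

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="unknown rank"):
            Lineage.from_string("Bacteria").prefix("strain")


class TestFilterCounts:
    def test_shallow_samples_dropped_first(self):
        # sample totals 600, 400, 700: the 400-read sample goes
        t = CountTable([[600, 400, 700]], ["f"], ["s1", "s2", "s3"])
        out = filter_counts(t, 0, 0, 0, sample_sum_min=500)
        assert out.sample_ids == ["s1", "s3"]
        assert np.array_equal(out.counts, [[600, 700]])

    def test_all_zero_feature_removed(self, small_table):
        out = filter_counts(small_table, 0, 0, obs_sum_min=1, sample_sum_min=0)
        assert "f2" not in out.feature_ids
        assert out.feature_ids == ["f1", "f3", "f4"]

    def test_low_prevalence_feature_removed(self):
        # present in 1 of 40 samples: 0.025 < 0.05
        counts = np.ones((2, 40))
        counts[0] = 0
        counts[0, 0] = 1
        t = CountTable(counts, ["rare", "common"], [f"s{i}" for i in range(40)])
        out = filter_counts(t, prevalence_min=0.05, abundance_min=0,
                            obs_sum_min=0, sample_sum_min=0)
        assert out.feature_ids == ["common"]

    def test_idempotent_on_typical_table(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(30, (20, 15)).astype(float)
        t = CountTable(counts, [f"f{i}" for i in range(20)], [f"s{j}" for j in range(15)])
        once = filter_counts(t, 0.05, 0.01, 100, 100)
        twice = filter_counts(once, 0.05, 0.01, 100, 100)
        assert once.feature_ids == twice.feature_ids
        assert once.sample_ids == twice.sample_ids
        assert np.array_equal(once.counts, twice.counts)

    def test_stringent_feature_set_within_relaxed(self):
        rng = np.random.default_rng(3)
        counts = (rng.pareto(1.2, (40, 30)) * 10).round()
        t = CountTable(counts, [f"f{i}" for i in range(40)], [f"s{j}" for j in range(30)])
        strict = filter_counts(t, 0.05, 0.01, 100, 500)
        relaxed = filter_counts(t, 2 / 30, 0.001, 10, 500)
        assert set(strict.feature_ids) <= set(relaxed.feature_ids)

    def test_empty_result_names_threshold(self, small_table):
        with pytest.raises(EmptyTableError, match="sample_sum_min"):
            filter_counts(small_table, 0, 0, 0, sample_sum_min=10_000)
        with pytest.raises(EmptyTableError, match="obs_sum_min"):
            filter_counts(small_table, 0, 0, obs_sum_min=10_000, sample_sum_min=0)

    def test_requires_raw_counts(self, small_table):
        clr = transform(small_table, "clr")
        with pytest.raises(ValueError, match="raw"):
            filter_counts(clr, 0, 0, 0, 0)


class TestGroupTaxa:
    def test_same_genus_rows_are_summed(self):
        lin = Lineage.from_string("Bacteria;F;B;L;Lact;Lactobacillus")
        t = CountTable([[3, 4], [1, 2]], ["a", "b"], ["s1", "s2"], [lin, lin])
        out = group_taxa(t, "genus")
        assert out.n_features == 1
        assert np.array_equal(out.counts, [[4, 6]])

    def test_family_resolved_stays_distinct_from_genus_rows(self, small_table):
        out = group_taxa(small_table, "genus")
        # f3 is family-only: keyed by its family prefix, separate from the
        # two genus-resolved rows of the same family
        keys = out.feature_ids
        assert "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae" in keys
        assert out.n_features == 4

    def test_column_sums_conserved(self, small_table):
        for level in ("phylum", "family", "genus"):
            out = group_taxa(small_table, level)
            assert np.allclose(out.counts.sum(axis=0), small_table.counts.sum(axis=0))

    def test_two_stage_grouping_matches_direct(self, small_table):
        via_genus = group_taxa(group_taxa(small_table, "genus"), "phylum")
        direct = group_taxa(small_table, "phylum")
        assert via_genus.feature_ids == direct.feature_ids
        assert np.allclose(via_genus.counts, direct.counts)

    def test_missing_lineages_rejected(self):
        t = CountTable([[1]], ["f"], ["s"])
        with pytest.raises(ValueError, match="lineages"):
            group_taxa(t, "genus")


class TestTransform:
    def test_tss_columns_sum_to_one(self):
        t = CountTable([[2], [3], [5]], ["a", "b", "c"], ["s"])
        out = transform(t, "tss")
        assert np.allclose(out.counts[:, 0], [0.2, 0.3, 0.5])
        assert out.normalization_state == "tss"

    def test_tss_normalization_tolerance(self, small_table):
        out = transform(small_table, "tss")
        assert np.all(np.abs(out.counts.sum(axis=0) - 1) < 1e-12)

    def test_clr_constant_column_is_zero(self):
        t = CountTable([[4], [4], [4]], ["a", "b", "c"], ["s"])
        out = transform(t, "clr", pseudocount=0.0)
        assert np.allclose(out.counts, 0)

    def test_clr_columns_sum_to_zero(self, small_table):
        out = transform(small_table, "clr")
        assert np.all(np.abs(out.counts.sum(axis=0)) < 1e-9)
        assert out.normalization_state == "clr"

    def test_clr_zero_data_needs_pseudocount(self, small_table):
        with pytest.raises(ValueError, match="pseudocount"):
            transform(small_table, "clr", pseudocount=0.0)

    def test_rarefy_hits_depth_exactly_and_reproduces(self):
        rng = np.random.default_rng(1)
        t = CountTable(rng.poisson(20, (10, 4)), [f"f{i}" for i in range(10)],
                       list("wxyz"))
        out1 = transform(t, "rarefy", depth=10, seed=42)
        out2 = transform(t, "rarefy", depth=10, seed=42)
        assert np.all(out1.counts.sum(axis=0) == 10)
        assert np.array_equal(out1.counts, out2.counts)

    def test_rarefy_depth_above_sample_total_names_sample(self, small_table):
        with pytest.raises(ValueError, match="'b'"):
            transform(small_table, "rarefy", depth=10)


class TestIO:
    def test_tsv_roundtrip(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_tsv(small_table, path)
        back = read_tsv(path)
        assert back.feature_ids == small_table.feature_ids
        assert back.sample_ids == small_table.sample_ids
        assert np.array_equal(back.counts, small_table.counts)

    def test_taxonomy_tsv(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("#id\tlineage\nf1\tk__Bacteria; p__Firmicutes\n")
        tax = read_taxonomy_tsv(path)
        assert str(tax["f1"]) == "Bacteria;Firmicutes"

    @pytest.mark.parametrize("fmt", ["hdf5", "json"])
    def test_biom_roundtrip(self, small_table, tmp_path, fmt):
        path = tmp_path / f"t.{fmt}.biom"
        write_biom(small_table, path, fmt=fmt)
        back = read_biom(path)
        assert back.feature_ids == small_table.feature_ids
        assert np.array_equal(back.counts, small_table.counts)
        assert back.lineages is not None
        assert str(back.lineages[0]) == str(small_table.lineages[0])
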