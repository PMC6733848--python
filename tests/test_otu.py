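import numpy as np
import pytest

from microgrowth.otu import (
    OtuTable,
    OtuTableParseError,
    read_otu_table,
    write_otu_table,
    filter_low_fraction_otus,
    rarefy,
    shannon_index,
)
from .conftest import make_table


class TestIO:
    def test_round_trip_identity(self, tmp_path):
        table = make_table(
            [[1, 0, 3, 7], [0, 2, 0, 9], [5, 5, 5, 5]],
            taxonomy=[f"k__B; g__G{j}" for j in range(4)],
        )
        path = tmp_path / "t.tsv"
        write_otu_table(table, path)
        assert read_otu_table(path) == table

    def test_negative_count_is_parse_error_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\ts1\ts2\no1\t3\t4\no2\t-1\t0\n")
        with pytest.raises(OtuTableParseError, match="bad.tsv:3"):
            read_otu_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\ts1\no1\t2.5\n")
        with pytest.raises(OtuTableParseError, match="non-integer"):
            read_otu_table(path)

    def test_duplicate_otu_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("#OTU ID\ts1\no1\t1\no1\t2\n")
        with pytest.raises(OtuTableParseError, match="duplicate"):
            read_otu_table(path)

    def test_missing_taxonomy_column_yields_empty_taxonomy(self, tmp_path):
        path = tmp_path / "notax.tsv"
        path.write_text("#OTU ID\ts1\ts2\no1\t1\t2\no2\t0\t4\n")
        table = read_otu_table(path)
        assert table.taxonomy == ["", ""]
        assert table.counts.tolist() == [[1, 0], [2, 4]]


class TestLowFractionFilter:
    def test_above_both_thresholds_retained(self):
        # 2 reads of 1000 = 0.2% in three samples
        counts = np.full((3, 1), 2)
        pad = np.full((3, 1), 998)
        table = make_table(np.hstack([counts, pad]))
        out = filter_low_fraction_otus(table)
        assert "o0" in out.otu_ids

    def test_single_qualifying_sample_removed(self):
        counts = np.array([[2, 998], [0, 1000], [0, 1000]])
        out = filter_low_fraction_otus(make_table(counts))
        assert out.otu_ids == ["o1"]

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 40, size=(20, 50))
        counts[:, 0] = 0
        table = make_table(counts)
        out = filter_low_fraction_otus(table, 0.001, 2)

        expected = []
        totals = counts.sum(axis=1)
        for j in range(50):
            hits = sum(
                1
                for i in range(20)
                if totals[i] > 0 and counts[i, j] / totals[i] >= 0.001
            )
            if hits >= 2:
                expected.append(f"o{j}")
        assert out.otu_ids == expected

    def test_filter_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.integers(0, 30, size=(15, 40)))
        base = set(filter_low_fraction_otus(table, 0.001, 2).otu_ids)
        stricter_frac = set(filter_low_fraction_otus(table, 0.01, 2).otu_ids)
        stricter_n = set(filter_low_fraction_otus(table, 0.001, 5).otu_ids)
        assert stricter_frac <= base
        assert stricter_n <= base


class TestRarefy:
    def test_sample_at_exact_depth_unchanged(self):
        counts = np.array([[2000, 3000], [100, 100]])
        out, dropped = rarefy(make_table(counts), depth=5000, seed=0)
        assert out.counts.tolist() == [[2000, 3000]]
        assert dropped == ["s1"]

    def test_row_sums_equal_depth(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3000, size=(10, 8))
        counts[:, 0] += 6000  # everyone comfortably above depth
        out, _ = rarefy(make_table(counts), depth=5000, seed=1)
        assert (out.sample_sums() == 5000).all()
        assert (out.counts <= counts).all()

    def test_hypergeometric_expectation(self):
        # one sample (A: 9000, B: 1000) rarefied to 5000: E[A] = 4500
        table = make_table([[9000, 1000]])
        draws = np.array(
            [rarefy(table, 5000, seed=s)[0].counts[0, 0] for s in range(1000)]
        )
        # variance of the hypergeometric draw for A
        n, K, N = 5000, 9000, 10000
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        se = np.sqrt(var / 1000)
        assert abs(draws.mean() - 4500) < 3 * se

    def test_no_sample_reaches_depth_warns_and_empties(self):
        table = make_table([[10, 10], [5, 0]])
        with pytest.warns(UserWarning, match="no sample reaches"):
            out, dropped = rarefy(table, depth=5000, seed=0)
        assert out.n_samples == 0
        assert dropped == ["s0", "s1"]


class TestShannon:
    def test_closed_forms(self):
        table = make_table([[7, 0, 0, 0], [5, 5, 5, 5], [1, 2, 3, 0]])
        res = shannon_index(table)
        assert res[0].shannon == 0.0
        assert res[1].shannon == pytest.approx(np.log(4), abs=1e-12)
        # direct evaluation of -sum p ln p for (1, 2, 3)
        assert res[2].shannon == pytest.approx(1.0114042647073518, abs=1e-10)

    def test_all_zero_sample_flagged(self):
        res = shannon_index(make_table([[0, 0, 0]]))
        assert not res[0].included
        assert np.isnan(res[0].shannon)

    def test_matches_brute_force_oracle_and_bounds(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 50, size=(200, 12))
        counts[:, 0] += 1  # keep samples non-empty
        table = make_table(counts)
        for i, r in enumerate(shannon_index(table)):
            total = counts[i].sum()
            expected = 0.0
            for c in counts[i]:
                if c > 0:
                    p = c / total
                    expected -= p * np.log(p)
            assert r.shannon == pytest.approx(expected, abs=1e-12)
            s_observed = (counts[i] > 0).sum()
            assert 0.0 <= r.shannon <= np.log(s_observed) + 1e-12

    def test_maximal_iff_uniform(self):
        uniform = make_table([[10, 10, 10]])
        skewed = make_table([[25, 4, 1]])
        assert shannon_index(uniform)[0].shannon == pytest.approx(np.log(3))
        assert shannon_index(skewed)[0].shannon < np.log(3)


class TestOtuTableValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_table([[1, -1]])

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            OtuTable(sample_ids=["a"], otu_ids=["x", "y"], counts=np.ones((1, 3), int))
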