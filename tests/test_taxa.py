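import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from microgrowth.taxa import scan_filter, encode_otu, bh_adjust, run_scan
from .conftest import make_table


class TestScanFilter:
    def test_low_prevalence_otu_removed(self):
        counts = np.zeros((50, 2), dtype=int)
        counts[:, 1] = 1000
        counts[:2, 0] = 100  # present in 4% of participants
        out = scan_filter(make_table(counts), min_prevalence=0.05)
        assert out.otu_ids == ["o1"]

    def test_sub_abundance_cells_zeroed_before_prevalence(self):
        # 0.05% within-sample abundance: zeroed, so never "detected"
        counts = np.zeros((40, 2), dtype=int)
        counts[:, 1] = 10_000
        counts[:, 0] = 5  # 5 / 10005 < 0.1%
        out = scan_filter(make_table(counts))
        assert out.otu_ids == ["o1"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        counts = rng.integers(0, 60, size=(40, 25))
        counts[rng.random((40, 25)) < 0.5] = 0
        counts[:, 0] += 500
        table = make_table(counts)
        out = scan_filter(table, 0.05, 0.001)

        expected = []
        totals = counts.sum(axis=1)
        for j in range(25):
            detected = 0
            for i in range(40):
                c = counts[i, j]
                if totals[i] > 0 and c / totals[i] >= 0.001 and c > 0:
                    detected += 1
            if detected / 40 >= 0.05:
                expected.append(f"o{j}")
        assert out.otu_ids == expected


class TestEncode:
    def test_worked_example(self):
        enc = encode_otu([0, 0, 5, 10, 20], otu_id="x")
        assert enc.median_positive_count == 10
        assert enc.binary.tolist() == [False, False, True, True, True]
        assert enc.tri_level.tolist() == [0, 0, 1, 2, 2]

    def test_ties_at_median_go_up(self):
        enc = encode_otu([3, 3, 3, 3])
        assert (enc.tri_level == 2).all()

    def test_single_positive_sample_is_high(self):
        enc = encode_otu([0, 0, 7])
        assert enc.tri_level.tolist() == [0, 0, 2]

    def test_absent_everywhere_errors(self):
        with pytest.raises(ValueError, match="absent"):
            encode_otu([0, 0, 0])

    def test_binary_and_tri_level_agree_on_absence(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 5, 100)
        counts[0] = 1
        enc = encode_otu(counts)
        assert ((enc.tri_level == 0) == ~enc.binary).all()


class TestBhAdjust:
    def test_hand_walked_step_up(self):
        adjusted, rejected = bh_adjust([0.01, 0.02, 0.30], q=0.15)
        # 0.01 <= 1/3*0.15, 0.02 <= 2/3*0.15, 0.30 > 0.15
        assert rejected.tolist() == [True, True, False]
        assert adjusted == pytest.approx([0.03, 0.03, 0.30])

    def test_all_ones(self):
        adjusted, rejected = bh_adjust(np.ones(5))
        assert not rejected.any()
        assert (adjusted == 1.0).all()

    def test_single_p_reduces_to_raw_threshold(self):
        _, rejected = bh_adjust([0.1], q=0.15)
        assert rejected.tolist() == [True]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_and_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.random(m)
            adjusted, rejected = bh_adjust(p, q=0.15)

            # brute-force step-up: largest i with p_(i) <= i/m q
            order = np.argsort(p)
            k = 0
            for i in range(1, m + 1):
                if p[order[i - 1]] <= i / m * 0.15:
                    k = i
            expected_reject = np.zeros(m, dtype=bool)
            expected_reject[order[:k]] = True
            assert np.array_equal(rejected, expected_reject)

            sm_reject, sm_adj, _, _ = multipletests(
                p, alpha=0.15, method="fdr_bh"
            )
            assert np.allclose(adjusted, sm_adj)
            assert np.array_equal(rejected, sm_reject)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(7)
        p = rng.random(30)
        adjusted, _ = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-15).all()


class TestRunScan:
    def _null_table(self, rng, n=120, m=15):
        counts = rng.integers(0, 30, size=(n, m))
        counts[rng.random((n, m)) < 0.3] = 0
        counts[0] += 1  # no all-zero OTUs
        return make_table(counts)

    def test_planted_effects_rank_first(self):
        rng = np.random.default_rng(31)
        table = self._null_table(rng, n=150, m=30)
        y = rng.normal(size=150)
        # plant strong presence effects on the first three OTUs
        for j in range(3):
            y += 1.5 * (table.counts[:, j] > 0)
        res = run_scan(table, pd.Series(y, index=table.sample_ids))
        top3 = set(res.nsmallest(3, "raw_p")["otu_id"])
        assert top3 == {"o0", "o1", "o2"}
        assert res.set_index("otu_id").loc["o0", "significant_post_fdr"]

    def test_tri_level_uses_joint_test(self):
        rng = np.random.default_rng(32)
        table = self._null_table(rng)
        y = rng.normal(size=120)
        res = run_scan(
            table, pd.Series(y, index=table.sample_ids), encoding="tri_level"
        )
        assert (res.loc[~res["failed"], "bh_adjusted_p"]
                >= res.loc[~res["failed"], "raw_p"] - 1e-12).all()
        assert set(res["encoding"]) == {"tri_level"}

    def test_families_adjusted_independently(self):
        rng = np.random.default_rng(33)
        table = self._null_table(rng)
        y1 = pd.Series(rng.normal(size=120), index=table.sample_ids)
        y2 = pd.Series(rng.normal(size=120), index=table.sample_ids)
        r1 = run_scan(table, y1)
        r2 = run_scan(table, y2)
        # each call is its own BH family: adjustment depends only on that
        # call's p-values
        adj1, _ = bh_adjust(r1["raw_p"].to_numpy())
        assert np.allclose(r1["bh_adjusted_p"], adj1)
        assert not np.allclose(r1["bh_adjusted_p"], r2["bh_adjusted_p"])

    def test_model_failure_recorded_not_raised(self):
        rng = np.random.default_rng(34)
        table = self._null_table(rng, n=50, m=5)
        # outcome all-NaN makes every fit fail, but the scan completes
        y = pd.Series(np.nan, index=table.sample_ids)
        res = run_scan(table, y)
        assert res["failed"].all()
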