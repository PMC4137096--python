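import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tinscope as ts
from tinscope.association import CorrelationRecord


def make_profile(estimates, sample_ids=None):
    estimates = np.asarray(estimates, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(len(estimates))]
    table = pd.DataFrame({
        "skip_count": 1, "incl_count": 1, "total_count": 2,
        "rel_skip": 0.0, "rel_incl": 0.0,
        "tin_estimate": estimates,
        "is_tin_sample": np.abs(estimates) >= 1.0,
    }, index=sample_ids)
    return ts.TinProfile(table=table, tin_cutoff=1.0,
                         tin_range=float(estimates.max() - estimates.min()))


def expr_from_rows(rows: dict, sample_ids):
    return pd.DataFrame(rows, index=sample_ids).T


class TestCorrelateGenes:
    def test_perfect_positive_and_negative_correlation(self):
        tin = make_profile([0.1, 0.5, -0.4, 1.2, -0.9])
        expr = expr_from_rows(
            {"up": tin.tin_estimates.to_numpy(), "down": -tin.tin_estimates.to_numpy()},
            tin.sample_ids,
        )
        res = ts.correlate_genes_with_tin(expr, tin, ["up", "down"])
        by_gene = {r.gene_id: r for r in res.records}
        assert by_gene["up"].r == pytest.approx(1.0)
        assert by_gene["down"].r == pytest.approx(-1.0)
        assert by_gene["up"].significant and by_gene["down"].significant

    def test_textbook_pearson_oracle(self):
        # x=[1..5], y=[2,1,4,3,5]: r = 0.8, t = 0.8*sqrt(3/0.36), df=3
        tin = make_profile([1, 2, 3, 4, 5])
        expr = expr_from_rows({"g": [2, 1, 4, 3, 5]}, tin.sample_ids)
        rec = ts.correlate_genes_with_tin(expr, tin, ["g"]).records[0]
        assert rec.r == pytest.approx(0.8)
        t = 0.8 * np.sqrt(3 / 0.36)
        assert rec.p == pytest.approx(2 * stats.t.sf(t, df=3))

    def test_analytic_p_matches_brute_force_permutation_p(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=10)
        x = y + rng.normal(scale=1.5, size=10)
        tin = make_profile(y)
        expr = expr_from_rows({"g": x}, tin.sample_ids)
        rec = ts.correlate_genes_with_tin(expr, tin, ["g"]).records[0]
        r_obs = abs(rec.r)
        hits = 0
        B = 10000
        for _ in range(B):
            perm = rng.permutation(y)
            r = np.corrcoef(x, perm)[0, 1]
            hits += abs(r) >= r_obs - 1e-12
        p_perm = (hits + 1) / (B + 1)
        assert rec.p == pytest.approx(p_perm, abs=0.03)

    def test_absent_genes_reported_not_dropped(self):
        tin = make_profile([1, 2, 3, 4])
        expr = expr_from_rows({"g": [1, 2, 1, 2]}, tin.sample_ids)
        res = ts.correlate_genes_with_tin(expr, tin, ["g", "ghost"])
        assert res.skipped == ["ghost"]
        assert [r.gene_id for r in res.records] == ["g"]

    def test_zero_variance_gene_degenerate(self):
        tin = make_profile([1, 2, 3, 4])
        expr = expr_from_rows({"flat": [5, 5, 5, 5]}, tin.sample_ids)
        rec = ts.correlate_genes_with_tin(expr, tin, ["flat"]).records[0]
        assert rec.degenerate and rec.r == 0.0 and not rec.significant

    def test_too_few_samples_refused(self):
        tin = make_profile([1, 2])
        expr = expr_from_rows({"g": [1, 2]}, tin.sample_ids)
        with pytest.raises(ValueError):
            ts.correlate_genes_with_tin(expr, tin, ["g"])


class TestSummarize:
    def records(self):
        return [
            CorrelationRecord("a", -0.9, 0.01, 10, True),
            CorrelationRecord("b", 0.5, 0.20, 10, False),
            CorrelationRecord("c", -0.7, 0.03, 10, True),
            CorrelationRecord("d", 0.6, 0.04, 10, True),
        ]

    def test_counting_example(self):
        s = ts.summarize_association(self.records(), alpha=0.05)
        assert s.pct_significant == pytest.approx(75.0)
        assert s.n_neg_significant == 2 and s.n_pos_significant == 1
        assert s.neg_pos_ratio == pytest.approx(2.0)
        assert s.mean_abs_r == pytest.approx((0.9 + 0.5 + 0.7 + 0.6) / 4)

    def test_no_significant_records(self):
        recs = [CorrelationRecord("a", 0.1, 0.8, 10, False)]
        s = ts.summarize_association(recs)
        assert s.pct_significant == 0.0
        assert np.isinf(s.neg_pos_ratio)  # undefined flagged as inf
        assert np.isnan(s.mean_r_significant)

    def test_order_invariance(self):
        recs = self.records()
        a = ts.summarize_association(recs)
        b = ts.summarize_association(list(reversed(recs)))
        assert vars(a) == vars(b)

    def test_degenerate_records_excluded_from_denominator(self):
        recs = self.records() + [CorrelationRecord("z", 0.0, 1.0, 10, False, degenerate=True)]
        assert ts.summarize_association(recs).n_genes_tested == 4

    def test_all_degenerate_refused(self):
        with pytest.raises(ValueError):
            ts.summarize_association([CorrelationRecord("z", 0.0, 1.0, 10, False, True)])


class TestGroupComparisons:
    def test_identical_groups_t_zero_p_one(self):
        tin = make_profile([1, 2, 3, 1, 2, 3])
        t, p = ts.independent_ttest(tin, pd.Series(list("aaabbb"), index=tin.sample_ids))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pooled_variance_hand_oracle(self):
        # [1,2,3,4] vs [3,4,5,6]: pooled var 5/3, t = -2/0.9129 = -2.19
        tin = make_profile([1, 2, 3, 4, 3, 4, 5, 6])
        labels = pd.Series(["x"] * 4 + ["y"] * 4, index=tin.sample_ids)
        t, p = ts.independent_ttest(tin, labels)
        assert t == pytest.approx(-2.19, abs=0.005)
        assert p == pytest.approx(2 * stats.t.sf(2.1909, df=6), abs=1e-3)

    def test_zero_variance_unequal_means_degenerate(self):
        tin = make_profile([0, 0, 0, 1, 1, 1])
        labels = pd.Series(list("aaabbb"), index=tin.sample_ids)
        with pytest.raises(ValueError, match="degenerate separation"):
            ts.independent_ttest(tin, labels)

    def test_small_group_refused(self):
        tin = make_profile([1, 2, 3])
        with pytest.raises(ValueError):
            ts.independent_ttest(tin, pd.Series(["a", "b", "b"], index=tin.sample_ids))


class TestPairedCorrelation:
    def test_identical_cohorts_r_one(self):
        tin_a = make_profile([1, -2, 0.5, 3], ["a1", "a2", "a3", "a4"])
        tin_b = make_profile([1, -2, 0.5, 3], ["b1", "b2", "b3", "b4"])
        rec, skipped = ts.paired_tin_correlation(
            tin_a, tin_b, {f"a{i}": f"b{i}" for i in range(1, 5)}
        )
        assert rec.r == pytest.approx(1.0)
        assert not skipped

    def test_random_pairings_average_near_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=12)
        ids_a = [f"a{i}" for i in range(12)]
        ids_b = [f"b{i}" for i in range(12)]
        tin_a = make_profile(vals, ids_a)
        rs = []
        for _ in range(200):
            tin_b = make_profile(rng.permutation(vals), ids_b)
            rec, _ = ts.paired_tin_correlation(tin_a, tin_b, dict(zip(ids_a, ids_b)))
            rs.append(rec.r)
        assert abs(np.mean(rs)) < 0.08

    def test_missing_sample_pair_skipped(self):
        tin_a = make_profile([1, 2, 3, 4], ["a1", "a2", "a3", "a4"])
        tin_b = make_profile([1, 2, 3, 4], ["b1", "b2", "b3", "b4"])
        rec, skipped = ts.paired_tin_correlation(
            tin_a, tin_b, {"a1": "b1", "a2": "b2", "a3": "b3", "a9": "b9"}
        )
        assert skipped == ["a9"] and rec.n == 3

    def test_fewer_than_three_pairs_refused(self):
        tin_a = make_profile([1, 2, 3], ["a1", "a2", "a3"])
        tin_b = make_profile([1, 2, 3], ["b1", "b2", "b3"])
        with pytest.raises(ValueError):
            ts.paired_tin_correlation(tin_a, tin_b, {"a1": "b1", "a2": "b2"})
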