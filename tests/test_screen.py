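"""The two-condition expression screen and its summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import markerscreen as ms
from markerscreen.screen import hits_frame, percentile, selected_genes

from conftest import brute_percentile, brute_screen


class TestPercentile:
    @pytest.mark.parametrize(
        "values,q,expected",
        [
            (list(range(1, 101)), 95, 95.05),   # 1 + 0.95*99 = 95.05 -> interpolate
            ([7.3], 40, 7.3),                   # degenerate n = 1
            ([0, 0, 0, 10], 50, 0.0),           # p = 2.5, both bracketing stats are 0
            ([1, 2, 3], 95, 2.9),               # p = 2.9 -> 2 + 0.9
        ],
    )
    def test_linear_interpolation_worked_examples(self, values, q, expected):
        assert percentile(values, q) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        st.floats(0.5, 100.0),
    )
    def test_matches_brute_force_oracle(self, values, q):
        assert percentile(values, q) == pytest.approx(brute_percentile(values, q), abs=1e-9)

    def test_nearest_rank_convention(self):
        # smallest order statistic with rank >= q*n/100
        assert percentile([1, 2, 3, 4], 50, method="nearest-rank") == 2.0
        assert percentile([1, 2, 3, 4], 51, method="nearest-rank") == 3.0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            percentile([], 95)
        with pytest.raises(ValueError, match="method"):
            percentile([1.0], 95, method="median-unbiased")


class TestSummaries:
    def test_median_and_q95_small_group(self, small_cohort):
        nm, ann = small_cohort
        s = ms.summarize_by_subtype(nm, ann, q=95)
        assert s.medians.at["HOT", "A"] == 12.0
        # subtype A values (10, 12, 14): p = 1 + 0.95*2 = 2.9 -> 12 + 0.9*2
        assert s.percentiles.at["HOT", "A"] == pytest.approx(13.8)
        assert s.n_samples == {"A": 3, "B": 3, "C": 3}

    def test_constant_gene_has_equal_median_and_percentile(self, small_cohort):
        nm, ann = small_cohort
        s = ms.summarize_by_subtype(nm, ann)
        for sub in s.subtypes:
            assert s.medians.at["FLAT", sub] == s.percentiles.at["FLAT", sub] == 1.0

    def test_matches_groupby_oracle_on_synthetic_cohort(self, default_sim):
        _, expr, ann, _ = default_sim
        nm = ms.normalize_by_reference(expr, "TBP")
        s = ms.summarize_by_subtype(nm, ann, q=95)
        rng = np.random.default_rng(0)
        for gene in rng.choice(nm.gene_ids, 25, replace=False):
            for sub in ann.subtypes:
                vals = nm.values.loc[gene, ann.samples_for(sub)].to_numpy()
                assert s.medians.at[gene, sub] == pytest.approx(np.median(vals), abs=1e-12)
                assert s.percentiles.at[gene, sub] == pytest.approx(
                    brute_percentile(vals, 95), abs=1e-9
                )

    def test_median_never_exceeds_high_percentile(self, default_sim):
        _, expr, ann, _ = default_sim
        nm = ms.normalize_by_reference(expr, "TBP")
        s = ms.summarize_by_subtype(nm, ann, q=95)
        assert (s.medians.to_numpy() <= s.percentiles.to_numpy() + 1e-12).all()

    def test_small_subtype_is_hard_error(self, small_cohort):
        nm, ann = small_cohort
        with pytest.raises(ValueError, match="at least 5"):
            ms.summarize_by_subtype(nm, ann, min_samples=5)

    def test_unannotated_samples_excluded(self, small_cohort):
        nm, ann = small_cohort
        trimmed = ms.SampleAnnotation(ann.labels.drop("s0"))
        s = ms.summarize_by_subtype(nm, trimmed, min_samples=2)
        assert s.n_samples["A"] == 2


class TestApplyScreen:
    def criteria(self, **kw):
        return ms.ScreenCriteria("A", **kw)

    def test_planted_gene_is_a_hit_and_boundary_is_strict(self, small_cohort):
        nm, ann = small_cohort
        s = ms.summarize_by_subtype(nm, ann)
        hits = {h.gene_id: h for h in ms.apply_screen(s, self.criteria())}
        assert hits["HOT"].hit                         # median 12 > 8, bg q95 < 0.15
        assert not hits["HIGH"].hit                    # high everywhere: cond2 fails
        assert not hits["FLAT"].hit
        # target median exactly at the threshold is NOT "more than" the threshold
        s9 = ms.summarize_by_subtype(nm, ann)
        at_thresh = {h.gene_id: h for h in ms.apply_screen(s9, self.criteria(median_min=12.0))}
        assert not at_thresh["HOT"].cond1

    def test_matches_triple_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_genes = rng.integers(5, 50)
            ns = rng.integers(3, 11, size=3)
            samples = [f"s{i}" for i in range(int(ns.sum()))]
            labels = pd.Series(
                np.repeat(["A", "B", "C"], ns), index=samples
            )
            vals = pd.DataFrame(
                rng.lognormal(0, 2, (int(n_genes), len(samples))),
                index=[f"g{i}" for i in range(int(n_genes))] ,
                columns=samples,
            )
            vals.loc["TBP"] = 1.0
            nm = ms.NormalizedMatrix(vals, reference_gene="TBP")
            ann = ms.SampleAnnotation(labels)
            s = ms.summarize_by_subtype(nm, ann, q=95)
            c = self.criteria(median_min=1.0, background_q_max=2.0)
            got = set(selected_genes(ms.apply_screen(s, c)))
            want = brute_screen(s.medians, s.percentiles, "A", 1.0, 2.0)
            assert got == want

    def test_monotone_in_both_thresholds(self, default_sim):
        _, expr, ann, _ = default_sim
        nm = ms.normalize_by_reference(expr, "TBP")
        s = ms.summarize_by_subtype(nm, ann)
        base = set(selected_genes(ms.apply_screen(s, ms.ScreenCriteria("chromophobe"))))
        for c in (
            ms.ScreenCriteria("chromophobe", median_min=12.0),
            ms.ScreenCriteria("chromophobe", background_q_max=0.05),
            ms.ScreenCriteria("chromophobe", median_min=20.0, background_q_max=0.01),
        ):
            assert set(selected_genes(ms.apply_screen(s, c))) <= base

    def test_permutation_invariance_over_sample_order(self, small_cohort):
        nm, ann = small_cohort
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(nm.sample_ids))
        nm2 = ms.NormalizedMatrix(nm.values[perm], reference_gene="TBP")
        s1 = ms.summarize_by_subtype(nm, ann)
        s2 = ms.summarize_by_subtype(nm2, ann)
        pd.testing.assert_frame_equal(s1.medians, s2.medians)
        pd.testing.assert_frame_equal(s1.percentiles, s2.percentiles)

    def test_output_sorted_by_target_median_then_gene_id(self, small_cohort):
        nm, ann = small_cohort
        hits = ms.apply_screen(ms.summarize_by_subtype(nm, ann), self.criteria())
        keys = [(-h.target_median, h.gene_id) for h in hits]
        assert keys == sorted(keys)

    def test_missing_target_subtype_errors(self, small_cohort):
        nm, ann = small_cohort
        s = ms.summarize_by_subtype(nm, ann)
        with pytest.raises(ValueError, match="'Z'"):
            ms.apply_screen(s, ms.ScreenCriteria("Z"))


class TestConditionCounts:
    def test_counts_and_percentages(self, small_cohort):
        nm, ann = small_cohort
        s = ms.summarize_by_subtype(nm, ann)
        out = ms.condition_counts(s, ms.ScreenCriteria("A"))
        assert out["total_genes"] == 4
        assert out["condition1"] == {"count": 2, "percent": 50.0}  # HOT and HIGH
        assert out["condition2"]["B"]["count"] == 1                # HOT only
        assert out["condition2"]["B"]["percent"] == 25.0

    def test_all_and_none_edge_cases(self, small_cohort):
        nm, ann = small_cohort
        s = ms.summarize_by_subtype(nm, ann)
        none = ms.condition_counts(s, ms.ScreenCriteria("A", median_min=1e9))
        assert none["condition1"] == {"count": 0, "percent": 0.0}
        everything = ms.condition_counts(
            s, ms.ScreenCriteria("A", median_min=0.5, background_q_max=1e9)
        )
        assert everything["condition2"]["C"]["percent"] == 100.0


def test_hits_frame_columns(small_cohort):
    nm, ann = small_cohort
    hits = ms.apply_screen(ms.summarize_by_subtype(nm, ann), ms.ScreenCriteria("A"))
    df = hits_frame(hits, q=95)
    assert list(df.columns) == [
        "gene_id", "target_median", "q95_B", "q95_C", "cond1", "cond2_B", "cond2_C", "hit",
    ]
    assert df.loc[df.gene_id == "HOT", "hit"].item()
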