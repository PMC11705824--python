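"""Greedy matching, signed-rank oracle equivalence, paired DA recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micropair import (
    SyntheticConfig,
    benjamini_hochberg,
    clr_transform,
    generate_cohort,
    match_nearest_neighbor,
    paired_da,
    pca,
    replace_zeros,
    select_components,
    wilcoxon_signed_rank,
)

from conftest import simplex_table


def _scores(coords, ids):
    return pd.DataFrame({"PC1": coords}, index=ids)


class TestMatchNearestNeighbor:
    def test_printed_1d_example_matches_exhaustive_optimum(self, two_group_meta):
        ids = ["a", "b", "c", "x", "y", "z"]
        scores = _scores([0.0, 10.0, 20.0, 1.0, 9.0, 30.0], ids)
        meta = two_group_meta(["a", "b", "c"], ["x", "y", "z"])
        got = {(c, h) for c, h, _ in match_nearest_neighbor(scores, meta).pairs}
        assert got == {("a", "x"), ("b", "y"), ("c", "z")}
        # exhaustive check: greedy equals the best of all 6 bijections here
        coords = dict(zip(ids, scores["PC1"]))
        best = min(
            itertools.permutations(["x", "y", "z"]),
            key=lambda p: sum(abs(coords[c] - coords[h]) for c, h in zip("abc", p)),
        )
        assert got == set(zip("abc", best))

    def test_zero_distance_pair_formed_first(self, two_group_meta):
        scores = _scores([5.0, 1.0, 5.0, 0.0], ["c1", "c2", "h1", "h2"])
        meta = two_group_meta(["c1", "c2"], ["h1", "h2"])
        pairs = match_nearest_neighbor(scores, meta)
        assert pairs.pairs[0] == ("c1", "h1", 0.0)

    def test_perfect_bijection_at_distance_zero_recovered(self, two_group_meta):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=10)
        case_ids = [f"c{i}" for i in range(10)]
        ctrl_ids = [f"h{i}" for i in range(10)]
        scores = pd.DataFrame(
            {"PC1": np.concatenate([coords, coords])}, index=case_ids + ctrl_ids
        )
        meta = two_group_meta(case_ids, ctrl_ids)
        pairs = match_nearest_neighbor(scores, meta)
        assert {(c, h) for c, h, _ in pairs.pairs} == {
            (f"c{i}", f"h{i}") for i in range(10)
        }
        assert all(d == 0.0 for _, _, d in pairs.pairs)

    def test_injective_and_deterministic(self, two_group_meta):
        rng = np.random.default_rng(2)
        case_ids = [f"c{i:02d}" for i in range(12)]
        ctrl_ids = [f"h{i:02d}" for i in range(9)]
        scores = pd.DataFrame(
            rng.normal(size=(21, 3)), index=case_ids + ctrl_ids,
            columns=["PC1", "PC2", "PC3"]
        )
        meta = two_group_meta(case_ids, ctrl_ids)
        a = match_nearest_neighbor(scores, meta)
        b = match_nearest_neighbor(scores, meta)
        assert a.pairs == b.pairs
        assert len(set(a.control_ids)) == len(a.control_ids) == 9
        assert len(a.unmatched_cases) == 3

    def test_53_cases_47_controls_yield_47_pairs(self, default_cohort):
        table, meta, _ = default_cohort
        from micropair import FilterRule, filter_rare_taxa

        filtered, _ = filter_rare_taxa(table, FilterRule())
        ordn = pca(clr_transform(replace_zeros(filtered)))
        select_components(ordn, 0.70)
        pairs = match_nearest_neighbor(ordn.selected_scores(), meta)
        assert pairs.n_pairs == 47
        assert len(pairs.unmatched_cases) == 6

    def test_k_exceeding_components_rejected(self, two_group_meta):
        scores = _scores([0.0, 1.0], ["c1", "h1"])
        meta = two_group_meta(["c1"], ["h1"])
        with pytest.raises(ValueError, match="exceeds"):
            match_nearest_neighbor(scores, meta, k=5)


def _enumeration_p(diffs):
    """Independent oracle: exact two-sided p over all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [
            ranks[list(s)].sum()
            for r in range(len(d) + 1)
            for s in itertools.combinations(range(len(d)), r)
        ]
    )
    lo = (w_all <= w_obs + 1e-9).sum()
    hi = (w_all >= w_obs - 1e-9).sum()
    return min(1.0, 2 * min(lo, hi) / len(w_all))


class TestWilcoxonSignedRank:
    @pytest.mark.parametrize(
        "diffs,w,p",
        [
            ([1, 2, 3, 4, 5], 15.0, 0.0625),
            ([1, -2, 3, -4], 4.0, 0.875),
        ],
    )
    def test_printed_examples(self, diffs, w, p):
        res = wilcoxon_signed_rank(diffs)
        assert res.w == w
        assert res.p == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_p_equals_sign_pattern_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        mags = np.sort(rng.uniform(0.5, 20.0, size=n))
        assert np.unique(mags).size == n
        for signs in itertools.product([1.0, -1.0], repeat=n):
            d = mags * np.array(signs)
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(_enumeration_p(d), abs=1e-12)

    def test_zeros_dropped_before_ranking(self):
        with_zeros = wilcoxon_signed_rank([0.0, 1, 2, 3, 0.0, 4, 5])
        without = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert with_zeros.p == without.p
        assert with_zeros.n_used == 5

    def test_all_zero_is_degenerate_not_one(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.degenerate
        assert np.isnan(res.p)

    def test_null_p_behaves_uniformly_at_n20(self):
        # the exact two-sided p is discrete; compare its moments and tail
        # mass with the uniform distribution instead of a straight KS fit
        rng = np.random.default_rng(33)
        pvals = np.array(
            [wilcoxon_signed_rank(rng.normal(size=20)).p for _ in range(300)]
        )
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.08)
        assert np.mean(pvals <= 0.05) == pytest.approx(0.05, abs=0.03)
        assert np.mean(pvals <= 0.5) == pytest.approx(0.5, abs=0.1)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_and_degenerate_inputs(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_preserves_input_order_and_dominates_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        # q of the sorted p is monotone non-decreasing
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_realized_fdr_under_null(self):
        rng = np.random.default_rng(44)
        false_rates = []
        for _ in range(500):
            q = benjamini_hochberg(rng.uniform(size=50))
            r = (q <= 0.1).sum()
            false_rates.append(1.0 if r > 0 else 0.0)
        assert np.mean(false_rates) <= 0.15


def _pipeline_pairs(table, meta):
    ordn = pca(clr_transform(replace_zeros(table)))
    select_components(ordn, 0.70)
    return match_nearest_neighbor(ordn.selected_scores(), meta)


class TestPairedDa:
    def test_spiked_taxa_take_smallest_p_values(self, small_cohort):
        (table, meta, truth), cfg = small_cohort
        da = paired_da(table, _pipeline_pairs(table, meta))
        spiked = set(truth.case_spiked) | set(truth.control_spiked)
        assert set(da.nsmallest(14, "p").index) == spiked
        hits = da.loc[sorted(spiked)]
        case_dirs = hits.loc[truth.case_spiked, "direction"]
        assert (case_dirs == "case-enriched").all()
        assert (hits.loc[truth.control_spiked, "direction"] == "control-enriched").all()

    def test_recovery_rate_across_replicates(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_taxa=80, n_rare_removable=0,
                                  spike_min_rank=10, spike_max_rank=70)
            table, meta, truth = generate_cohort(cfg)
            da = paired_da(table, _pipeline_pairs(table, meta))
            spiked = set(truth.case_spiked) | set(truth.control_spiked)
            hits += set(da.nsmallest(14, "p").index) == spiked
        assert hits / 10 >= 0.8

    def test_degenerate_taxon_flagged_and_outside_fdr_family(self, two_group_meta):
        # taxon 0 identical within every pair -> all differences zero
        case_rows = np.array([[0.2, 0.5, 0.3], [0.2, 0.6, 0.2]])
        ctrl_rows = np.array([[0.2, 0.4, 0.4], [0.2, 0.7, 0.1]])
        table = simplex_table(
            np.vstack([case_rows, ctrl_rows]), sample_ids=["c1", "c2", "h1", "h2"]
        )
        meta = two_group_meta(["c1", "c2"], ["h1", "h2"])
        from micropair.matching import MatchedPairSet

        pairs = MatchedPairSet(
            pairs=[("c1", "h1", 0.0), ("c2", "h2", 0.0)], unmatched_cases=[],
            k_components=1
        )
        da = paired_da(table, pairs)
        first = da.iloc[0]
        assert first["degenerate"]
        assert np.isnan(first["q"])
        assert not da.iloc[1]["degenerate"]

    def test_missing_pair_sample_rejected(self, small_cohort):
        (table, meta, _), _ = small_cohort
        from micropair.matching import MatchedPairSet

        pairs = MatchedPairSet(pairs=[("nope", "ctrl_001", 0.0)], unmatched_cases=[],
                               k_components=1)
        with pytest.raises(ValueError, match="missing"):
            paired_da(table, pairs)

    def test_paired_beats_unpaired_when_clusters_dominate(self):
        wins = 0
        for seed in range(8):
            cfg = SyntheticConfig(
                seed=seed, spike_fold=1.5, n_taxa=80, n_rare_removable=0,
                spike_min_rank=10, spike_max_rank=70,
            )
            assert cfg.pair_cluster_sd >= 3 * cfg.subject_sd
            table, meta, truth = generate_cohort(cfg)
            da = paired_da(table, _pipeline_pairs(table, meta))
            spiked = sorted(set(truth.case_spiked) | set(truth.control_spiked))
            sens_paired = np.mean([da.loc[t, "p"] <= 0.05 for t in spiked])
            p_unpaired = [
                stats.mannwhitneyu(
                    table.data.loc[meta.cases, t], table.data.loc[meta.controls, t],
                    alternative="two-sided",
                ).pvalue
                for t in spiked
            ]
            sens_unpaired = np.mean(np.asarray(p_unpaired) <= 0.05)
            wins += sens_paired > sens_unpaired
        assert wins >= 7
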