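"""Calprotectin flags, linear-model associations, Kendall oracle, RDA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micropair import (
    BiomarkerPanel,
    SyntheticConfig,
    classify_calprotectin,
    clr_transform,
    generate_cohort,
    kendall_matrix,
    rda_rank,
    replace_zeros,
    screen_blood_biomarkers,
    taxon_biomarker_glm,
)
from micropair.preprocess import ClrMatrix
from micropair.tables import CALPROTECTIN

from conftest import simplex_table


def _panel(values, threshold=35.0):
    frame = pd.DataFrame({CALPROTECTIN: values},
                         index=[f"s{i}" for i in range(len(values))])
    return BiomarkerPanel(frame, threshold)


class TestClassifyCalprotectin:
    def test_boundary_and_outlier_values(self):
        flags = classify_calprotectin(_panel([59.15, 35.0, 0.0, 35.01]))
        assert list(flags) == [True, False, False, True]

    def test_missing_stays_missing(self):
        flags = classify_calprotectin(_panel([np.nan, 40.0]))
        assert flags.iloc[0] is pd.NA
        assert bool(flags.iloc[1])

    def test_monotone_in_threshold(self):
        values = [10.0, 30.0, 36.0, 80.0, 200.0]
        low = classify_calprotectin(_panel(values, threshold=20.0)).fillna(False)
        high = classify_calprotectin(_panel(values, threshold=50.0)).fillna(False)
        assert (high <= low).all()

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            classify_calprotectin(_panel([-1.0]))


class TestTaxonBiomarkerGlm:
    def test_exact_linear_dependence_recovered(self, two_group_meta):
        # invert the half-minimum pseudocount so the transformed
        # abundance is exactly linear in the standardized log-marker
        rng = np.random.default_rng(0)
        n = 40
        marker = rng.uniform(10, 100, n)
        z = (np.log(marker) - np.log(marker).mean()) / np.log(marker).std()
        y = -3.0 + 0.7 * z + rng.normal(0, 1e-9, n)
        target = np.exp(y) - np.exp(y.min()) / 3.0
        other = np.full(n, 0.05)
        bulk = 1.0 - target - other
        ids = [f"s{i}" for i in range(n)]
        table = simplex_table(np.column_stack([target, other, bulk]),
                              sample_ids=ids, taxa=["t_target", "t_other", "t_bulk"])
        meta = two_group_meta(ids[: n // 2], ids[n // 2:])
        panel = BiomarkerPanel(pd.DataFrame({CALPROTECTIN: marker}, index=ids))
        out = taxon_biomarker_glm(table, panel, meta, ["t_target"])
        row = out.iloc[0]
        assert row["coefficient"] == pytest.approx(0.7, abs=1e-6)
        assert row["p"] < 1e-100
        assert row["sign"] == "positive"

    def test_coupled_taxa_found_uncoupled_left_alone(self):
        found = 0
        spared = []
        for seed in range(15):
            cfg = SyntheticConfig(seed=seed, n_taxa=80, n_rare_removable=0,
                                  spike_min_rank=10, spike_max_rank=70)
            table, meta, truth = generate_cohort(cfg)
            panel = BiomarkerPanel.from_metadata(meta)
            candidates = truth.case_spiked + truth.control_spiked
            out = taxon_biomarker_glm(table, panel, meta, candidates,
                                      biomarkers=[CALPROTECTIN])
            sig_pos = set(out.loc[out.significant_at_10pct_fdr
                                  & (out.sign == "positive"), "taxon"])
            coupled = {t for t in truth.coupled if t in truth.case_spiked}
            found += coupled <= sig_pos
            uncoupled = [t for t in candidates if t not in truth.coupled]
            spared.append(np.mean([t not in sig_pos for t in uncoupled]))
        assert found / 15 >= 0.8
        assert np.mean(spared) >= 0.9

    def test_permuted_biomarker_controls_fdr(self):
        false_rates = []
        for seed in range(30):
            cfg = SyntheticConfig(seed=seed, n_taxa=40, n_rare_removable=0,
                                  coupling_slope=0.0, spike_fold=1.0,
                                  spike_min_rank=5, spike_max_rank=35)
            table, meta, _ = generate_cohort(cfg)
            panel = BiomarkerPanel.from_metadata(meta)
            out = taxon_biomarker_glm(table, panel, meta, table.taxa[:20],
                                      biomarkers=[CALPROTECTIN])
            r = int(out["significant_at_10pct_fdr"].sum())
            false_rates.append(1.0 if r > 0 else 0.0)
        assert np.mean(false_rates) <= 0.15

    def test_empty_subset_rejected(self, small_cohort):
        (table, meta, _), _ = small_cohort
        panel = BiomarkerPanel.from_metadata(meta)
        with pytest.raises(ValueError):
            taxon_biomarker_glm(table, panel, meta, [])


class TestKendallMatrix:
    def test_perfect_concordance_and_discordance(self, two_group_meta):
        n = 6
        up = np.linspace(0.01, 0.2, n)
        table = simplex_table(np.column_stack([up, up[::-1], 1 - up - up[::-1]]),
                              sample_ids=[f"s{i}" for i in range(n)],
                              taxa=["t_up", "t_down", "t_bulk"])
        panel = _panel(np.arange(1.0, n + 1))
        out = kendall_matrix(table, panel, ["t_up", "t_down"])
        assert out.loc["t_up", CALPROTECTIN] == pytest.approx(1.0)
        assert out.loc["t_down", CALPROTECTIN] == pytest.approx(-1.0)

    @staticmethod
    def _brute_force_tau_b(x, y):
        n = len(x)
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx == dy:
                    conc += 1
                else:
                    disc += 1
        denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
        return (conc - disc) / denom

    def test_tie_corrected_example(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 3]
        expected = self._brute_force_tau_b(x, y)
        got = stats.kendalltau(x, y).statistic
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(5, 25)
            x = rng.integers(0, 8, n).astype(float)
            y = rng.integers(0, 8, n).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            assert stats.kendalltau(x, y).statistic == pytest.approx(
                self._brute_force_tau_b(x, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        n = 20
        vals = rng.dirichlet(np.ones(3), size=n)
        table = simplex_table(vals, sample_ids=[f"s{i}" for i in range(n)],
                              taxa=["a", "b", "c"])
        marker = rng.uniform(1, 100, n)
        t1 = kendall_matrix(table, _panel(marker), ["a"])
        t2 = kendall_matrix(table, _panel(np.exp(marker / 30)), ["a"])
        assert t1.loc["a", CALPROTECTIN] == pytest.approx(
            t2.loc["a", CALPROTECTIN], abs=1e-12
        )


def _clr_mat(values, ids):
    centered = values - values.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(centered, index=ids,
                                  columns=[f"t{j}" for j in range(values.shape[1])]))


class TestRdaRank:
    def test_exact_linear_data_fully_constrained(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(size=n)
        beta = np.array([2.0, -1.0, 0.5, -1.5])  # zero-sum: valid CLR direction
        mat = _clr_mat(np.outer(x, beta), [f"s{i}" for i in range(n)])
        cov = pd.Series(x, index=mat.data.index)
        rda = rda_rank(mat, cov)
        assert rda.constrained_variance_fraction == pytest.approx(1.0, abs=1e-10)
        assert list(rda.ranking.index) == ["t0", "t3", "t1", "t2"]

    def test_independent_covariate_explains_little(self):
        rng = np.random.default_rng(2)
        n = 60
        mat = _clr_mat(rng.normal(size=(n, 20)), [f"s{i}" for i in range(n)])
        cov = pd.Series(rng.normal(size=n), index=mat.data.index)
        assert rda_rank(mat, cov).constrained_variance_fraction < 0.1

    def test_affine_covariate_rescaling_preserves_ranking(self):
        rng = np.random.default_rng(3)
        n = 40
        mat = _clr_mat(rng.normal(size=(n, 10)), [f"s{i}" for i in range(n)])
        cov = pd.Series(rng.uniform(5, 50, n), index=mat.data.index)
        a = rda_rank(mat, cov)
        b = rda_rank(mat, cov * 3.7 - 12.0)
        assert list(a.ranking.index) == list(b.ranking.index)
        assert a.constrained_variance_fraction == pytest.approx(
            b.constrained_variance_fraction, abs=1e-12
        )

    def test_coupled_taxa_occupy_top_ranks(self):
        hits = 0
        for seed in range(15):
            cfg = SyntheticConfig(seed=seed, n_taxa=80, n_rare_removable=0,
                                  spike_min_rank=10, spike_max_rank=70,
                                  n_coupled_case_spiked=3, n_coupled_other=2)
            table, meta, truth = generate_cohort(cfg)
            mat = clr_transform(replace_zeros(table))
            cov = np.log(meta.frame[CALPROTECTIN])
            hits += set(rda_rank(mat, cov).top(5)) == set(truth.coupled)
        assert hits / 15 >= 0.8

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(5)
        mat = _clr_mat(rng.normal(size=(10, 4)), [f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="constant"):
            rda_rank(mat, pd.Series(np.ones(10), index=mat.data.index))


class TestBloodScreen:
    def test_shifted_marker_selected_null_markers_mostly_not(self, small_cohort):
        (table, meta, _), _ = small_cohort
        frame = meta.frame.copy()
        rng = np.random.default_rng(17)
        frame["shifted_marker"] = rng.normal(0, 1, len(frame)) + (
            frame["group"] == "case"
        ) * 2.0
        meta2 = type(meta)(frame)
        panel = BiomarkerPanel.from_metadata(meta2)
        out = screen_blood_biomarkers(panel, meta2).set_index("biomarker")
        assert bool(out.loc["shifted_marker", "selected"])
        assert out.loc["shifted_marker", "p"] < 1e-6
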