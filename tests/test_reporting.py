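"""Cohort statistics: summaries, signed-rank tests, correlations, study runs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import scoliosim as ss
from scoliosim.reporting import run_study, summarize_cohort, wilcoxon_vs, pearson_r
from scoliosim.synthetic import load_reference_cohort


def wilcoxon_enumeration(values, reference=100.0):
    """Exhaustive 2^n sign-flip null distribution (oracle for small n)."""
    d = np.asarray(values, float) - reference
    d = d[d != 0]
    n = d.size
    ranks = sstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


class TestSummarize:
    def test_reference_cohort_summary_matches_printed_statistics(self):
        df = load_reference_cohort()
        summary = summarize_cohort(df)
        assert round(summary.loc["age_y", "mean"], 1) == 13.8
        assert round(summary.loc["age_y", "sd"], 1) == 1.8
        assert round(summary.loc["height_cm", "mean"], 1) == 161.2
        assert round(summary.loc["height_cm", "sd"], 1) == 12.3
        assert round(summary.loc["mass_kg", "mean"], 1) == 47.5
        assert round(summary.loc["mass_kg", "sd"], 1) == 8.0
        assert round(summary.loc["cobb_deg", "mean"], 1) == 22.1
        assert round(summary.loc["cobb_deg", "sd"], 1) == 4.4

    def test_hand_computed_sd(self):
        df = pd.DataFrame({"v": [10.0, 20.0]})
        s = summarize_cohort(df)
        assert s.loc["v", "mean"] == pytest.approx(15.0)
        assert s.loc["v", "sd"] == pytest.approx(7.0710678, abs=1e-6)

    def test_constant_column_has_zero_sd(self):
        s = summarize_cohort(pd.DataFrame({"v": [3.0, 3.0, 3.0]}))
        assert s.loc["v", "sd"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame({"v": [1.0]}))


class TestWilcoxon:
    def test_symmetric_pair_gives_p_one(self):
        t = wilcoxon_vs([90.0, 110.0])
        assert t.p_value == pytest.approx(1.0)

    def test_five_positive_values_exact_tail(self):
        t = wilcoxon_vs([101, 102, 103, 104, 105])
        assert t.p_value == pytest.approx(0.0625)
        assert t.n_effective == 5

    def test_all_at_reference(self):
        t = wilcoxon_vs([100.0, 100.0])
        assert t.p_value == 1.0 and t.n_effective == 0

    def test_twenty_four_positive_values_minimal_p(self):
        t = wilcoxon_vs(100.0 + np.arange(1, 25))
        assert t.p_value == pytest.approx(2.0 * 2.0**-24)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        values = 100.0 + np.round(rng.normal(0, 5, n), 1)
        t = wilcoxon_vs(values)
        assert t.p_value == pytest.approx(wilcoxon_enumeration(values), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(1)
        values = 100.0 + rng.normal(0, 5, 12)  # continuous -> no ties
        t = wilcoxon_vs(values)
        ref = sstats.wilcoxon(values - 100.0, alternative="two-sided", method="exact")
        assert t.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        values = 100.0 + rng.normal(1.0, 4.0, 60)
        t = wilcoxon_vs(values)
        ref = sstats.wilcoxon(values - 100.0, alternative="two-sided", method="approx", correction=True)
        assert t.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert 0.0 <= t.p_value <= 1.0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-9

    def test_constructed_orthogonality(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_sentinel(self):
        r, p = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)


@pytest.fixture(scope="module")
def tiny_study():
    cohort = ss.generate_cohort(ss.CohortParams(n=2, seed=9))
    return cohort, run_study(cohort)


class TestRunStudy:

    def test_outputs_are_complete(self, tiny_study, tmp_path):
        cohort, result = tiny_study
        assert result.manifest["n_solved"] == 2
        assert not result.failed
        assert set(result.percents_long.condition) >= {
            "unloaded_vs_undeformed", "backpack", "frontpack",
            "sidepack_concave", "sidepack_convex",
        }
        result.save(tmp_path)
        for name in ("cohort_summary.csv", "forces_long.csv", "percents_long.csv",
                     "ratios.csv", "tests.csv", "manifest.json"):
            assert (tmp_path / name).exists()

    def test_deterministic_rerun(self, tiny_study):
        cohort, result = tiny_study
        again = run_study(cohort)
        pd.testing.assert_frame_equal(result.percents_long, again.percents_long)
        pd.testing.assert_frame_equal(result.forces_long, again.forces_long)

    def test_percent_of_unloaded_monotone_per_subject(self, tiny_study):
        _, result = tiny_study
        pl = result.percents_long
        loaded = pl[pl.condition != "unloaded_vs_undeformed"]
        for (_, _, _), grp in loaded.groupby(["subject_id", "condition", "level_offset"]):
            v = grp.sort_values("pct_bw").pct_of_reference.to_numpy()
            assert np.all(np.diff(v) > 0)
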