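"""Cohort statistics against brute-force textbook oracles."""

import numpy as np
import pandas as pd
import pytest

from deutwater.cohort import (
    correlations,
    covariate_check_anova,
    group_summary,
    normalize_to_subject_mean,
    paired_first_last,
    subject_means,
    turnover_mass_slope,
)


@pytest.fixture
def long_df():
    rng = np.random.default_rng(7)
    rows = []
    for i, (sid, sex) in enumerate([("A", "M"), ("B", "M"), ("C", "F"), ("D", "F")]):
        for p in range(5):
            rows.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "period_order": p,
                    "body_mass": 3000 + 800 * i + rng.normal(0, 50),
                    "water_turnover": 200 + 30 * i + rng.normal(0, 10),
                    "fat_percent": 10 + rng.normal(0, 1),
                }
            )
    return pd.DataFrame(rows)


class TestSubjectMeansAndGroups:
    def test_subject_means_equal_brute_force(self, long_df):
        means = subject_means(long_df, ["water_turnover"]).set_index("subject_id")
        for sid, sub in long_df.groupby("subject_id"):
            brute = sum(sub.water_turnover) / len(sub)
            assert means.loc[sid, "water_turnover"] == pytest.approx(brute, rel=1e-12)

    def test_single_period_subject_is_identity(self):
        df = pd.DataFrame(
            {"subject_id": ["X"], "sex": ["F"], "water_turnover": [123.4]}
        )
        means = subject_means(df, ["water_turnover"])
        assert means.water_turnover.iloc[0] == 123.4
        assert means.sex.iloc[0] == "F"

    def test_reference_group_turnover(self, reference):
        """Male mean 359; female mean 241 and SD 28 after rounding."""
        summaries = {
            s.group: s for s in group_summary(reference, "water_turnover")
        }
        assert round(summaries["M"].mean) == 359
        assert round(summaries["F"].mean) == 241
        assert round(summaries["F"].sd) == 28

    def test_identical_values_have_zero_sd(self):
        df = pd.DataFrame(
            {"subject_id": list("abc"), "sex": ["F"] * 3, "v": [5.0, 5.0, 5.0]}
        )
        (s,) = group_summary(df, "v")
        assert s.sd == 0.0 and s.mean == 5.0 and s.n == 3


class TestNormalization:
    def test_simple_series(self):
        df = pd.DataFrame({"subject_id": ["a"] * 3, "v": [2.0, 4.0, 6.0]})
        out = normalize_to_subject_mean(df, ["v"])
        assert out.v.tolist() == [0.5, 1.0, 1.5]

    def test_constant_series_all_ones_and_unit_invariance(self, long_df):
        const = pd.DataFrame({"subject_id": ["a"] * 4, "v": [3.3] * 4})
        assert normalize_to_subject_mean(const, ["v"]).v.tolist() == [1.0] * 4
        a = normalize_to_subject_mean(long_df, ["water_turnover"]).water_turnover
        rescaled = long_df.assign(water_turnover=long_df.water_turnover * 3.785)
        b = normalize_to_subject_mean(rescaled, ["water_turnover"]).water_turnover
        assert np.allclose(a, b)

    def test_normalized_mean_is_one_per_subject(self, long_df):
        out = normalize_to_subject_mean(long_df, ["body_mass"])
        per = out.groupby("subject_id").body_mass.mean()
        assert np.allclose(per, 1.0)


class TestPairedFirstLast:
    def test_no_change_gives_null(self):
        df = pd.DataFrame(
            {
                "subject_id": list("aabbcc"),
                "period_order": [0, 1] * 3,
                "v": [5.0, 5.0, 7.0, 7.0, 9.0, 9.0],
            }
        )
        t, dof, p = paired_first_last(df, "v")
        assert t == 0.0 and dof == 2 and p == 1.0

    def test_constant_nonzero_differences_are_degenerate(self):
        df = pd.DataFrame(
            {
                "subject_id": list("aabbccdd"),
                "period_order": [0, 1] * 4,
                "v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            }
        )
        with pytest.raises(ValueError, match="zero variance"):
            paired_first_last(df, "v")

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(11)
        first = rng.normal(100, 10, 6)
        last = first + rng.normal(2, 5, 6)
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(list("abcdef"), 2),
                "period_order": [0, 1] * 6,
                "v": np.ravel(np.column_stack([first, last])),
            }
        )
        t, dof, p = paired_first_last(df, "v")
        d = last - first
        t_brute = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_brute, rel=1e-10)
        assert dof == 5

    def test_first_last_taken_in_chronological_order(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "a", "b", "b"],
                "period_order": [2, 0, 1, 1, 0],  # shuffled
                "v": [30.0, 10.0, 20.0, 8.0, 4.0],
            }
        )
        t, dof, _ = paired_first_last(df, "v")
        # a: 10 -> 30 (+20); b: 4 -> 8 (+4): mean 12, sd 11.3137
        d = np.array([20.0, 4.0])
        assert t == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(2)), rel=1e-10)


class TestCorrelations:
    def test_perfect_and_anti_correlation(self):
        df = pd.DataFrame({"subject_id": "a", "x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        (r, t, dof, p) = correlations(df, "x", "y")["pooled"]
        assert r == pytest.approx(1.0)
        df["y"] = -df["y"]
        (r, _, _, _) = correlations(df, "x", "y")["pooled"]
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {"subject_id": "a", "x": rng.normal(size=30), "y": rng.normal(size=30)}
        )
        (r, t, dof, p) = correlations(df, "x", "y")["pooled"]
        x, y = df.x.to_numpy(), df.y.to_numpy()
        r_brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(r_brute, rel=1e-10)
        assert t == pytest.approx(r_brute * np.sqrt(28 / (1 - r_brute**2)), rel=1e-10)
        assert dof == 28

    def test_within_subject_scope(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(["a", "b"], 10),
                "x": rng.normal(size=20),
            }
        )
        df["y"] = df.x * np.where(df.subject_id == "a", 1.0, -1.0) + rng.normal(
            0, 0.1, 20
        )
        within = correlations(df, "x", "y", scope="within-subject")
        assert within["a"][0] > 0.9
        assert within["b"][0] < -0.9
        assert all(v[2] == 8 for v in within.values())


class TestTurnoverMassSlope:
    def test_reference_cohort_slope(self, reference):
        assert round(turnover_mass_slope(reference), 1) == 4.5

    def test_two_points_exact(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "water_turnover": [200.0, 300.0],
                "body_mass": [3000.0, 5000.0],
            }
        )
        assert turnover_mass_slope(df) == pytest.approx(100.0 * 100.0 / 2000.0)

    def test_invariant_under_turnover_offset(self, reference):
        shifted = reference.assign(water_turnover=reference.water_turnover + 50.0)
        assert turnover_mass_slope(shifted) == pytest.approx(
            turnover_mass_slope(reference), rel=1e-12
        )


class TestCovariateAnova:
    def test_hand_computed_balanced_two_by_two(self):
        """Textbook sums of squares on a 2x2 design with 2 replicates."""
        df = pd.DataFrame(
            {
                "time_of_day": ["am", "am", "am", "am", "pm", "pm", "pm", "pm"],
                "subject_id": ["s1", "s1", "s2", "s2", "s1", "s1", "s2", "s2"],
                "v": [10.0, 12.0, 11.0, 13.0, 14.0, 16.0, 19.0, 21.0],
            }
        )
        # by hand: grand mean 14.5; SS_time = 72, SS_subject = 18,
        # SS_interaction = 8, SS_within = 8 on 4 df -> F = 36, 9, 4
        table = covariate_check_anova(df, "v")
        f = {i: row for i, row in table.iterrows()}
        assert f["C(time_of_day)"]["F"] == pytest.approx(36.0, rel=1e-10)
        assert f["C(subject_id)"]["F"] == pytest.approx(9.0, rel=1e-10)
        assert f["C(time_of_day):C(subject_id)"]["F"] == pytest.approx(4.0, rel=1e-10)

    def test_identical_groups_give_negligible_f(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "time_of_day": ["am", "pm"] * 6,
                "subject_id": np.repeat(["s1", "s2"], 6),
                # pure noise with no group structure at all
                "v": 5.0 + rng.normal(0, 1e-6, 12),
            }
        )
        table = covariate_check_anova(df, "v")
        assert table.loc["C(time_of_day)", "PR(>F)"] > 0.05

    def test_null_factor_yields_uniformish_pvalues(self):
        """With no real effect, the time-of-day p-value is non-degenerate."""
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(50):
            df = pd.DataFrame(
                {
                    "time_of_day": ["am", "pm"] * 12,  # balanced within subject
                    "subject_id": np.repeat(["s1", "s2", "s3"], 8),
                    "v": rng.normal(10, 1, 24),
                }
            )
            pvals.append(covariate_check_anova(df, "v").loc["C(time_of_day)", "PR(>F)"])
        pvals = np.asarray(pvals)
        # roughly uniform: spread across (0,1), not piled at either end
        assert 0.2 < np.mean(pvals) < 0.8
        assert (pvals < 0.05).mean() < 0.25
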