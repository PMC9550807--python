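"""Logistic odds ratios, Bonferroni, group comparisons, family trends."""

import itertools

import numpy as np
import pandas as pd
import pytest

from famburden.association import (bonferroni_adjust, compare_groups,
                                   fit_logistic_or, freq_correlation,
                                   within_family_trend)
from famburden.datasets import load_family_scores


def crossprod_or(n11, n10, n01, n00):
    return (n11 * n00) / (n10 * n01)


class TestLogisticOR:
    def test_2x2_closed_form(self):
        # 30 exposed cases, 10 unexposed cases, 10 exposed controls,
        # 30 unexposed controls -> OR = 9
        x = [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30
        y = [1] * 40 + [0] * 40
        res = fit_logistic_or(x, y)
        assert res.odds_ratio == pytest.approx(9.0, abs=1e-6)
        assert res.ci95[0] < res.odds_ratio < res.ci95[1]

    def test_2x2_sweep(self):
        # all tables with every cell >= 5 on a coarse grid
        for n11, n10, n01, n00 in itertools.product((5, 12, 30), repeat=4):
            x = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
            y = [1] * (n11 + n10) + [0] * (n01 + n00)
            res = fit_logistic_or(x, y)
            assert res.odds_ratio == pytest.approx(
                crossprod_or(n11, n10, n01, n00), rel=1e-6
            )

    def test_complete_separation_sentinel(self):
        x = [0.0] * 20 + [1.0] * 20
        y = [0] * 20 + [1] * 20
        res = fit_logistic_or(x, y)
        assert res.separated
        assert np.isinf(res.odds_ratio)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_logistic_or([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])

    def test_ci_narrows_with_n(self):
        rng = np.random.default_rng(10)
        widths = []
        for n in (50, 200, 800):
            x = np.concatenate([rng.normal(0.5, 1, n), rng.normal(0, 1, n)])
            y = np.concatenate([np.ones(n), np.zeros(n)])
            r = fit_logistic_or(x, y)
            widths.append(np.log(r.ci95[1]) - np.log(r.ci95[0]))
        assert widths[0] > widths[1] > widths[2]

    def test_null_calibration(self):
        """Permutation null: type-I error at alpha=0.05 is 0.05 +/- 0.02."""
        rng = np.random.default_rng(11)
        n = 60
        x = rng.normal(size=n)
        hits = 0
        reps = 1000
        for _ in range(reps):
            y = rng.permutation([1] * 20 + [0] * 40)
            if fit_logistic_or(x, y).p_raw < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.02)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 4, 0.04), (0.5, 4, 1.0), (0.2, 1, 0.2),
    ])
    def test_closed_forms(self, p, m, expected):
        assert bonferroni_adjust([p], m)[0] == pytest.approx(expected)

    def test_default_m_and_monotone(self):
        ps = [0.01, 0.2, 0.04]
        adj = bonferroni_adjust(ps)
        assert adj == [pytest.approx(0.03), pytest.approx(0.6),
                       pytest.approx(0.12)]
        assert all(a >= p for a, p in zip(adj, ps))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestCompareGroups:
    def _table(self, rng, shift=0.0, n_case=30, n_ctrl=200):
        return pd.DataFrame({
            "group": ["familial_case"] * n_case
            + ["population_control"] * n_ctrl,
            "prs_z": np.concatenate([
                rng.normal(shift, 1, n_case), rng.normal(0, 1, n_ctrl)
            ]),
        })

    def test_single_comparison_identity(self):
        rng = np.random.default_rng(12)
        t = self._table(rng, shift=1.0)
        out = compare_groups(t, [("familial_case", "population_control")],
                             score_types=("prs_z",))
        assert out.iloc[0]["p_adjusted"] == pytest.approx(
            out.iloc[0]["p_raw"]
        )
        assert out.iloc[0]["odds_ratio"] > 1

    def test_empty_group_skipped(self):
        rng = np.random.default_rng(13)
        t = self._table(rng)
        out = compare_groups(
            t, [("familial_case", "sporadic_case"),
                ("familial_case", "population_control")],
            score_types=("prs_z",),
        )
        assert len(out) == 1

    def test_null_adjusted_p_high_on_average(self):
        rng = np.random.default_rng(14)
        vals = []
        for _ in range(50):
            t = self._table(rng, shift=0.0, n_case=40, n_ctrl=40)
            out = compare_groups(t, [("familial_case", "population_control")],
                                 score_types=("prs_z",), m=4)
            vals.append(out.iloc[0]["p_adjusted"])
        assert np.mean(vals) > 0.6


class TestWithinFamilyTrend:
    def test_published_listing_family_means(self):
        df = load_family_scores()
        summary, count, not_comp = within_family_trend(df)
        f1 = summary.set_index("family_id").loc["FMS01"]
        assert f1["weighted_mean_affected"] == pytest.approx(1.8175)
        assert f1["prs_mean_affected"] == pytest.approx(1.7275)
        assert f1["weighted_mean_unaffected"] == pytest.approx(-0.18)
        assert f1["prs_mean_unaffected"] == pytest.approx(-1.275)
        assert bool(f1["trend_positive"])

    def test_published_listing_trend_count(self):
        """Three of six comparable families show the affected > unaffected
        trend on both scores (strict mean rule)."""
        summary, count, _ = within_family_trend(load_family_scores())
        positives = set(summary[summary.trend_positive]["family_id"])
        assert count == 3
        assert positives == {"FMS01", "FMS03", "FMS07"}

    def test_tie_is_negative(self):
        df = pd.DataFrame({
            "family_id": ["F"] * 2,
            "status": ["affected", "unaffected"],
            "weighted_sum_score": [1.0, 1.0],
            "prs": [2.0, 1.0],
        })
        _, count, _ = within_family_trend(df)
        assert count == 0

    def test_not_comparable_family_reported(self):
        df = pd.DataFrame({
            "family_id": ["F8"] * 2,
            "status": ["affected", "affected"],
            "weighted_sum_score": [1.0, 2.0],
            "prs": [1.0, 2.0],
        })
        summary, count, not_comp = within_family_trend(df)
        assert not_comp == ["F8"]
        assert summary.empty

    def test_affine_invariance(self):
        df = load_family_scores()
        s1, c1, _ = within_family_trend(df)
        df2 = df.copy()
        df2["weighted_sum_score"] = 3.0 * df2["weighted_sum_score"] + 7.0
        df2["prs"] = 0.5 * df2["prs"] - 1.0
        s2, c2, _ = within_family_trend(df2)
        assert c1 == c2
        assert list(s1["trend_positive"]) == list(s2["trend_positive"])


class TestFreqCorrelation:
    def test_identical(self):
        r, r2 = freq_correlation([0.1, 0.4, 0.8], [0.1, 0.4, 0.8])
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_negation_about_mean(self):
        a = np.array([0.1, 0.4, 0.8, 0.3])
        b = 2 * a.mean() - a
        r, _ = freq_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            freq_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
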