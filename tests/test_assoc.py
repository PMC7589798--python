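"""Association models: closed forms, hand computations and enumeration oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srna_transgen.assoc import (
    class_anova,
    deg_overlap_rate,
    direction_by_class_expression_model,
    direction_chisq,
    dmr_overlap_logistic,
    lfc_correlation,
    lfc_vs_direction_glm,
    nearest_dmr,
    offspring_lfc_model,
    one_sample_t,
    one_sample_t_values,
    outlier_enrichment,
    overlap_group,
    table2_model,
)
from srna_transgen.io_formats import DMRRecord, GenomicInterval


class TestLFCCorrelation:
    def test_identical_vectors_have_r_one(self, rng):
        x = rng.normal(size=50)
        res = lfc_correlation(x, x)
        assert res.estimates["r"][0] == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_t_at_published_scale(self):
        """r = 0.23 at n = 315 gives t = 4.18 from the closed form (the
        unrounded-data value is slightly larger)."""
        r, n = 0.23, 315
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        assert t == pytest.approx(4.18, abs=0.01)

    def test_matches_scipy_pearson_on_random_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = lfc_correlation(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert res.estimates["r"][0] == pytest.approx(r_ref)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            lfc_correlation([1, 2], [3, 4])


class TestOneSampleT:
    def test_zero_mean_gives_zero_t(self):
        assert one_sample_t(0.0, 1.0, 30).statistic == 0.0

    def test_summary_example(self):
        """mean -0.32, sd 0.41, n 315 -> t = -13.85 from the rounded summary."""
        res = one_sample_t(-0.32, 0.41, 315)
        assert res.statistic == pytest.approx(-13.852, abs=0.01)
        assert res.p < 1e-4

    def test_unit_example(self):
        assert one_sample_t(1.0, 1.0, 100).statistic == pytest.approx(10.0)

    def test_raw_vector_variant_matches_scipy(self, rng):
        x = rng.normal(0.3, 1.0, 80)
        res = one_sample_t_values(x)
        t_ref, p_ref = stats.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)


class TestOffspringModel:
    def test_coefficient_recovery(self, rng):
        n = 315
        x2 = rng.normal(0, 0.8, n)
        x3 = rng.normal(0, 0.8, n)
        y = -0.5 * x2 + 0.3 * x3 + rng.normal(0, 0.1, n)
        res = offspring_lfc_model(x2, x3, y)
        assert res.estimates["lfc_2nd"][0] == pytest.approx(-0.5, abs=0.05)
        assert res.estimates["lfc_3rd"][0] == pytest.approx(0.3, abs=0.05)
        assert res.estimates["p_lfc_2nd"][0] < 1e-4

    def test_null_predictors_rarely_significant(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            x2, x3, y = rng.normal(size=(3, 40))
            res = offspring_lfc_model(x2, x3, y)
            hits += res.estimates["p_lfc_2nd"][0] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)

    def test_collinear_predictors_raise(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear|rank"):
            offspring_lfc_model(x, 2 * x, x)


class TestDirectionChisq:
    def test_balanced_table_is_null(self):
        groups = ["none"] * 100 + ["siRNA"] * 100 + ["ndsRNA"] * 100
        dirs = (["up"] * 50 + ["down"] * 50) * 3
        res = direction_chisq(groups, dirs)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        """Chi-square equals the hand-computed sum of (O-E)^2/E."""
        table = np.array([[488, 512], [418, 582], [659, 341]], dtype=float)
        groups = (
            ["none"] * 1000 + ["ndsRNA"] * 1000 + ["siRNA"] * 1000
        )
        dirs = (
            ["up"] * 488 + ["down"] * 512
            + ["up"] * 418 + ["down"] * 582
            + ["up"] * 659 + ["down"] * 341
        )
        res = direction_chisq(groups, dirs)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = float(((table - expected) ** 2 / expected).sum())
        assert res.statistic == pytest.approx(hand)
        assert res.estimates["up_prop_siRNA"][0] == pytest.approx(0.659)

    def test_two_by_two_closed_form_identity(self, rng):
        """On a 2x2 the statistic is (ad-bc)^2 N / (row and column products)."""
        a, b, c, d = rng.integers(10, 100, 4)
        groups = ["none"] * (a + b) + ["siRNA"] * (c + d)
        dirs = ["up"] * a + ["down"] * b + ["up"] * c + ["down"] * d
        res = direction_chisq(groups, dirs)
        N = a + b + c + d
        closed = (a * d - b * c) ** 2 * N / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(closed)

    def test_p_matches_permutation_null(self, rng):
        """Chi-square p agrees with a 10,000-draw permutation null."""
        groups = np.array(["none"] * 40 + ["siRNA"] * 30 + ["ndsRNA"] * 30)
        dirs = np.array(["up"] * 55 + ["down"] * 45)
        rng.shuffle(dirs)
        res = direction_chisq(groups, dirs)
        stat_obs = res.statistic

        def chi2_by_hand(up_flags):
            obs = np.array(
                [
                    [up_flags[groups == g].sum(), (~up_flags[groups == g]).sum()]
                    for g in ("none", "siRNA", "ndsRNA")
                ],
                dtype=float,
            )
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            return float(((obs - exp) ** 2 / exp).sum())

        up = dirs == "up"
        exceed = 0
        draws = 10_000
        for _ in range(draws):
            exceed += chi2_by_hand(rng.permutation(up)) >= stat_obs - 1e-12
        p_perm = exceed / draws
        assert res.p == pytest.approx(p_perm, abs=3 * math.sqrt(0.25 / draws) + 0.02)


class TestDMRModels:
    def test_logistic_recovers_planted_class_log_odds(self, rng):
        n = 5000
        length = rng.lognormal(6.0, 0.5, n)
        dclass = rng.choice(["O", "N", "F"], n)
        srna = rng.choice(["dicer", "ndsRNA"], n)
        logit = -2.0 + 0.3 * (np.log(length) - 6.0) + 1.2 * (srna == "dicer")
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame(
            {"overlaps_dmr": y.astype(int), "length": length,
             "distance_class": dclass, "srna_class": srna}
        )
        out = dmr_overlap_logistic(df)
        coef = out["srna_class"].estimates["srna_class_0"][0]
        assert coef == pytest.approx(1.2, abs=0.2)
        assert out["srna_class"].p < 1e-6
        assert out["log_length"].p < 1e-3

    def test_constant_response_is_flagged_not_raised(self):
        df = pd.DataFrame(
            {"overlaps_dmr": [1] * 20, "length": [100.0] * 20,
             "distance_class": ["N"] * 20, "srna_class": ["dicer"] * 20}
        )
        out = dmr_overlap_logistic(df)
        assert "degenerate" in out["full"].note
        assert math.isnan(out["full"].p)

    def test_lfc_vs_direction_recovers_shift(self, rng):
        n = 600
        direction = rng.choice(["up", "down"], n)
        lfc = 0.4 * (direction == "up") + rng.normal(0, 0.5, n)
        res = lfc_vs_direction_glm(lfc, direction)
        assert res.estimates["direction_up"][0] == pytest.approx(0.4, abs=0.1)
        assert res.p < 1e-6

    def test_lfc_vs_direction_single_direction_flagged(self):
        res = lfc_vs_direction_glm([0.1, 0.2, 0.3], ["up", "up", "up"])
        assert "degenerate" in res.note

    def test_nearest_dmr_window_exclusion_matches_brute_force(self, rng):
        dmrs = [
            DMRRecord(GenomicInterval("c1", int(s), int(s) + 200), "up")
            for s in rng.integers(0, 500_000, 40)
        ]
        loci = [
            GenomicInterval("c1", int(s), int(s) + 300)
            for s in rng.integers(0, 500_000, 200)
        ]
        near = nearest_dmr(loci, dmrs)
        within = (near["distance"] <= 20_000).sum()
        brute = sum(
            1
            for iv in loci
            if min(iv.distance(d.interval) for d in dmrs) <= 20_000
        )
        assert within == brute


class TestDEGModels:
    def test_rate_recovery_and_odds_ratio(self, rng):
        n = 10_000
        ov = rng.random(n) < 0.3
        de = np.where(ov, rng.random(n) < 0.132, rng.random(n) < 0.084)
        res = deg_overlap_rate(de, ov)
        assert res.estimates["rate_overlap"][0] == pytest.approx(0.132, abs=0.01)
        assert res.estimates["rate_background"][0] == pytest.approx(0.084, abs=0.01)
        a = np.sum(de & ov); b = np.sum(~de & ov); c = np.sum(de & ~ov); d = np.sum(~de & ~ov)
        assert res.estimates["odds_ratio"][0] == pytest.approx(a * d / (b * c))

    def test_direction_model_recovers_expression_slope(self, rng):
        n = 2000
        logx = rng.normal(0, 1, n)
        cls = rng.choice(["none", "siRNA", "ndsRNA"], n)
        z = -1.0 * logx
        d = np.where(rng.random(n) < 1 / (1 + np.exp(-z)), "up", "down")
        out = direction_by_class_expression_model(d, logx, cls)
        slope = out["log_expression"].estimates["log_expression_0"][0]
        assert slope == pytest.approx(-1.0, abs=0.15)
        assert out["log_expression"].p < 1e-10

    def test_single_class_drops_term_with_warning(self, rng):
        n = 200
        logx = rng.normal(0, 1, n)
        d = rng.choice(["up", "down"], n)
        with pytest.warns(UserWarning, match="class term dropped"):
            out = direction_by_class_expression_model(d, logx, ["none"] * n)
        assert "overlap_class" not in out


class TestTable2Model:
    def _data(self, rng, n=2000, interaction=True):
        mrna = rng.choice(["up", "none", "down"], n)
        stype = rng.choice(["siRNA", "ndsRNA"], n)
        shift = np.zeros(n)
        if interaction:
            shift += 0.4 * ((stype == "ndsRNA") & (mrna == "down"))
            shift -= 0.4 * ((stype == "ndsRNA") & (mrna == "up"))
        return pd.DataFrame(
            {"lfc": shift + rng.normal(0, 0.5, n), "mrna_change": mrna, "srna_type": stype}
        )

    def test_term_degrees_of_freedom(self, rng):
        out = table2_model(self._data(rng, n=600, interaction=False))
        assert out["mrna_tgen_change"].df[0] == 2
        assert out["srna_type"].df[0] == 1
        assert out["interaction"].df[0] == 2

    def test_interaction_detected_when_planted(self, rng):
        out = table2_model(self._data(rng, n=4000, interaction=True))
        assert out["interaction"].p < 1e-6

    def test_type2_matches_statsmodels_direct(self, rng):
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        df = self._data(rng, n=500)
        out = table2_model(df)
        fit = ols("lfc ~ C(mrna_change) * C(srna_type)", data=df).fit()
        ref = anova_lm(fit, typ=2)
        assert out["srna_type"].statistic == pytest.approx(ref.loc["C(srna_type)", "F"])


class TestOutlierEnrichment:
    def test_perfect_tail_concentration_is_minimal_p(self, rng):
        lfc = np.concatenate([rng.normal(0, 1, 95), rng.normal(10, 0.1, 5)])
        member = lfc > 5
        res = outlier_enrichment(lfc, member, tail_q=0.05)
        # all 5 members in a tail of 5 из 100: the exact choose-based minimum
        n_tail, K, N = 5, 5, 100
        p_min = 1.0 / math.comb(N, n_tail) * math.comb(N - K, n_tail - n_tail)
        assert res.p == pytest.approx(
            math.comb(K, 5) * math.comb(N - K, 0) / math.comb(N, 5), rel=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Hypergeometric p equals the closed choose-based enumeration, n <= 30."""
        r = np.random.default_rng(seed)
        N = int(r.integers(10, 31))
        lfc = r.normal(size=N)
        member = r.random(N) < 0.4
        res = outlier_enrichment(lfc, member, tail_q=0.2)
        n_tail = max(1, math.ceil(0.2 * N))
        K = int(member.sum())
        k_obs = int(res.estimates["members_in_tail"][0])
        enum = sum(
            math.comb(K, j) * math.comb(N - K, n_tail - j)
            for j in range(k_obs, min(K, n_tail) + 1)
            if n_tail - j <= N - K
        ) / math.comb(N, n_tail)
        assert res.p == pytest.approx(enum, rel=1e-9)

    def test_random_membership_p_uniform(self, rng):
        ps = []
        for _ in range(1000):
            lfc = rng.normal(size=100)
            member = rng.random(100) < 0.3
            ps.append(outlier_enrichment(lfc, member, tail_q=0.1).p)
        # discrete p-values are super-uniform; check no excess of small ones
        assert np.mean(np.array(ps) < 0.05) <= 0.07

    def test_lower_tail_side(self, rng):
        lfc = np.concatenate([rng.normal(0, 1, 90), np.full(10, -15.0)])
        member = lfc < -5
        res = outlier_enrichment(lfc, member, tail_q=0.1, side="lower")
        assert res.p < 1e-10


class TestClassAnova:
    def test_hand_formula_on_three_group_toy(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        values = sum(groups.values(), [])
        labels = sum(([k] * 3 for k in groups), [])
        res = class_anova(values, labels)
        grand = np.mean(values)
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values())
        f_hand = (ssb / 2) / (ssw / 6)
        assert res.statistic == pytest.approx(f_hand)
        assert res.df == (2, 6)

    def test_shifted_group_is_significant(self, rng):
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        labels = ["a"] * 50 + ["b"] * 50
        assert class_anova(values, labels).p < 0.001

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            class_anova([1.0, 2.0], ["a", "a"])


class TestOverlapGroup:
    def test_nearest_class_wins_within_window(self):
        loci = [
            (GenomicInterval("c1", 1000, 1200), "siRNA"),
            (GenomicInterval("c1", 3000, 3200), "ndsRNA"),
        ]
        gene = GenomicInterval("c1", 1500, 1600)
        assert overlap_group(gene, loci, window=5000) == "siRNA"
        far_gene = GenomicInterval("c1", 50_000, 50_100)
        assert overlap_group(far_gene, loci, window=5000) == "none"
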