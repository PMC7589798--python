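"""Normalization, filtering, BH adjustment and the NB likelihood-ratio test.

The in-package IRLS NB GLM is checked against statsmodels' independent
negative-binomial GLM implementation; BH against statsmodels' multitest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from srna_transgen.io_formats import SampleMeta, ValidationError
from srna_transgen.diffabund import (
    CONTRASTS,
    CountMatrix,
    bh_adjust,
    design_matrices,
    estimate_dispersions,
    filter_rpm,
    nb_glm_fit,
    nb_loglik,
    nb_lrt,
    run_contrast,
    select_samples,
    size_factors,
)


def _parent_samples(n_per_group=3):
    out = []
    for i in range(n_per_group):
        out.append(SampleMeta(f"c{i}", "parent", "control", "72h", "second"))
    for i in range(n_per_group):
        out.append(SampleMeta(f"w{i}", "parent", "wounded", "72h", "second"))
    return out


class TestSizeFactors:
    def test_identical_columns_are_symmetric(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = size_factors(df)
        assert sf[0] == pytest.approx(sf[1])

    def test_doubled_column_has_double_factor(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(df)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self, rng):
        """Oracle: a from-scratch median-of-ratios reimplementation."""
        counts = rng.negative_binomial(5, 0.1, size=(300, 6)).astype(float)
        counts[0] = 0  # ensure the all-positive filter matters
        df = pd.DataFrame(counts, columns=list("abcdef"))
        sf = size_factors(df)

        mask = (counts > 0).all(axis=1)
        geo = np.exp(np.log(counts[mask]).mean(axis=1))
        expected = [np.median(counts[mask, j] / geo) for j in range(6)]
        assert sf == pytest.approx(expected, rel=0.05)

    def test_fallback_to_library_size(self):
        df = pd.DataFrame({"a": [0, 4], "b": [2, 0]})
        sf = size_factors(df)
        assert sf == pytest.approx([4 / 3, 2 / 3])


class TestFilterRPM:
    def _matrix(self, counts, libs):
        samples = [
            SampleMeta(f"s{i}", "parent", "control", "1h", "second", library_size=l)
            for i, l in enumerate(libs)
        ]
        df = pd.DataFrame(
            counts, columns=[s.sample_id for s in samples],
            index=[f"l{i}" for i in range(len(counts))],
        )
        return CountMatrix(counts=df, samples=samples)

    def test_boundary_mean_rpm_two_is_kept(self):
        # rpm per sample: 3, 3, 1, 1 -> mean exactly 2
        m = self._matrix([[3, 3, 1, 1]], [1_000_000] * 4)
        assert len(filter_rpm(m, 2.0).counts) == 1

    def test_all_zero_locus_dropped_and_recount(self, rng):
        counts = rng.poisson(3.0, size=(50, 4))
        counts[7] = 0
        m = self._matrix(counts.tolist(), [1_000_000] * 4)
        kept = filter_rpm(m, 2.0)
        brute = [
            i
            for i in range(50)
            if np.mean(counts[i] / 1e6 * 1e6) >= 2.0
        ]
        assert list(kept.counts.index) == [f"l{i}" for i in brute]
        assert "l7" not in kept.counts.index


class TestBH:
    def test_closed_form_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_itself(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 60)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(expected)

    def test_monotone_in_p_rank_and_nan_passthrough(self, rng):
        p = rng.random(100)
        p[3] = np.nan
        q = bh_adjust(p)
        assert np.isnan(q[3])
        ok = ~np.isnan(p)
        order = np.argsort(p[ok])
        assert np.all(np.diff(q[ok][order]) >= -1e-12)
        assert np.all(q[ok] >= p[ok] - 1e-12)


class TestNBGLM:
    def test_loglik_matches_scipy(self, rng):
        from scipy import stats

        y = rng.poisson(10.0, 20).astype(float)
        mu = np.full(20, 9.0)
        alpha = 0.2
        r = 1 / alpha
        expected = stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert nb_loglik(y, mu, alpha) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [0.05, 0.1, 0.5])
    def test_fit_matches_statsmodels_oracle(self, rng, alpha):
        """IRLS betas and log-likelihood agree with statsmodels NB GLM."""
        n = 40
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        offset = np.log(rng.uniform(0.5, 2.0, n))
        mu = np.exp(X @ np.array([2.0, 1.0]) + offset)
        y = rng.poisson(rng.gamma(1 / alpha, mu * alpha)).astype(float)
        fit = nb_glm_fit(y, X, offset, alpha)
        sm_fit = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
        assert fit.beta == pytest.approx(sm_fit.params, abs=1e-5)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)


class TestNBLRT:
    def test_identical_counts_give_null_result(self):
        samples = _parent_samples()
        y = np.array([7, 7, 7, 7, 7, 7])
        res = nb_lrt(y, samples, np.ones(6), 0.1)
        assert res.lfc == pytest.approx(0.0, abs=1e-6)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_requires_two_samples_per_level(self):
        samples = _parent_samples()[0:3] + [_parent_samples()[3]]
        with pytest.raises(ValidationError):
            nb_lrt(np.array([1, 2, 3, 4]), samples, np.ones(4), 0.1)

    def test_stat_nonnegative_p_in_unit_interval(self, rng):
        samples = _parent_samples()
        for _ in range(200):
            y = rng.poisson(rng.uniform(1, 100), 6)
            res = nb_lrt(y, samples, np.ones(6), float(rng.uniform(0.01, 1.0)))
            assert 0.0 < res.p <= 1.0

    def test_all_zero_locus_is_null(self):
        res = nb_lrt(np.zeros(6), _parent_samples(), np.ones(6), 0.1)
        assert res.p == 1.0 and res.lfc == 0.0

    def test_strong_effect_detected_with_accurate_lfc(self, rng):
        samples = _parent_samples()
        y = np.array([20, 25, 22, 80, 95, 88])
        res = nb_lrt(y, samples, np.ones(6), 0.05)
        assert res.p < 0.01
        assert res.lfc == pytest.approx(np.log2(87.666 / 22.333), abs=0.05)

    def test_lrt_statistic_matches_statsmodels_loglik_difference(self, rng):
        """Dual route: our LRT equals 2*(llf-llr) from statsmodels fits."""
        from scipy import stats as sps

        samples = _parent_samples()
        X_full, X_red = design_matrices(samples)
        sf = np.ones(6)
        for _ in range(20):
            y = rng.poisson(rng.uniform(2, 200), 6).astype(float)
            if y.sum() == 0:
                continue
            alpha = 0.1
            res = nb_lrt(y, samples, sf, alpha)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            llf = sm.GLM(y, X_full, family=fam).fit().llf
            llr = sm.GLM(y, X_red, family=fam).fit().llf
            stat = max(0.0, 2 * (llf - llr))
            assert res.p == pytest.approx(float(sps.chi2.sf(stat, 1)), abs=1e-4)


class TestNestedDesign:
    def _offspring_samples(self):
        out = []
        for treatment in ("control", "wounded"):
            for line in range(1, 5):
                for sib in range(2):
                    out.append(
                        SampleMeta(
                            f"o_{treatment[0]}{line}_{sib}",
                            "offspring",
                            treatment,
                            None,
                            "second",
                            maternal_line=f"{treatment[0].upper()}{line}",
                        )
                    )
        return out

    def test_design_shapes_and_df(self):
        samples = self._offspring_samples()
        X_full, X_red = design_matrices(samples, nested_maternal=True)
        # intercept + treatment + 3 shared line-index blocks; LRT df = 1
        assert X_full.shape == (16, 5)
        assert X_red.shape == (16, 4)
        assert np.linalg.matrix_rank(X_full) == 5
        assert np.linalg.matrix_rank(X_red) == 4

    def test_planted_effect_recovered_with_line_effects(self, rng):
        """The nested model recovers the treatment LFC under sibling structure."""
        samples = self._offspring_samples()
        lfc = 1.5
        lfcs = []
        for _ in range(100):
            line_shift = {f"{t}{l}": rng.normal(0, 0.2) for t in "CW" for l in range(1, 5)}
            mu = np.array(
                [
                    40
                    * np.exp(line_shift[s.maternal_line])
                    * (2**lfc if s.treatment == "wounded" else 1.0)
                    for s in samples
                ]
            )
            y = rng.poisson(mu)
            res = nb_lrt(y, samples, np.ones(16), 0.05, nested_maternal=True)
            lfcs.append(res.lfc)
        assert np.mean(lfcs) == pytest.approx(1.5, abs=0.15)


class TestRunContrast:
    def test_contrast_sample_selection_matches_metadata(self, tiny_bundle):
        samples = tiny_bundle.counts.samples
        sel = select_samples(samples, CONTRASTS["parent_72h_leaf2"])
        assert sorted(sel) == sorted(
            s.sample_id
            for s in samples
            if s.generation == "parent" and s.timepoint == "72h" and s.leaf_pair == "second"
        )
        assert len(sel) == 6
        assert len(select_samples(samples, CONTRASTS["offspring_leaf2"])) == 16

    def test_run_contrast_output_contract(self, tiny_bundle):
        strata = {
            lid: "ndsRNA" for lid in tiny_bundle.counts.locus_ids
        }
        df = run_contrast(tiny_bundle.counts, strata, "parent_72h_leaf2")
        assert set(df.columns) >= {"locus_id", "stratum", "baseMean", "lfc", "p", "q"}
        ok = df["p"].notna()
        assert ((df.loc[ok, "q"] >= df.loc[ok, "p"] - 1e-12)).all()
        # q monotone in p within the (single) stratum
        sub = df.loc[ok].sort_values("p")
        assert np.all(np.diff(sub["q"]) >= -1e-12)
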