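"""Group inference: summary-statistic tests against raw-data oracles,
voxel-wise ANCOVA against a generic linear-model fit, permutation
cluster-extent control, and post-hoc contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nvcoupling.images import GROUPS
from nvcoupling.inference import (
    bonferroni_threshold,
    build_design,
    chi_square_independence,
    cluster_fwe,
    fisher_exact_rxc,
    oneway_anova_from_summary,
    pearson_with_p,
    posthoc_pairwise,
    two_sample_t_from_summary,
    voxelwise_ancova,
)


def data_with_summary(n, mean, sd, rng):
    """Raw vector with exactly the requested mean and sd."""
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def _cohort(n_per_group, rng, groups=GROUPS):
    rows = []
    i = 0
    for g in groups:
        for _ in range(n_per_group):
            rows.append(
                {
                    "subject": f"s{i:03d}",
                    "group": g,
                    "age": float(rng.uniform(10, 55)),
                    "gender": "M" if rng.random() < 0.7 else "F",
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestSummaryStatistics:
    def test_anova_matches_raw_data_oracle(self, rng):
        specs = [(20, 21.55, 11.28), (29, 27.76, 12.04), (37, 24.96, 10.16)]
        raw = [data_with_summary(n, m, s, rng) for n, m, s in specs]
        F, df1, df2, p = oneway_anova_from_summary(specs)
        F_raw, p_raw = stats.f_oneway(*raw)
        assert F == pytest.approx(F_raw, rel=1e-10)
        assert p == pytest.approx(p_raw, rel=1e-8)

    def test_anova_equal_means_zero(self):
        assert oneway_anova_from_summary([(5, 1.0, 2.0), (7, 1.0, 3.0)])[0] == 0.0

    def test_t_matches_raw_data_oracle(self, rng):
        a, b = (20, 4.72, 4.01), (29, 121.79, 129.04)
        t, df, p = two_sample_t_from_summary(a, b)
        t_raw, p_raw = stats.ttest_ind(
            data_with_summary(*a, rng), data_with_summary(*b, rng)
        )
        assert t == pytest.approx(t_raw, rel=1e-10)
        assert p == pytest.approx(p_raw, rel=1e-8)
        assert df == 47

    def test_t_equal_means_zero(self):
        assert two_sample_t_from_summary((5, 2.0, 1.0), (8, 2.0, 3.0))[0] == 0.0

    @pytest.mark.parametrize(
        "table",
        [
            [[18, 2], [18, 11], [27, 10]],
            [[5, 10], [8, 3]],
            [[10, 20, 30], [15, 12, 9]],
        ],
    )
    def test_chi2_matches_scipy(self, table):
        chi2, df, p = chi_square_independence(table)
        s_chi2, s_p, s_df, _ = stats.chi2_contingency(np.asarray(table), correction=False)
        assert chi2 == pytest.approx(s_chi2, rel=1e-12)
        assert df == s_df
        assert p == pytest.approx(s_p, rel=1e-10)

    def test_chi2_proportional_table_zero(self):
        assert chi_square_independence([[10, 20], [5, 10]])[0] == pytest.approx(0.0)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])


class TestFisherExact:
    @pytest.mark.parametrize("table", [[[3, 7], [5, 2]], [[8, 2], [1, 5]], [[4, 4], [4, 4]]])
    def test_2x2_matches_hypergeometric(self, table):
        _, p_scipy = stats.fisher_exact(table)
        assert fisher_exact_rxc(table) == pytest.approx(p_scipy, rel=1e-9)

    def test_single_column_degenerate(self):
        assert fisher_exact_rxc([[4], [7]]) == pytest.approx(1.0)

    def test_independent_2x3_near_one(self):
        # exactly proportional rows: observed table is the most likely
        assert fisher_exact_rxc([[10, 20, 30], [5, 10, 15]]) > 0.9


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.standard_normal(10)
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        r, p = pearson_with_p(x, y)
        s = stats.pearsonr(x, y)
        assert r == pytest.approx(s.statistic, rel=1e-12)
        assert p == pytest.approx(s.pvalue, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestVoxelwiseAncova:
    def test_matches_statsmodels_nested_f(self, rng):
        import statsmodels.api as sm

        cohort = _cohort(8, rng)
        design = build_design(cohort)
        stack = rng.standard_normal((design.n, 10))
        F, p, _ = voxelwise_ancova(stack, design)
        for v in range(10):
            full = sm.OLS(stack[:, v], design.X_full).fit()
            red = sm.OLS(stack[:, v], design.X_reduced).fit()
            f_sm = (
                (red.ssr - full.ssr) / design.df_effect
            ) / (full.ssr / design.df_resid)
            assert F[v] == pytest.approx(f_sm, rel=1e-9)

    def test_null_p_values_uniform(self, rng):
        """Kolmogorov-Smirnov calibration on 2000 independent null voxels."""
        cohort = _cohort(10, rng)
        design = build_design(cohort)
        stack = rng.standard_normal((design.n, 2000))
        _, p, _ = voxelwise_ancova(stack, design)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_zero_variance_voxel_excluded(self, rng):
        cohort = _cohort(5, rng)
        design = build_design(cohort)
        stack = rng.standard_normal((design.n, 4))
        stack[:, 2] = 3.0
        F, p, excluded = voxelwise_ancova(stack, design)
        assert excluded[2] and F[2] == 0.0 and p[2] == 1.0


class TestClusterFwe:
    def test_single_supra_threshold_voxel(self, rng):
        cohort = _cohort(8, rng)
        design = build_design(cohort)
        mask = np.ones((6, 6, 6), bool)
        stack = rng.standard_normal((design.n, mask.sum()))
        # plant one massive single-voxel group effect
        stack[:, 100] = design.group_index * 50.0 + rng.normal(0, 0.1, design.n)
        res = cluster_fwe(stack, design, mask, n_perm=100, seed=0)
        assert any(c.n_voxels == 1 for c in res.clusters)
        top = max(res.clusters, key=lambda c: c.peak_f)
        assert np.unravel_index(100, (6, 6, 6)) == top.peak_ijk

    def test_no_supra_threshold_returns_empty(self, rng):
        cohort = _cohort(5, rng)
        design = build_design(cohort)
        mask = np.ones((4, 4, 4), bool)
        stack = rng.standard_normal((design.n, mask.sum())) * 0.01
        res = cluster_fwe(stack, design, mask, cluster_forming_p=1e-6, n_perm=100, seed=0)
        assert res.clusters == []
        assert res.significant == []

    def test_planted_effect_recovered_with_dice_overlap(self):
        """A strong regional CBF deficit yields a significant cluster
        overlapping the planted region (Dice > 0.5) in every replicate."""
        from nvcoupling.perfusion import prepare_cbf
        from nvcoupling.synthetic import CohortSpec, generate_cbf, make_masks

        hits = 0
        n_rep = 5
        for seed in range(n_rep):
            effect = {
                "cortex": {g: 1.0 for g in GROUPS},
                "calcarine": {"A-LHON": 0.7, "C-LHON": 0.7, "HC": 1.0},
                "temporal": {g: 1.0 for g in GROUPS},
            }
            spec = CohortSpec(
                n_per_group={g: 12 for g in GROUPS},
                cbf_effect_by_region=effect,
                seed=100 + seed,
            )
            brain, _, _, labels = make_masks(spec)
            maps = [prepare_cbf(generate_cbf(spec, i), brain) for i in range(spec.n_subjects)]
            from nvcoupling.synthetic import generate_cohort_table

            table, _ = generate_cohort_table(spec)
            design = build_design(table)
            stack = np.stack([m.values[brain] for m in maps])
            res = cluster_fwe(stack, design, brain, n_perm=300, seed=seed)
            region = labels == 2
            got = False
            for c in res.significant:
                cl = res.label_volume == c.label
                dice = 2 * (cl & region).sum() / (cl.sum() + region.sum())
                got = got or dice > 0.5
            hits += got
        assert hits == n_rep


class TestPosthoc:
    def _roi_table(self, cohort, rng, effect=0.0):
        rows = []
        for _, r in cohort.iterrows():
            bump = effect if r["group"] == "A-LHON" else 0.0
            for roi in ("r1", "r2"):
                rows.append(
                    {
                        "subject": r["subject"],
                        "roi": roi,
                        "ratio": rng.normal(1.0 + bump, 0.1),
                        "reho": rng.normal(1.0, 0.1),
                        "cbf": rng.normal(1.0, 0.1),
                    }
                )
        return pd.DataFrame(rows)

    def test_contrast_t_squared_equals_wald_f(self, rng):
        import statsmodels.api as sm

        cohort = _cohort(8, rng)
        roi = self._roi_table(cohort, rng, effect=0.3)
        out = posthoc_pairwise(roi, cohort)
        sub = roi[roi["roi"] == "r1"].merge(cohort, on="subject")
        design = build_design(sub)
        fit = sm.OLS(sub["ratio"].to_numpy(), design.X_full).fit()
        c = np.zeros(5)
        c[0], c[2] = 1.0, -1.0  # A-LHON vs HC
        wald = float(fit.f_test(c).fvalue)
        row = out[
            (out["roi"] == "r1") & (out["measure"] == "ratio")
            & (out["group1"] == "A-LHON") & (out["group2"] == "HC")
        ].iloc[0]
        assert row["t"] ** 2 == pytest.approx(wald, rel=1e-9)

    def test_null_false_positive_rate_matches_alpha(self, rng):
        """With identical groups, Bonferroni flags are almost never set."""
        flags = 0
        total = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            cohort = _cohort(8, r)
            out = posthoc_pairwise(self._roi_table(cohort, r), cohort)
            flags += int(out["significant"].sum())
            total += len(out)
        # expected false flags: total * 0.05/18 ~ 0.5; allow a wide margin
        assert flags <= 3

    def test_detects_planted_group_shift(self, rng):
        cohort = _cohort(15, rng)
        out = posthoc_pairwise(self._roi_table(cohort, rng, effect=0.5), cohort)
        hit = out[
            (out["measure"] == "ratio") & (out["group1"] == "A-LHON")
            & (out["group2"] == "HC")
        ]
        assert hit["significant"].all()


class TestBonferroni:
    def test_family_thresholds(self):
        assert bonferroni_threshold(3, 3, 3) == pytest.approx(0.05 / 27)
        assert bonferroni_threshold(3, 5, 2) == pytest.approx(0.05 / 30)
        assert bonferroni_threshold(3, 2, 2) == pytest.approx(0.05 / 12)
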