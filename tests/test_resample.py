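import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import cohortnet as cn
from cohortnet.resample import EdgeResamples, _wave_matrix


class TestSubsampleSize:
    @pytest.mark.parametrize("n,frac,expected", [(43, 0.8, 34), (10, 0.8, 8), (5, 1.0, 5)])
    def test_floor_arithmetic(self, n, frac, expected):
        assert cn.subsample_size(n, frac) == expected

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="subsample too small"):
            cn.subsample_size(2, 0.5)


class TestMannWhitneyU:
    def test_fully_separated_small_samples(self):
        u, p = cn.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 arrangements

    def test_identical_multisets(self, rng):
        x = rng.standard_normal(8)
        u, _ = cn.mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_single_observations(self):
        u, p = cn.mann_whitney_u([5], [1])
        assert u == 1 and p == pytest.approx(1.0)

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.standard_normal(6)
            y = rng.standard_normal(7)
            u, p = cn.mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            # scipy's U counts x>y pairs identically for untied data
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_near_exact_at_boundary(self, rng):
        """Just past the enumeration cutoff (combined n = 21) the corrected
        normal approximation agrees with exact enumeration within 0.01."""
        for _ in range(20):
            x = rng.standard_normal(10)
            y = rng.standard_normal(11)
            _, p_normal = cn.mann_whitney_u(x, y)  # normal path (n = 21)
            p_exact = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert abs(p_exact - p_normal) < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cn.mann_whitney_u([], [1.0])


class TestMoodsMedianTest:
    def test_fully_separated_hand_oracle(self):
        chi2, p = cn.moods_median_test([1, 2, 3], [4, 5, 6])
        assert chi2 == pytest.approx(6.0, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(6.0, 1), abs=1e-12)

    def test_matches_scipy_convention(self, rng):
        for _ in range(10):
            x = rng.standard_normal(30)
            y = rng.standard_normal(25) + 0.3
            chi2, p = cn.moods_median_test(x, y)
            ref_chi2, ref_p, *_ = stats.median_test(
                x, y, ties="below", correction=False
            )
            assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_degenerate_pooled_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate pooled data"):
            cn.moods_median_test([1, 1, 1], [1, 1, 1])

    def test_null_rejection_rate_matches_hypergeometric_level(self, rng):
        """For continuous iid samples the count above the pooled median is
        hypergeometric; the empirical rejection rate must match the exact
        level of the chi-square decision rule (slightly above 5% at n=100
        per group, since the uncorrected chi-square is mildly liberal)."""
        n = 100
        crit = stats.chi2.isf(0.05, 1)
        a = np.arange(0, n + 1)
        # chi2 = 4 d^2 / (n/2) with d = |a - n/2| when all margins equal n
        exact_level = stats.hypergeom.pmf(a, 2 * n, n, n)[
            (4 * (a - n / 2) ** 2) / (n / 2) > crit
        ].sum()
        n_rep = 400
        rejections = 0
        for _ in range(n_rep):
            _, p = cn.moods_median_test(
                rng.standard_normal(n), rng.standard_normal(n)
            )
            rejections += p < 0.05
        se = np.sqrt(exact_level * (1 - exact_level) / n_rep)
        assert abs(rejections / n_rep - exact_level) <= 3 * se


class TestBhFdr:
    def test_step_up_hand_oracle(self):
        np.testing.assert_allclose(
            cn.bh_fdr([0.01, 0.03, 0.04, 0.05]), [0.04, 0.05, 0.05, 0.05], atol=1e-12
        )

    def test_all_ones_capped(self):
        np.testing.assert_array_equal(cn.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_identity(self):
        assert cn.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_matches_statsmodels(self, rng):
        for _ in range(5):
            p = rng.uniform(0, 1, 20)
            _, expected, *_ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(cn.bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cn.bh_fdr([0.5, 1.2])


class TestResampleUln:
    def test_shapes_and_determinism(self, cohort, registry, fa_partition):
        res1 = cn.resample_uln(cohort, registry, fa_partition, iterations=20, seed=5, beta=6)
        res2 = cn.resample_uln(cohort, registry, fa_partition, iterations=20, seed=5, beta=6)
        n_edges = 10 * 9 // 2
        assert res1.samples_noncarrier.shape == (20, n_edges)
        assert res1.samples_carrier.shape == (20, n_edges)
        assert res1.m == 34
        np.testing.assert_array_equal(res1.samples_noncarrier, res2.samples_noncarrier)
        np.testing.assert_array_equal(res1.samples_carrier, res2.samples_carrier)

    def test_full_group_subsample_is_constant(self, cohort, registry, fa_partition):
        """fraction=1 with equal groups exhausts each group: every iteration
        yields the identical W^ave vector."""
        nc = cohort.group_table(False).subset(np.arange(43))
        c = cohort.group_table(True)
        table = cn.CohortTable.concat([nc, c])
        res = cn.resample_uln(table, registry, fa_partition, iterations=2,
                              seed=1, fraction=1.0, beta=6)
        np.testing.assert_allclose(
            res.samples_noncarrier[0], res.samples_noncarrier[1], atol=1e-12
        )

    def test_fast_path_matches_reference_pipeline(self, cohort, registry, fa_partition):
        """The vectorized per-iteration path reproduces the explicit
        build_lln -> build_uln route."""
        g = cohort.group_table(True).subset(np.arange(34))
        lln = cn.build_lln(g, registry, beta=6)
        uln = cn.build_uln(lln, fa_partition)
        nodes = registry.network_nodes
        modules = fa_partition.modules
        memb = np.zeros((len(nodes), len(modules)))
        for i, node in enumerate(nodes):
            memb[i, modules.index(fa_partition.assignment[node])] = 1.0
        wave = _wave_matrix(
            g.data[nodes].to_numpy(float),
            g.data[["age", "sex"]].to_numpy(float),
            6, memb, memb.sum(axis=0), "pearson", "tom",
        )
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                assert wave[i, modules.index(b)] == pytest.approx(
                    uln.edge(a, b), abs=1e-14
                )

    def test_requires_partition(self, cohort, registry):
        with pytest.raises(ValueError, match="partition"):
            cn.resample_uln(cohort, registry, None)


def swap_groups(res: EdgeResamples) -> EdgeResamples:
    return EdgeResamples(
        modules=res.modules,
        edges=res.edges,
        samples_noncarrier=res.samples_carrier,
        samples_carrier=res.samples_noncarrier,
        iterations=res.iterations,
        m=res.m,
        beta=res.beta,
    )


@pytest.fixture(scope="module")
def resamples(cohort, registry, fa_partition):
    return cn.resample_uln(cohort, registry, fa_partition,
                           iterations=200, seed=7, beta=6)


class TestCompareEdges:
    def test_wm_family_has_nine_comparisons(self, resamples):
        assert len(cn.compare_edges(resamples, family="wm_edges")) == 9

    def test_all_edges_family(self, resamples):
        assert len(cn.compare_edges(resamples, family="all_edges")) == 45

    def test_exchangeability(self, resamples):
        """Swapping group labels negates median differences and leaves
        p-values unchanged."""
        fwd = cn.compare_edges(resamples)
        rev = cn.compare_edges(swap_groups(resamples))
        for f, r in zip(fwd, rev):
            assert f.median_nc == r.median_c and f.median_c == r.median_nc
            assert f.p_mood == pytest.approx(r.p_mood, abs=1e-12)
            assert f.p_u == pytest.approx(r.p_u, abs=1e-12)

    def test_planted_coupling_flagged(self, resamples):
        """The carrier-specific cytokine-WM coupling planted by the default
        generator surfaces as a flagged edge with a larger carrier median."""
        by_edge = {r.edge: r for r in cn.compare_edges(resamples)}
        cyt = by_edge[("Cytokines", "WM")]
        assert cyt.flagged
        assert cyt.median_c > cyt.median_nc

    def test_p_values_in_range(self, resamples):
        for r in cn.compare_edges(resamples, family="all_edges"):
            for p in (r.p_u, r.p_mood, r.p_fdr, r.p_u_fdr):
                assert 0 <= p <= 1

    def test_comparison_frame_columns(self, resamples):
        frame = cn.comparison_frame(cn.compare_edges(resamples))
        assert {"edge", "p_mood", "p_fdr", "flagged"} <= set(frame.columns)


class TestNullBehaviour:
    def test_identical_groups_mood_p_uniform(self, registry):
        """Copying one group into both labels makes the resampled W^ave
        distributions identical in law: Mood's test keeps its 5% level."""
        cfg = cn.SimulationConfig(n_noncarrier=43, n_carrier=43, n_missing=0, seed=3)
        base = cn.simulate_cohort(cfg, registry).group_table(False)
        copy = cn.CohortTable(
            base.data.assign(
                apoe4=1,
                participant_id=["c" + p for p in base.data["participant_id"]],
            ),
            registry,
        )
        table = cn.CohortTable.concat([base, copy])
        corr = cn.correlation_matrix(table, registry).abs()
        fa = registry.fatty_acids
        part = cn.build_partition(registry, cn.cluster_fatty_acids(corr.loc[fa, fa]))

        n_rep = 60
        rejections = 0
        for seed in range(n_rep):
            res = cn.resample_uln(table, registry, part, iterations=60,
                                  seed=100 + seed, beta=6)
            i = res.edges.index(("Cytokines", "WM"))
            _, p = cn.moods_median_test(
                res.samples_noncarrier[:, i], res.samples_carrier[:, i]
            )
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 3 * se

    def test_null_pair_edge_comparison_is_anticonservative(self, registry):
        """Documented caveat: with two *independent* cohorts drawn from the
        same distribution, many resampling iterations resolve the sampling
        difference between the observed cohorts, so the edge comparison flags
        far more than 5% of edges. This quantifies (not hides) the
        anti-conservativeness of the as-described procedure."""
        flagged_fracs = []
        for seed in range(3):
            nc, c = cn.simulate_null_pair(
                cn.SimulationConfig(seed=seed), registry
            )
            table = cn.CohortTable.concat([nc, c])
            corr = cn.correlation_matrix(table, registry).abs()
            fa = registry.fatty_acids
            part = cn.build_partition(
                registry, cn.cluster_fatty_acids(corr.loc[fa, fa])
            )
            res = cn.resample_uln(table, registry, part, iterations=500,
                                  seed=seed, beta=6)
            results = cn.compare_edges(res, family="wm_edges")
            flagged_fracs.append(np.mean([r.flagged for r in results]))
        assert np.mean(flagged_fracs) > 0.05
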