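import numpy as np
import pytest

from indets import (
    AnalysisConfig,
    REPORT_ROWS,
    SyntheticConfig,
    bray_curtis,
    distance_decay_export,
    geographic_distance,
    jaccard,
    linear_comparison,
    run_truncation_analysis,
    similarity_regression,
    simulate_dataset,
    sorensen,
    stratification_experiment,
)

from conftest import make_table


class TestLinearComparison:
    def test_identity_is_exact(self):
        x = np.array([0.1, 0.4, 0.35, 0.8, 0.55])
        r = linear_comparison(x, x.copy(), n_perm=99, seed=0)
        assert r.r2_adj == 1.0
        assert r.slope == 1.0
        assert r.intercept == 0.0
        assert not r.slope_differs_from_1

    def test_exact_scaling(self):
        x = np.array([0.1, 0.4, 0.35, 0.8, 0.55])
        r = linear_comparison(x, 0.9 * x, n_perm=99, seed=0)
        assert r.slope == pytest.approx(0.9)
        assert r.r2_adj == pytest.approx(1.0)
        assert r.slope_differs_from_1

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        x = rng.uniform(size=40)
        y = x + rng.normal(0, 0.05, size=40)
        r = linear_comparison(x, y, n_perm=499, seed=1)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.slope == pytest.approx(fit.params[1], rel=1e-10)
        assert r.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert r.r2_adj == pytest.approx(fit.rsquared_adj, rel=1e-10)
        lo, hi = fit.conf_int()[1]
        assert r.slope_ci95 == pytest.approx((lo, hi), rel=1e-8)
        assert r.slope_differs_from_1 == (not lo <= 1.0 <= hi)
        assert r.perm_p < 0.01  # strong true relation

    def test_permutation_p_uniform_under_null(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        pvals = []
        for k in range(200):
            x = rng.uniform(size=20)
            y = rng.uniform(size=20)
            pvals.append(linear_comparison(x, y, n_perm=199, seed=k).perm_p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_comparison(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_similarity_regression_requires_matched_labels(self):
        t = make_table([[2, 0], [1, 1], [3, 3]])
        a = bray_curtis(t)
        b = bray_curtis(t.subset_plots(["p2", "p1", "p0"]))
        with pytest.raises(ValueError):
            similarity_regression(a, b, n_perm=9)


@pytest.fixture(scope="module")
def zero_ums_report():
    cfg = SyntheticConfig(n_plots=12, stems_per_plot=150, pool_stems=20_000,
                          unid_species_frac=0.0, seed=5)
    t, geo = simulate_dataset(cfg)
    a = AnalysisConfig(n_perm=99, rc_reps=49, mantel_perm=49, nmds_starts=4,
                       seed=5)
    return run_truncation_analysis(t, geo, a)


@pytest.fixture(scope="module")
def biased_report(small_dataset):
    t, geo = small_dataset
    a = AnalysisConfig(n_perm=199, rc_reps=99, mantel_perm=99, nmds_starts=6,
                       seed=5)
    return run_truncation_analysis(t, geo, a)


class TestTruncationAnalysis:
    def test_report_schema(self, biased_report):
        assert set(biased_report.rows) == set(REPORT_ROWS)
        assert set(biased_report.mantel) == {
            (v, i) for v in ("ams", "ims") for i in ("bray_curtis", "raup_crick")
        }
        df = biased_report.to_frame()
        assert list(df.index) == list(REPORT_ROWS)
        assert biased_report.summary()  # renders without error

    def test_zero_ums_identity(self, zero_ums_report):
        # with no unidentified species the IMS view is the AMS view, so every
        # AMS-vs-IMS comparison is exactly y = x
        for name in REPORT_ROWS:
            if name == "bray_genus":
                continue
            row = zero_ums_report.rows[name]
            assert row.r2_adj == 1.0, name
            assert row.slope == 1.0, name
        for index in ("bray_curtis", "raup_crick"):
            assert (
                zero_ums_report.mantel[("ams", index)].r
                == zero_ums_report.mantel[("ims", index)].r
            )

    def test_biased_loss_depresses_alpha_and_similarity(self, biased_report):
        t, df, p = biased_report.paired_t
        assert t > 0 and p < 0.05  # alpha(AMS) > alpha(IMS) per plot
        assert biased_report.rows["bray"].slope < 1.0
        assert (
            biased_report.rows["bray_genus"].r2_adj
            < biased_report.rows["bray"].r2_adj
        )

    def test_deterministic_under_seed(self, small_dataset):
        t, geo = small_dataset
        a = AnalysisConfig(n_perm=49, rc_reps=29, mantel_perm=29,
                           nmds_starts=3, seed=17)
        r1 = run_truncation_analysis(t, geo, a)
        r2 = run_truncation_analysis(t, geo, a)
        assert r1.to_frame().equals(r2.to_frame())
        assert r1.mantel_frame().equals(r2.mantel_frame())


class TestStratification:
    def test_full_fraction_zero_ums_is_identity(self):
        cfg = SyntheticConfig(n_plots=10, stems_per_plot=120, pool_stems=10_000,
                              unid_species_frac=0.0, seed=6)
        t, _ = simulate_dataset(cfg)
        res = stratification_experiment(t, fractions=(1.0,), n_iter=5, seed=6)
        for idx in ("bray_curtis", "sorensen", "jaccard"):
            assert res.mean(1.0, idx) == pytest.approx(1.0)
            assert res.table.loc[(1.0, idx), "sd_r2_adj"] == pytest.approx(0.0)

    def test_deterministic_under_seed(self, small_table):
        a = stratification_experiment(small_table, fractions=(0.5,), n_iter=8,
                                      seed=9)
        b = stratification_experiment(small_table, fractions=(0.5,), n_iter=8,
                                      seed=9)
        assert a.table.equals(b.table)

    def test_r2_degrades_with_fraction(self, small_table):
        res = stratification_experiment(
            small_table, fractions=(1.0, 0.5, 0.25), n_iter=15, seed=10
        )
        for idx in ("bray_curtis", "sorensen", "jaccard"):
            assert res.mean(1.0, idx) > res.mean(0.5, idx) > res.mean(0.25, idx)

    def test_ims_baseline_option(self, small_table):
        res = stratification_experiment(small_table, fractions=(1.0,),
                                        n_iter=3, seed=11, baseline="ims")
        for idx in ("bray_curtis", "sorensen", "jaccard"):
            assert res.mean(1.0, idx) == pytest.approx(1.0)

    def test_tiny_fraction_rejected(self, small_table):
        with pytest.raises(ValueError):
            stratification_experiment(small_table, fractions=(0.001,),
                                      n_iter=2, seed=0)


class TestDistanceDecayExport:
    def test_rows_sorted_and_counted(self, small_dataset):
        t, geo = small_dataset
        sim = bray_curtis(t)
        dist = geographic_distance(geo.subset(list(sim.labels)))
        df = distance_decay_export(sim, dist)
        n = sim.n
        assert len(df) == n * (n - 1) // 2
        assert (np.diff(df["distance_km"]) >= 0).all()

    def test_identical_pair_at_zero_distance(self):
        from indets.community import PlotGeo

        t = make_table([[2, 3], [2, 3], [9, 0]])
        geo = PlotGeo(("p0", "p1", "p2"), "planar",
                      np.array([0.0, 0.0, 5.0]), np.array([0.0, 0.0, 0.0]))
        df = distance_decay_export(bray_curtis(t), geographic_distance(geo))
        first = df.iloc[0]
        assert first["distance_km"] == 0.0
        assert first["similarity"] == pytest.approx(1.0)

    def test_label_mismatch_rejected(self, small_dataset):
        t, geo = small_dataset
        sim = bray_curtis(t)
        dist = geographic_distance(geo)
        from indets import PairwiseMatrix

        wrong = PairwiseMatrix(tuple(reversed(dist.labels)), dist.values,
                               "distance_km")
        with pytest.raises(ValueError):
            distance_decay_export(sim, wrong)
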