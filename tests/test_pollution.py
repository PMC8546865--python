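"""Pollution linkage: haversine geometry, Box-Cox pooling, radius matching,
repeated-median trends, and correlation recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import boxcox_llf, rankdata

from plastimine.pollution import (
    EARTH_RADIUS_KM,
    boxcox_lambda,
    correlate_pollution,
    country_join,
    haversine_km,
    match_pollution,
    pool_surveys,
    radius_sensitivity,
    repeated_median_fit,
)
from plastimine.synthetic import (
    GeneratorConfig,
    generate_catalogs,
    generate_enzyme_families,
    generate_geo_metadata,
    generate_pollution_surveys,
)


def brute_force_repeated_median(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    inner = []
    for i in range(n):
        slopes = [
            (y[j] - y[i]) / (x[j] - x[i]) for j in range(n) if j != i and x[j] != x[i]
        ]
        inner.append(np.median(slopes))
    slope = float(np.median(inner))
    return slope, float(np.median(y - slope * x))


class TestHaversine:
    def test_zero_for_same_point(self):
        assert haversine_km((12.3, -45.0), (12.3, -45.0)) == 0.0

    def test_quarter_great_circle(self):
        # pi*R/2, agreeing to 4 significant figures
        d = haversine_km((0, 0), (0, 90))
        assert d == pytest.approx(math.pi * EARTH_RADIUS_KM / 2, rel=1e-12)
        assert d == pytest.approx(10007.54, rel=5e-4)

    def test_one_degree_at_equator(self):
        assert haversine_km((0, 0), (0, 1)) == pytest.approx(111.195, rel=5e-4)

    def test_symmetry_and_range_check(self):
        a, b = (10.0, 20.0), (-30.0, 110.0)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))
        with pytest.raises(ValueError):
            haversine_km((95.0, 0.0), (0.0, 0.0))


class TestBoxCox:
    def test_lognormal_sample_gives_lambda_near_zero(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(size=500))
        assert abs(boxcox_lambda(x)) < 0.1

    def test_normal_sample_gives_lambda_near_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10.0, 1.0, size=500)
        assert abs(boxcox_lambda(x) - 1.0) < 0.25

    def test_returned_lambda_beats_grid(self):
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(size=200)) + 0.5
        lam = boxcox_lambda(x)
        best = boxcox_llf(lam, x)
        grid = np.arange(-5.0, 5.0 + 1e-9, 0.01)
        assert best >= max(boxcox_llf(l, x) for l in grid) - 1e-6

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_lambda([1.0, 0.0, 2.0])


class TestPooling:
    def survey(self, values, sid="SURVEY0"):
        n = len(values)
        return pd.DataFrame(
            {"survey_id": sid, "lat": np.zeros(n), "lon": np.arange(n, dtype=float),
             "value": values}
        )

    def test_per_survey_zscore_moments(self):
        rng = np.random.default_rng(2)
        surveys = [
            self.survey(np.exp(rng.normal(size=30)), "SURVEY0"),
            self.survey(rng.uniform(5, 50, size=25), "SURVEY1"),
        ]
        pooled = pool_surveys(surveys)
        for _, grp in pooled.groupby("survey_id"):
            assert grp["pooled_z"].mean() == pytest.approx(0.0, abs=1e-10)
            assert grp["pooled_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance_of_rank_order(self):
        rng = np.random.default_rng(4)
        base = np.exp(rng.normal(size=40))
        pooled = pool_surveys(
            [self.survey(base, "SURVEY0"), self.survey(base * 1000.0, "SURVEY1")]
        )
        z0 = pooled[pooled["survey_id"] == "SURVEY0"]["pooled_z"].to_numpy()
        z1 = pooled[pooled["survey_id"] == "SURVEY1"]["pooled_z"].to_numpy()
        assert np.array_equal(rankdata(z0), rankdata(z1))

    def test_single_survey_equals_plain_boxcox_zscore(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(1.0, 9.0, size=20)
        pooled = pool_surveys([self.survey(vals)])
        from scipy.stats import boxcox

        lam = boxcox_lambda(vals)
        t = boxcox(vals, lam)
        z = (t - t.mean()) / t.std()
        np.testing.assert_allclose(pooled["pooled_z"].to_numpy(), z, atol=1e-8)

    def test_nonpositive_values_shifted(self):
        vals = np.array([-2.0, 0.0, 1.0, 4.0, 9.0])
        pooled = pool_surveys([self.survey(vals)])
        assert pooled["shift"].iloc[0] == pytest.approx(3.0)  # 1 - min

    def test_too_small_survey_rejected(self):
        with pytest.raises(ValueError):
            pool_surveys([self.survey(np.array([1.0, 2.0]))])


class TestMatching:
    def points(self, coords, sid="SURVEY0"):
        df = pd.DataFrame(coords, columns=["lat", "lon"])
        df["survey_id"] = sid
        df["point_index"] = np.arange(len(df))
        df["value"] = 1.0
        df["pooled_z"] = np.arange(len(df), dtype=float)
        return df

    def samples(self, coords):
        df = pd.DataFrame(coords, columns=["lat", "lon"])
        df["sample_id"] = [f"S{i}" for i in range(len(df))]
        return df

    def test_nearest_point_within_radius(self):
        matched = match_pollution(
            self.samples([(0.0, 0.0)]), self.points([(0.0, 1.0), (0.0, 5.0)]), 400.0
        )
        assert matched.iloc[0]["point_index"] == 0
        assert matched.iloc[0]["distance_km"] == pytest.approx(111.195, rel=1e-3)

    def test_unmatched_beyond_radius(self):
        matched = match_pollution(
            self.samples([(0.0, 0.0)]), self.points([(0.0, 1.0), (0.0, 5.0)]), 100.0
        )
        assert math.isnan(matched.iloc[0]["distance_km"])

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        samples = self.samples(list(zip(rng.uniform(-60, 60, 50), rng.uniform(-180, 180, 50))))
        points = self.points(list(zip(rng.uniform(-60, 60, 50), rng.uniform(-180, 180, 50))))
        radius = 3000.0
        matched = match_pollution(samples, points, radius)
        for i, row in matched.iterrows():
            dists = [
                haversine_km(
                    (samples.iloc[i]["lat"], samples.iloc[i]["lon"]),
                    (p["lat"], p["lon"]),
                )
                for _, p in points.iterrows()
            ]
            best = int(np.argmin(dists))
            if dists[best] <= radius:
                assert row["point_index"] == best
                assert row["distance_km"] == pytest.approx(dists[best])
            else:
                assert math.isnan(row["distance_km"])

    def test_matched_distances_respect_radius_and_monotone_coverage(self):
        rng = np.random.default_rng(14)
        samples = self.samples(list(zip(rng.uniform(-60, 60, 30), rng.uniform(-180, 180, 30))))
        points = self.points(list(zip(rng.uniform(-60, 60, 10), rng.uniform(-180, 180, 10))))
        counts = pd.Series(rng.integers(0, 9, 30).astype(float), index=samples["sample_id"])
        tab = radius_sensitivity(samples, points, counts, [500, 2000, 8000, 20015])
        assert (tab["n_matched"].diff().dropna() >= 0).all()
        assert tab.iloc[-1]["n_matched"] == len(samples)  # half circumference


class TestRepeatedMedian:
    def test_collinear_points(self):
        x = np.arange(1.0, 6.0)
        fit = repeated_median_fit(x, 2 * x + 1)
        assert (fit.slope, fit.intercept) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_single_gross_outlier_ignored(self):
        x = np.arange(1.0, 7.0)
        y = 2 * x + 1
        y[5] = 1e6
        fit = repeated_median_fit(x, y)
        assert fit.slope == pytest.approx(2.0)

    def test_matches_double_median_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        fit = repeated_median_fit(x, y)
        slope, intercept = brute_force_repeated_median(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_breakdown_below_half(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 10, 21)
        y = 2 * x + 1
        corrupt = rng.choice(21, size=9, replace=False)  # 43% < 50%
        y2 = y.copy()
        y2[corrupt] = rng.uniform(-1e4, 1e4, size=9)
        fit = repeated_median_fit(x, y2)
        assert abs(fit.slope - 2.0) < 2.0  # stays near the clean slope

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        fit1 = repeated_median_fit(x, y)
        perm = rng.permutation(15)
        fit2 = repeated_median_fit(x[perm], y[perm])
        assert fit1.slope == pytest.approx(fit2.slope)
        assert fit1.intercept == pytest.approx(fit2.intercept)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            repeated_median_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationRecovery:
    def study(self, seed, n=60, rho=0.5):
        cfg = GeneratorConfig(
            seed=seed, n_samples=n, n_families=2, family_size=2, seq_length=60,
            genes_per_sample=100, control_genes=10, target_rho=rho,
        )
        fams = generate_enzyme_families(cfg)
        meta = generate_geo_metadata(cfg)
        _, _, _, planted = generate_catalogs(cfg, fams, meta)
        surveys = generate_pollution_surveys(cfg, meta)
        return meta, pool_surveys(surveys), planted

    def test_monotone_counts_give_rho_one(self):
        rng = np.random.default_rng(1)
        matched = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(10)],
             "pooled_z": np.sort(rng.normal(size=10)),
             "distance_km": 1.0}
        )
        counts = pd.Series(np.arange(10.0), index=matched["sample_id"])
        corr, trend = correlate_pollution(matched, counts)
        assert corr.rho == pytest.approx(1.0)
        assert trend.slope > 0

    def test_independent_counts_stay_near_zero(self):
        meta, pooled, _ = self.study(seed=21, rho=0.0)
        matched = match_pollution(meta, pooled, 400.0)
        rng = np.random.default_rng(2)
        counts = pd.Series(
            rng.integers(0, 40, len(meta)).astype(float),
            index=meta["sample_id"],
        )
        corr, _ = correlate_pollution(matched, counts)
        assert abs(corr.rho) < 0.3

    def test_target_rho_recovered_within_tolerance(self):
        meta, pooled, planted = self.study(seed=1)
        tab = radius_sensitivity(meta, pooled, planted, [200.0, 400.0, 800.0])
        assert (tab["coverage"] == 1.0).all()
        assert np.allclose(tab["rho"], 0.5, atol=0.15)


class TestCountryJoin:
    def test_exact_key_join(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "country": ["CN", "SE", "XX"], "n_hits": [5, 2, 7]}
        )
        waste = pd.DataFrame({"country": ["CN", "SE"], "share": [0.27, 0.01]})
        out = country_join(samples, waste)
        assert set(out["sample_id"]) == {"a", "b"}
        assert out.set_index("sample_id").loc["a", "share"] == pytest.approx(0.27)
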