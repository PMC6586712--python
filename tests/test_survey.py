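"""Design-based estimators: extent, means, local variance, and S:N."""

import numpy as np
import pandas as pd
import pytest

from nnpi.survey import (
    category_extent,
    ci_nonoverlap,
    local_mean_variance,
    population_mean,
    signal_to_noise,
    srs_total_variance,
)

from conftest import make_sites


def nnpi_frame(site_ids, categories):
    return pd.DataFrame({"site_id": site_ids, "overall": categories})


class TestCategoryExtent:
    def test_all_low_takes_all_weight(self):
        sites = make_sites(["A", "B"], weight=[4.0, 6.0])
        est = category_extent(sites, nnpi_frame(["A", "B"], ["LOW", "LOW"]),
                              variance_method="srs")
        by_cat = {e.category: e for e in est}
        assert by_cat["LOW"].area_ha == pytest.approx(10.0)
        assert by_cat["MODERATE"].area_ha == 0.0
        assert by_cat["LOW"].pct_of_domain == pytest.approx(100.0)

    def test_weight_sums_and_percents(self):
        sites = make_sites(list("ABCD"), weight=[1.0, 2.0, 3.0, 4.0])
        cats = ["LOW", "LOW", "HIGH", "HIGH"]
        est = category_extent(sites, nnpi_frame(list("ABCD"), cats),
                              variance_method="srs")
        by_cat = {e.category: e for e in est}
        assert by_cat["LOW"].area_ha == pytest.approx(3.0)
        assert by_cat["HIGH"].area_ha == pytest.approx(7.0)
        assert by_cat["LOW"].pct_of_domain == pytest.approx(30.0)
        assert by_cat["HIGH"].pct_of_domain == pytest.approx(70.0)

    def test_srs_se_matches_hand_computed_variance(self):
        # z = w*y for LOW: (1, 2, 0, 0); v = n/(n-1) * sum((z - 0.75)^2)
        sites = make_sites(list("ABCD"), weight=[1.0, 2.0, 3.0, 4.0])
        cats = ["LOW", "LOW", "HIGH", "HIGH"]
        est = category_extent(sites, nnpi_frame(list("ABCD"), cats),
                              variance_method="srs")
        z = np.array([1.0, 2.0, 0.0, 0.0])
        hand = 4 / 3 * np.sum((z - z.mean()) ** 2)
        low = [e for e in est if e.category == "LOW"][0]
        assert low.se == pytest.approx(np.sqrt(hand))
        assert low.ci95 == (
            pytest.approx(max(0.0, 3.0 - 1.96 * low.se)),
            pytest.approx(3.0 + 1.96 * low.se),
        )

    def test_domain_split_by_ecoregion(self):
        sites = make_sites(list("ABCD"), weight=[1.0] * 4,
                           ecoregion=["CPL", "CPL", "XER", "XER"])
        est = category_extent(sites, nnpi_frame(list("ABCD"), ["LOW"] * 4),
                              domain_spec="ecoregion", variance_method="srs")
        domains = {e.domain for e in est}
        assert domains == {"CPL", "XER"}

    def test_conservation_categories_sum_to_domain_weight(self, synth_dataset):
        from nnpi.metrics import site_metrics
        from nnpi.classify import classify_table

        ds = synth_dataset
        ndf = classify_table(site_metrics(ds))
        prob = ds.probability_sites()
        for dom in ("national", "ecoregion", "wetland_type"):
            est = category_extent(prob, ndf[ndf["visit_no"] == 1], dom)
            totals = {}
            for e in est:
                totals[e.domain] = totals.get(e.domain, 0.0) + e.area_ha
            for domain, total in totals.items():
                if dom == "national":
                    expected = prob["weight"].sum()
                else:
                    expected = prob.loc[prob[dom] == domain, "weight"].sum()
                assert total == pytest.approx(expected, abs=1e-9 * max(1, expected))

    def test_scale_equivariance_in_weights(self):
        sites = make_sites(list("ABCD"), weight=[1.0, 2.0, 3.0, 4.0])
        cats = nnpi_frame(list("ABCD"), ["LOW", "LOW", "HIGH", "HIGH"])
        a = category_extent(sites, cats, variance_method="srs")
        sites_k = sites.assign(weight=sites["weight"] * 7.0)
        b = category_extent(sites_k, cats, variance_method="srs")
        for ea, eb in zip(a, b):
            assert eb.area_ha == pytest.approx(7.0 * ea.area_ha)
            assert eb.se == pytest.approx(7.0 * ea.se)
            assert eb.pct_of_domain == pytest.approx(ea.pct_of_domain)


class TestPopulationMean:
    def test_equal_weights_is_arithmetic_mean(self):
        sites = make_sites(list("ABC"))
        est = population_mean([1.0, 2.0, 6.0], sites, variance_method="srs")[0]
        assert est.mean == pytest.approx(3.0)

    def test_weighted_mean_example(self):
        sites = make_sites(list("AB"), weight=[1.0, 3.0])
        est = population_mean([1.0, 3.0], sites, variance_method="srs")[0]
        assert est.mean == pytest.approx(2.5)

    def test_single_site_domain_has_undefined_se(self):
        sites = make_sites(["A"])
        est = population_mean([4.2], sites, variance_method="srs")[0]
        assert est.mean == pytest.approx(4.2)
        assert est.se is None and est.ci95 is None

    def test_mean_bounded_by_values(self, synth_dataset):
        prob = synth_dataset.probability_sites()
        vals = np.linspace(-5, 5, len(prob))
        for est in population_mean(vals, prob, "ecoregion"):
            assert vals.min() - 1e-12 <= est.mean <= vals.max() + 1e-12

    def test_weights_scale_invariance_of_mean_and_se(self):
        rng = np.random.default_rng(0)
        sites = make_sites([f"S{i}" for i in range(30)],
                           weight=rng.gamma(2, 3, 30),
                           x=rng.random(30), y=rng.random(30))
        vals = rng.normal(size=30)
        a = population_mean(vals, sites)[0]
        b = population_mean(vals, sites.assign(weight=sites["weight"] * 11.0))[0]
        assert b.mean == pytest.approx(a.mean)
        assert b.se == pytest.approx(a.se)


class TestLocalMeanVariance:
    def test_identical_contributions_give_zero(self):
        rng = np.random.default_rng(1)
        coords = rng.random((40, 2))
        assert local_mean_variance(np.full(40, 3.3), coords) == pytest.approx(0.0)

    def test_fallback_to_srs_below_neighborhood_size(self, caplog):
        z = np.array([1.0, 2.0, 4.0])
        coords = np.array([[0, 0], [0, 1], [1, 0]], dtype=float)
        with caplog.at_level("WARNING"):
            v = local_mean_variance(z, coords, nbh_size=4)
        assert v == pytest.approx(srs_total_variance(z))
        assert "falling back" in caplog.text

    def test_agrees_with_srs_on_spatially_random_data(self):
        """No spatial structure: the two estimators agree within 25% on
        average over 50 seeds."""
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            coords = rng.random((120, 2))
            z = rng.normal(10, 2, 120)
            ratios.append(local_mean_variance(z, coords) / srs_total_variance(z))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_beats_srs_under_spatial_trend(self):
        """A strong smooth trend inflates the global variance but not the
        local one."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            coords = rng.random((150, 2))
            z = 50 * coords[:, 0] + 30 * coords[:, 1] + rng.normal(0, 1, 150)
            if local_mean_variance(z, coords) < srs_total_variance(z):
                wins += 1
        assert wins == 20


class TestSignalToNoise:
    @staticmethod
    def frame(v1, pairs):
        rows = [{"site_id": f"S{i}", "visit_no": 1, "value": v} for i, v in enumerate(v1)]
        rows += [{"site_id": f"S{i}", "visit_no": 2, "value": v} for i, v in pairs.items()]
        return pd.DataFrame(rows)

    def test_zero_noise_with_signal_is_infinite(self):
        df = self.frame([1.0, 2.0, 3.0, 4.0], {0: 1.0, 1: 2.0})
        r = signal_to_noise(df)
        assert np.isinf(r.ratio) and r.noise_var == 0.0

    def test_all_equal_everywhere_is_undefined(self):
        df = self.frame([5.0] * 4, {0: 5.0, 1: 5.0})
        with pytest.raises(ValueError, match="undefined"):
            signal_to_noise(df)

    def test_hand_computed_example(self):
        # visit-1: 0, 2, 4 -> signal var 4; pairs differ by 2 and 0 ->
        # noise = mean(4, 0)/2 = 1
        df = self.frame([0.0, 2.0, 4.0], {0: 2.0, 1: 2.0})
        r = signal_to_noise(df)
        assert r.signal_var == pytest.approx(4.0)
        assert r.noise_var == pytest.approx(1.0)
        assert r.ratio == pytest.approx(4.0)

    def test_parameter_recovery_on_simulated_revisits(self):
        """Between-site SD 3, within-site SD 1 -> S:N ~ 9 within 30%."""
        rng = np.random.default_rng(123)
        n_sites, n_pairs = 500, 200
        mu = rng.normal(0, 3, n_sites)
        v1 = mu + rng.normal(0, 1, n_sites)
        revisit = rng.choice(n_sites, n_pairs, replace=False)
        rows = [{"site_id": f"S{i}", "visit_no": 1, "value": v1[i]} for i in range(n_sites)]
        rows += [
            {"site_id": f"S{i}", "visit_no": 2, "value": mu[i] + rng.normal(0, 1)}
            for i in revisit
        ]
        r = signal_to_noise(pd.DataFrame(rows))
        # total visit-1 variance 9+1 = 10 over noise 1
        assert r.ratio == pytest.approx(10.0, rel=0.30)


def test_ci_nonoverlap_flag():
    assert ci_nonoverlap((0.0, 1.0), (2.0, 3.0))
    assert not ci_nonoverlap((0.0, 2.5), (2.0, 3.0))


def test_ci_coverage_near_nominal_over_synthetic_populations():
    """95% CI on a category-area total covers the truth in 95% +/- 2% of
    1000 replicates: finite population, unequal draw probabilities, sites
    drawn with replacement, weight = a_i / (n p_i)."""
    rng = np.random.default_rng(2024)
    M, n, reps = 400, 80, 1000
    area = rng.gamma(2.0, 50.0, M)
    is_low = rng.random(M) < 0.45
    truth = area[is_low].sum()
    # inclusion roughly proportional to areal size (the area-resource
    # design convention), jittered so weights remain genuinely unequal
    p = area * rng.lognormal(0.0, 0.5, M)
    p = p / p.sum()
    hits = 0
    for _ in range(reps):
        draw = rng.choice(M, size=n, replace=True, p=p)
        w = area[draw] / (n * p[draw])
        z = w * is_low[draw]
        total = z.sum()
        se = np.sqrt(srs_total_variance(z))
        if total - 1.96 * se <= truth <= total + 1.96 * se:
            hits += 1
    assert hits / reps == pytest.approx(0.95, abs=0.02)
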