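"""Disaggregation and OLS estimation: conservation, splits, fits, totals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blockpop as bp
from blockpop.estimators import EstimationError


class TestDisaggregate:
    def test_proportional_split(self):
        assert bp.disaggregate(100, [1, 1, 2]).tolist() == [25.0, 25.0, 50.0]

    def test_zero_weights_leave_unallocated(self, caplog):
        with caplog.at_level("WARNING"):
            out = bp.disaggregate(500, [0, 0, 0])
        assert out.tolist() == [0.0, 0.0, 0.0]
        assert any("unallocatable" in r.message for r in caplog.records)

    def test_negative_weight_rejected(self):
        with pytest.raises(EstimationError):
            bp.disaggregate(10, [1, -1])

    @given(st.integers(0, 10**6),
           st.lists(st.floats(0, 1e6), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_conserves_parent_and_matches_formula(self, parent, weights):
        out = bp.disaggregate(parent, weights)
        total = sum(weights)
        if total == 0:
            assert out.sum() == 0
        else:
            assert out.sum() == pytest.approx(parent, rel=1e-9, abs=1e-9)
            for w, o in zip(weights, out):
                assert o == pytest.approx(parent * w / total, rel=1e-9, abs=1e-9)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c):
        w = np.array([3.0, 1.0, 6.0])
        base = bp.disaggregate(120, w)
        scaled = bp.disaggregate(120, c * w)
        assert np.allclose(base, scaled, rtol=1e-9)


class TestRunDisaggregation:
    def test_single_child_gets_parent_population(self, rect_building):
        units = [
            bp.StatUnit(id="C0", level="country", parent_id=None, population=42),
            bp.StatUnit(id="M0", level="municipality", parent_id="C0", population=42),
            bp.StatUnit(id="D0", level="district", parent_id="M0", population=42),
            bp.StatUnit(id="n1", level="neighbourhood", parent_id="D0",
                        population=42, land_area=1.0),
        ]
        h = bp.Hierarchy(units)
        lod = bp.LODSpec("LOD0", "a")
        px = {"n1": bp.UnitProxy("n1", lod, 55.0, 6.0, 1)}
        res = bp.DisaggregationModel(h, px, "D1", lod).fit()
        assert res.predicted.iloc[0] == 42.0

    def test_conservation_per_parent(self, world):
        lod = bp.LODSpec("LOD0+", "b")
        nbhd = bp.compute_unit_proxies(world.buildings, world.hierarchy, lod)
        res = bp.DisaggregationModel(world.hierarchy, nbhd, "D2", lod).fit()
        df = res.estimates.set_index("unit_id")
        for mu in world.hierarchy.units_at("municipality"):
            kids = [u.id for u in world.hierarchy.descendants_at(mu.id, "neighbourhood")]
            assert df.loc[kids, "predicted"].sum() == pytest.approx(
                mu.population, rel=1e-9)

    def test_missing_proxy_errors(self, world):
        lod = bp.LODSpec("LOD0", "a")
        with pytest.raises(EstimationError, match="missing proxy"):
            bp.DisaggregationModel(world.hierarchy, {}, "D6", lod).fit()

    def test_semantic_b_equals_c_when_fractions_pure(self, noiseless_world):
        h, blds = noiseless_world.hierarchy, noiseless_world.buildings
        for task in ("D1", "D5"):
            rb = bp.DisaggregationModel.from_buildings(
                h, blds, task, bp.LODSpec("LOD1", "b")).fit()
            rc = bp.DisaggregationModel.from_buildings(
                h, blds, task, bp.LODSpec("LOD1", "c")).fit()
            assert np.array_equal(rb.predicted.to_numpy(), rc.predicted.to_numpy())


class TestSplit:
    def test_basic_split(self):
        train, test = bp.split_train_test([f"u{i}" for i in range(100)], 0.1, seed=1)
        assert len(train) == 10 and len(test) == 90
        assert not set(train) & set(test)

    def test_seed_reproducibility(self):
        ids = [f"u{i}" for i in range(50)]
        assert bp.split_train_test(ids, 0.1, seed=5) == bp.split_train_test(ids, 0.1, seed=5)
        assert bp.split_train_test(ids, 0.1, seed=5) != bp.split_train_test(ids, 0.1, seed=6)

    def test_round_half_up_of_train_size(self):
        ids = [f"u{i}" for i in range(12237)]
        train, test = bp.split_train_test(ids, 0.1, seed=0)
        assert len(train) == 1224
        assert len(train) + len(test) == 12237

    def test_minimum_training_size(self):
        train, _ = bp.split_train_test(list("abcdefgh"), 0.1, seed=0)
        assert len(train) == 3

    def test_too_few_units_errors(self):
        with pytest.raises(EstimationError):
            bp.split_train_test(["a", "b", "c"], 0.1, seed=0)


class TestFitOLS:
    def test_exact_line(self):
        x = np.arange(1, 11, dtype=float)
        m = bp.fit_ols(x, 2 * x)
        assert m.intercept == pytest.approx(0.0, abs=1e-10)
        assert m.coef_proxy == pytest.approx(2.0, rel=1e-10)

    def test_rank_deficiency_rejected(self):
        x = np.full(10, 7.0)  # constant regressor duplicates the intercept
        with pytest.raises(EstimationError, match="rank-deficient"):
            bp.fit_ols(x, np.arange(10.0))

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 50)
        h = rng.uniform(3, 30, 50)
        y = 5 + 0.8 * x + 2.5 * h + rng.normal(0, 1, 50)
        m = bp.fit_ols(x, y, mean_height=h)
        X = np.column_stack([np.ones(50), x, h])
        beta = np.linalg.pinv(X) @ y
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        assert m.coef_proxy == pytest.approx(beta[1], abs=1e-8)
        assert m.coef_mean_height == pytest.approx(beta[2], abs=1e-8)

    def test_no_intercept_variant(self):
        x = np.arange(1, 8, dtype=float)
        m = bp.fit_ols(x, 3 * x, intercept=False)
        assert m.intercept == 0.0
        assert m.coef_proxy == pytest.approx(3.0, rel=1e-10)


class TestPredict:
    def test_simple_prediction(self):
        m = bp.fit_ols(np.arange(1, 11, dtype=float), 2 * np.arange(1, 11.0))
        assert bp.predict_population(m, [50.0])[0] == pytest.approx(100.0)

    def test_negative_clamped_with_log(self, caplog):
        m = bp.RegressionModel(intercept=-12.0, coef_proxy=0.0,
                               coef_mean_height=None, n=5, rss=0.0)
        with caplog.at_level("WARNING"):
            out = bp.predict_population(m, [1.0, 2.0])
        assert out.tolist() == [0.0, 0.0]
        assert any("clamped" in r.message for r in caplog.records)

    def test_batch_equals_elementwise(self):
        rng = np.random.default_rng(8)
        m = bp.RegressionModel(intercept=3.0, coef_proxy=0.5,
                               coef_mean_height=None, n=5, rss=0.0)
        xs = rng.uniform(0, 100, 25)
        batch = bp.predict_population(m, xs)
        single = [bp.predict_population(m, [x])[0] for x in xs]
        assert np.allclose(batch, single)


class TestCountryTotal:
    def test_perfect_predictions_recover_truth(self, small_world):
        h = small_world.hierarchy
        ids = [u.id for u in h.units_at("neighbourhood")]
        train, test = bp.split_train_test(ids, 0.1, seed=0)
        preds = {uid: float(h[uid].population) for uid in test}
        total = bp.estimate_country_total(h, train, preds, "neighbourhood")
        assert total == h.root.population

    def test_incomplete_coverage_errors(self, small_world):
        h = small_world.hierarchy
        ids = [u.id for u in h.units_at("neighbourhood")]
        train, test = bp.split_train_test(ids, 0.1, seed=0)
        with pytest.raises(EstimationError, match="missing"):
            bp.estimate_country_total(h, train, {test[0]: 1.0}, "neighbourhood")

    def test_exact_world_country_estimate_is_exact(self, noiseless_world):
        """In the noiseless-proportional world the proxy-population relation
        is exactly linear, so a sampling census recovers the country total."""
        h = noiseless_world.hierarchy
        lod = bp.LODSpec("LOD0+", "c")
        nbhd = bp.compute_unit_proxies(noiseless_world.buildings, h, lod)
        res = bp.PopulationRegression(h, nbhd, "neighbourhood", lod).fit(seed=2)
        assert res.country_total == pytest.approx(h.root.population, rel=1e-6)


class TestEnhancedModel:
    def test_enhancement_rejected_at_lod0(self, world):
        lod = bp.LODSpec("LOD0", "b")
        nbhd = bp.compute_unit_proxies(world.buildings, world.hierarchy, lod)
        with pytest.raises(EstimationError, match="LOD0"):
            bp.PopulationRegression(world.hierarchy, nbhd, "neighbourhood",
                                    lod, enhanced=True)

    def test_enhanced_fit_runs_at_lod1(self, world):
        lod = bp.LODSpec("LOD1", "c")
        nbhd = bp.compute_unit_proxies(world.buildings, world.hierarchy, lod)
        res = bp.PopulationRegression(world.hierarchy, nbhd, "neighbourhood",
                                      lod, enhanced=True).fit(seed=4)
        assert res.model.coef_mean_height is not None
        assert (res.predicted >= 0).all()

    def test_summary_mentions_fit(self, world):
        lod = bp.LODSpec("LOD1", "b")
        nbhd = bp.compute_unit_proxies(world.buildings, world.hierarchy, lod)
        res = bp.PopulationRegression(world.hierarchy, nbhd, "neighbourhood",
                                      lod).fit(seed=4)
        text = res.summary()
        assert "median APE" in text and "country total" in text
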