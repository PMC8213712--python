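"""Standardization, collinearity, logistic fitting, ROC, scale comparison."""

import numpy as np
import pytest
from scipy.special import expit, logit

from cluesim import synthetic
from cluesim.rasterkit import CLASS_CODES, DRIVER_NAMES, DriverStack, Grid, LULCMap
from cluesim.suitability import (
    apply_standardization,
    collinearity_diagnostics,
    fit_binary_logistic,
    fit_suitability_model,
    predict_all,
    predict_probability,
    roc_auc,
    scale_selection,
    standardize,
)

from conftest import make_lulc


def _stack_from_arrays(arrays: dict) -> DriverStack:
    return DriverStack(
        {n: Grid(np.asarray(a, dtype=float), cellsize=60) for n, a in arrays.items()},
        raw=False,
    )


def _random_stack(rng, shape=(40, 40)) -> DriverStack:
    return _stack_from_arrays({n: rng.normal(size=shape) for n in DRIVER_NAMES})


class TestStandardize:
    def test_two_point_layer(self):
        rng = np.random.default_rng(0)
        arrays = {n: rng.normal(size=(1, 2)) for n in DRIVER_NAMES}
        arrays["elevation"] = np.array([[0.0, 10.0]])
        std, params = standardize(_stack_from_arrays(arrays))
        np.testing.assert_allclose(std["elevation"].values, [[-1.0, 1.0]])
        assert params["elevation"] == (5.0, 5.0)  # population sd

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        std, _ = standardize(_random_stack(rng))
        std2, _ = standardize(std)
        for n in DRIVER_NAMES:
            np.testing.assert_allclose(std2[n].values, std[n].values, atol=1e-12)

    def test_outputs_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        std, _ = standardize(_random_stack(rng))
        for n in DRIVER_NAMES:
            v = std[n].values[std[n].valid_mask]
            assert abs(v.mean()) < 1e-9
            assert abs(v.std() - 1) < 1e-9

    def test_constant_layer_error_names_driver(self):
        rng = np.random.default_rng(3)
        arrays = {n: rng.normal(size=(5, 5)) for n in DRIVER_NAMES}
        arrays["slope"] = np.zeros((5, 5))
        with pytest.raises(ValueError, match="slope"):
            standardize(_stack_from_arrays(arrays))


class TestCollinearity:
    def test_orthogonal_drivers_have_unit_vif(self):
        # orthonormal columns: tolerance 1, VIF 1
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(np.column_stack([np.ones(49), rng.normal(size=(49, 7))]))
        q = q[:, 1:]  # mean-centred, mutually orthogonal columns
        arrays = {n: q[:, i].reshape(7, 7) for i, n in enumerate(DRIVER_NAMES)}
        rep = collinearity_diagnostics(_stack_from_arrays(arrays))
        for n in DRIVER_NAMES:
            assert rep.tolerance[n] == pytest.approx(1.0, abs=1e-9)
            assert rep.vif[n] == pytest.approx(1.0, abs=1e-9)
        assert rep.flagged == ()

    def test_duplicated_driver_flagged(self):
        rng = np.random.default_rng(5)
        arrays = {n: rng.normal(size=(10, 10)) for n in DRIVER_NAMES}
        arrays["slope"] = arrays["elevation"].copy()
        rep = collinearity_diagnostics(_stack_from_arrays(arrays))
        assert rep.tolerance["slope"] < 1e-9
        assert "slope" in rep.flagged and "elevation" in rep.flagged

    def test_vif_tolerance_reciprocity(self, landscape200):
        rep = collinearity_diagnostics(landscape200["drivers"])
        for n in DRIVER_NAMES:
            assert abs(rep.vif[n] * rep.tolerance[n] - 1.0) < 1e-9

    def test_reciprocity_consistent_with_published_pair(self):
        # a printed tolerance of 0.207 (3 dp) is reciprocal with the
        # printed VIF of 4.833 within rounding
        lo, hi = 1 / 0.2075, 1 / 0.2065
        assert lo <= 4.833 <= hi


class TestLogisticFit:
    def test_permuted_labels_give_null_model(self, landscape200):
        # breaking the label/driver link leaves only the intercept:
        # logit(prevalence) at n = 40,000
        rng = np.random.default_rng(6)
        lulc = landscape200["t0"]
        vals = np.asarray(lulc.values).copy()
        mask = lulc.grid.valid_mask
        perm = vals[mask]
        rng.shuffle(perm)
        vals[mask] = perm
        shuffled = LULCMap(lulc.grid.copy(values=vals))
        std, _ = standardize(landscape200["drivers"])
        cm = fit_binary_logistic(shuffled, 1, std)
        prevalence = (perm == 1).mean()
        assert abs(cm.intercept - logit(prevalence)) < 0.05
        for b in cm.coefficients.values():
            assert abs(b) < 0.05

    def test_single_driver_generative_recovery(self):
        # binary outcome drawn from a logistic law with beta = 1.5 on one
        # standardized driver: recovered within ±0.1 at n = 40,000
        rng = np.random.default_rng(7)
        x = rng.normal(size=(200, 200))
        x = (x - x.mean()) / x.std()
        p = expit(-0.5 + 1.5 * x)
        y = (rng.random(x.shape) < p).astype(np.int32) + 1  # classes 1/2
        lulc = make_lulc(y)
        arrays = {n: rng.normal(size=(200, 200)) for n in DRIVER_NAMES}
        arrays["elevation"] = x
        std, _ = standardize(_stack_from_arrays(arrays))
        cm = fit_binary_logistic(lulc, 2, std, included=("elevation",))
        assert cm.coefficients["elevation"] == pytest.approx(1.5, abs=0.1)
        assert cm.converged and not cm.separation

    def test_prescaling_invariance(self, landscape100):
        # doubling a driver before standardization cannot move the fit
        lulc = landscape100["lulc"]
        drivers = landscape100["drivers"]
        doubled = drivers.map_layers(
            lambda n, g: g.copy(values=np.asarray(g.values) * 2.0)
            if n == "elevation"
            else g,
            raw=True,
        )
        m1 = fit_suitability_model(lulc, drivers)
        m2 = fit_suitability_model(lulc, doubled)
        for c in CLASS_CODES:
            b1 = m1.classes[c].coefficients["elevation"]
            b2 = m2.classes[c].coefficients["elevation"]
            assert b1 == pytest.approx(b2, abs=1e-6)

    def test_fitted_probability_mean_equals_prevalence(self, landscape100):
        # the logistic score equation: with an intercept, mean fitted
        # probability equals the class prevalence
        lulc = landscape100["lulc"]
        model = fit_suitability_model(lulc, landscape100["drivers"])
        probs = predict_all(model, landscape100["drivers"])
        mask = lulc.grid.valid_mask
        vals = np.asarray(lulc.values)[mask]
        for c in CLASS_CODES:
            mean_p = np.asarray(probs[c].values)[mask].mean()
            assert mean_p == pytest.approx((vals == c).mean(), abs=1e-6)

    def test_empty_class_rejected(self, landscape100):
        std, _ = standardize(landscape100["drivers"])
        vals = np.asarray(landscape100["lulc"].values).copy()
        vals[vals == 4] = 2
        no4 = LULCMap(landscape100["lulc"].grid.copy(values=vals))
        with pytest.raises(ValueError, match="absent"):
            fit_binary_logistic(no4, 4, std)

    def test_separation_flagged_not_raised(self):
        rng = np.random.default_rng(8)
        arrays = {n: rng.normal(size=(20, 20)) for n in DRIVER_NAMES}
        x = rng.normal(size=(20, 20))
        arrays["elevation"] = x
        y = np.where(x > 0, 2, 1).astype(np.int32)  # perfectly separable
        std, _ = standardize(_stack_from_arrays(arrays))
        cm = fit_binary_logistic(make_lulc(y), 2, std, included=("elevation",))
        assert cm.separation


class TestPredict:
    def test_null_model_gives_half(self, landscape100):
        model = fit_suitability_model(landscape100["lulc"], landscape100["drivers"])
        model.classes[1].intercept = 0.0
        model.classes[1].coefficients = {}
        p = predict_probability(model, landscape100["drivers"], 1)
        assert np.allclose(p.values[p.valid_mask], 0.5)

    def test_published_farmland_constant_closed_form(self):
        # eta = -0.009 at the standardized origin -> P = 0.49775
        assert expit(-0.009) == pytest.approx(0.49775, abs=5e-6)

    def test_monotone_in_positive_coefficient(self, landscape100):
        model = fit_suitability_model(landscape100["lulc"], landscape100["drivers"])
        c = 1
        name = max(
            model.classes[c].coefficients, key=lambda k: model.classes[c].coefficients[k]
        )
        assert model.classes[c].coefficients[name] > 0
        drivers = landscape100["drivers"]
        p0 = predict_probability(model, drivers, c)
        bumped = drivers.map_layers(
            lambda n, g: g.copy(values=np.asarray(g.values, dtype=float) + (50.0 if n == name else 0.0)),
            raw=True,
        )
        p1 = predict_probability(model, bumped, c)
        m = p0.valid_mask
        assert np.all(p1.values[m] >= p0.values[m] - 1e-12)

    def test_probabilities_in_open_unit_interval(self, landscape100):
        model = fit_suitability_model(landscape100["lulc"], landscape100["drivers"])
        for c in CLASS_CODES:
            p = predict_probability(model, landscape100["drivers"], c)
            v = p.values[p.valid_mask]
            assert (v > 0).all() and (v < 1).all()

    def test_model_json_round_trip(self, landscape100, tmp_path):
        from cluesim.suitability import SuitabilityModel

        model = fit_suitability_model(landscape100["lulc"], landscape100["drivers"])
        model.save(tmp_path / "m.json")
        back = SuitabilityModel.load(tmp_path / "m.json")
        for c in CLASS_CODES:
            assert back.classes[c].intercept == model.classes[c].intercept
            assert back.classes[c].coefficients == model.classes[c].coefficients


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(9)
        s = rng.random(10_000)
        t = rng.random(10_000) < 0.3
        assert roc_auc(s, t) == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_pairwise_estimator(self):
        rng = np.random.default_rng(10)
        s = np.round(rng.random(60), 1)  # coarse grid forces ties
        t = rng.random(60) < 0.4
        pos, neg = s[t], s[~t]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert roc_auc(s, t) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        s = rng.normal(size=500)
        t = rng.random(500) < 0.25
        assert roc_auc(s, t) == pytest.approx(roc_auc_score(t, s), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


@pytest.fixture(scope="module")
def fine_landscape():
    # a fine-scale (30 m) landscape to aggregate across factors 2..5
    dem = synthetic.generate_dem(200, 200, cellsize=30.0, seed=14)
    feats = synthetic.generate_features(200, 200, cellsize=30.0, seed=14)
    drivers = synthetic.generate_drivers(dem, feats)
    lulc, _truth = synthetic.generate_lulc(drivers, seed=14)
    return lulc, drivers


class TestScaleSelection:
    def test_table_shape_and_range(self, fine_landscape):
        lulc, drivers = fine_landscape
        table = scale_selection(lulc, drivers, factors=(2, 3))
        assert list(table.index) == [60.0, 90.0]
        assert set(table.columns) == set(CLASS_CODES)
        vals = table.values[np.isfinite(table.values)]
        assert ((vals >= 0.45) & (vals <= 1.0)).all()

    def test_generating_classes_keep_auc_above_bar_at_factor_2(self, fine_landscape):
        lulc, drivers = fine_landscape
        table = scale_selection(lulc, drivers, factors=(2,))
        row = table.loc[60.0]
        assert (row.dropna() > 0.7).all()
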