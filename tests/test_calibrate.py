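import numpy as np
import pytest
from scipy.stats import spearmanr

from fava import (
    CalibrationParams,
    ScoredNetwork,
    calibrate_network,
    eval_calibration,
    fit_calibration,
    window_points,
)
from fava.calibrate import CalibrationPoint

TRUE = CalibrationParams(0.05, 0.1, 0.8, -8.0, 0.5)


def curve_points(params, x):
    return [CalibrationPoint(float(xi), float(eval_calibration(xi, params)), 100)
            for xi in x]


class TestWindowPoints:
    def test_small_stream_against_hand_computation(self):
        scores = np.linspace(1, 0, 20)
        labels = np.array(["TP"] * 10 + ["FP"] * 10, dtype=object)
        pts = window_points(scores, labels, window=10, step=5)
        assert len(pts) == 3
        assert pts[0] == CalibrationPoint(float(scores[:10].mean()), 1.0, 10)
        assert pts[1].y == pytest.approx(0.5)
        assert pts[2].y == pytest.approx(0.0)

    def test_all_tp_stream_gives_unit_precision(self):
        scores = np.linspace(1, 0, 30)
        labels = np.array(["TP"] * 30, dtype=object)
        assert all(p.y == 1.0 for p in window_points(scores, labels, 10, 10))

    def test_excluded_labels_skipped_before_windowing(self):
        scores = np.linspace(1, 0, 40)
        labels = np.array((["TP", "EXCLUDED", "FP", "FP"] * 10), dtype=object)
        pts = window_points(scores, labels, window=30, step=10)
        assert pts[0].n == 30
        assert pts[0].y == pytest.approx(10 / 30)

    def test_matches_brute_force_windowing(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.uniform(-1, 1, 300))[::-1]
        labels = np.array(
            [rng.choice(["TP", "FP", "EXCLUDED"], p=[0.4, 0.4, 0.2]) for _ in scores],
            dtype=object,
        )
        pts = window_points(scores, labels, window=50, step=20)
        ev = [(s, l) for s, l in zip(scores, labels) if l != "EXCLUDED"]
        expected = []
        for start in range(0, len(ev) - 50 + 1, 20):
            chunk = ev[start : start + 50]
            expected.append(
                (
                    np.mean([s for s, _ in chunk]),
                    np.mean([l == "TP" for _, l in chunk]),
                )
            )
        assert len(pts) == len(expected)
        for p, (x, y) in zip(pts, expected):
            assert p.x == pytest.approx(x) and p.y == pytest.approx(y)

    def test_too_few_evaluable_pairs_raises(self):
        scores = np.linspace(1, 0, 5)
        labels = np.array(["TP"] * 5, dtype=object)
        with pytest.raises(ValueError, match="evaluable"):
            window_points(scores, labels, window=10, step=5)

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            window_points(
                np.array([0.1, 0.9] * 10), np.array(["TP"] * 20, dtype=object), 10, 5
            )


class TestEvalCalibration:
    def test_constant_curve(self):
        p = CalibrationParams(0.5, 0.0, 0.0, 1.0, 0.0)
        assert eval_calibration(0.3, p) == pytest.approx(0.5)
        assert eval_calibration(-0.9, p) == pytest.approx(0.5)

    def test_steep_sigmoid_approaches_step(self):
        p = CalibrationParams(0.0, 0.0, 1.0, -500.0, 0.0)
        assert eval_calibration(1.0, p) == pytest.approx(1.0)
        assert eval_calibration(-1.0, p) == pytest.approx(0.0)

    def test_matches_scalar_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.uniform(-2, 2, size=5)
            p = CalibrationParams(*a)
            for x in rng.uniform(-1, 1, size=5):
                expected = a[0] + a[1] * x + a[2] / (1 + np.exp(a[3] * (x - a[4])))
                assert eval_calibration(x, p) == pytest.approx(expected, abs=1e-12)

    def test_extreme_logistic_argument_saturates(self):
        p = CalibrationParams(0.0, 0.0, 0.7, 1e6, 0.0)
        assert eval_calibration(5.0, p) == 0.0
        assert eval_calibration(-5.0, p) == pytest.approx(0.7)


class TestFitCalibration:
    def test_recovers_known_curve_from_noiseless_points(self):
        x = np.linspace(-1, 1, 40)
        fit = fit_calibration(curve_points(TRUE, x))
        dev = np.abs(eval_calibration(x, fit) - eval_calibration(x, TRUE))
        assert dev.max() < 1e-3

    def test_constant_points_fit_flat(self):
        pts = [CalibrationPoint(x, 0.3, 50) for x in np.linspace(-1, 1, 20)]
        fit = fit_calibration(pts)
        grid = np.linspace(-1, 1, 100)
        assert np.abs(eval_calibration(grid, fit) - 0.3).max() < 1e-6

    def test_recovers_curve_under_noise(self):
        rng = np.random.default_rng(2)
        x = np.linspace(-1, 1, 40)
        pts = [
            CalibrationPoint(float(xi), float(eval_calibration(xi, TRUE) + rng.normal(0, 0.02)), 100)
            for xi in x
        ]
        fit = fit_calibration(pts)
        dev = np.abs(eval_calibration(x, fit) - eval_calibration(x, TRUE))
        assert dev.max() < 0.05

    def test_deterministic(self):
        x = np.linspace(-1, 1, 30)
        pts = curve_points(TRUE, x)
        a = fit_calibration(pts)
        b = fit_calibration(pts)
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_requires_enough_points(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_calibration(curve_points(TRUE, np.linspace(0, 1, 5)))


class TestCalibrateNetwork:
    def make_net(self, scores):
        genes = [f"g{i:03d}" for i in range(len(scores) + 1)]
        return ScoredNetwork.from_pairs(
            [(genes[i], genes[i + 1], s) for i, s in enumerate(scores)]
        )

    def test_monotone_curve_preserves_ranking(self):
        rng = np.random.default_rng(3)
        # scores within [0,1]: the reference curve stays inside [0,1] there,
        # so no clamping ties blur the rank comparison
        net = self.make_net(rng.uniform(0, 1, 50))
        out = calibrate_network(net, TRUE)
        rho = spearmanr(out.table["score"], out.table["probability"]).statistic
        assert rho == pytest.approx(1.0)

    def test_equal_scores_equal_probabilities(self):
        net = self.make_net([0.4] * 10)
        out = calibrate_network(net, TRUE)
        assert out.table["probability"].nunique() == 1

    def test_probabilities_are_clamped_elementwise_eval(self):
        p = CalibrationParams(-0.2, 1.5, 0.0, 1.0, 0.0)  # leaves [0,1] at extremes
        rng = np.random.default_rng(4)
        scores = rng.uniform(-1, 1, 30)
        net = self.make_net(scores)
        with pytest.warns(UserWarning, match="clamped"):
            out = calibrate_network(net, p)
        raw = eval_calibration(out.table["score"].to_numpy(), p)
        np.testing.assert_allclose(
            out.table["probability"], np.clip(raw, 0, 1), atol=1e-12
        )
        assert out.table["probability"].between(0, 1).all()

    def test_non_monotone_curve_warns(self):
        p = CalibrationParams(0.5, 0.0, -0.4, -8.0, 0.0)  # decreasing sigmoid
        net = self.make_net(np.linspace(-1, 1, 20))
        with pytest.warns(UserWarning, match="not monotone"):
            calibrate_network(net, p)

    def test_isotonic_fallback_is_monotone(self):
        rng = np.random.default_rng(5)
        x = np.linspace(-1, 1, 30)
        pts = [
            CalibrationPoint(float(xi), float(np.clip(eval_calibration(xi, TRUE) + rng.normal(0, 0.05), 0, 1)), 50)
            for xi in x
        ]
        net = self.make_net(rng.uniform(-1, 1, 40))
        out = calibrate_network(net, TRUE, points=pts, isotonic=True)
        t = out.table.sort_values("score")
        assert (np.diff(t["probability"]) >= -1e-12).all()
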