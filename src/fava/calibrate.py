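"""Calibration of raw latent-space correlations into posterior probabilities.

The raw PCC score of a pair says how close two genes sit in the latent
space, but its scale depends on the dataset. To make scores interpretable
and comparable across data types, they are calibrated against a pathway
gold standard: local precision ``y = TP/(TP+FP)`` is measured within a
sliding window over the score-ranked pair list, plotted against the mean
score ``x`` in the window, and the five-parameter curve

    y = a0 + a1*x + a2 / (1 + exp(a3*(x - a4)))

is fitted to the window points by least squares with Nelder-Mead simplex
optimization. The fitted curve converts every score into a posterior
probability of same-pathway membership; because the sigmoid component is
monotone the conversion normally preserves the ranking, and the code checks
this explicitly on the observed score range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.optimize
from scipy.special import expit

from .benchmark import EXCLUDED, TP
from .network import ScoredNetwork, canonical_sort

__all__ = [
    "CalibrationPoint",
    "CalibrationParams",
    "window_points",
    "eval_calibration",
    "fit_calibration",
    "calibrate_network",
]


class CalibrationPoint(NamedTuple):
    x: float  # mean raw score within the window
    y: float  # local precision TP/(TP+FP)
    n: int  # window size


@dataclass
class CalibrationParams:
    """Fitted coefficients of the calibration curve plus the fit residual."""

    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    sse: float = np.nan
    converged: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3, self.a4])

    def is_monotone_on(self, lo: float, hi: float, n_grid: int = 512) -> bool:
        """Whether the fitted curve is non-decreasing on [lo, hi]."""
        grid = np.linspace(lo, hi, n_grid)
        y = eval_calibration(grid, self)
        return bool(np.all(np.diff(y) >= -1e-12))


def window_points(
    scores: np.ndarray,
    labels: np.ndarray,
    window: int = 1000,
    step: int = 100,
) -> list[CalibrationPoint]:
    """Sliding-window local precision over a score-ranked TP/FP stream.

    EXCLUDED labels are dropped before windowing. Scores must be sorted
    descending. Window positions start at rank 0 and advance by `step`;
    only full windows are emitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("stream must be sorted by score descending")
    if window < 10:
        raise ValueError("window must be >= 10")
    keep = labels != EXCLUDED
    s = scores[keep]
    is_tp = (labels[keep] == TP).astype(float)
    if len(s) < window:
        raise ValueError(
            f"only {len(s)} evaluable pairs; need at least one window of {window}"
        )
    points = []
    for start in range(0, len(s) - window + 1, step):
        sl = slice(start, start + window)
        points.append(
            CalibrationPoint(float(s[sl].mean()), float(is_tp[sl].mean()), window)
        )
    return points


def eval_calibration(x, p: CalibrationParams):
    """Evaluate a0 + a1*x + a2/(1 + exp(a3*(x - a4))) (no clamping).

    The logistic term is computed with a saturating sigmoid, so extreme
    arguments return exactly 0 or a2 instead of overflowing.
    """
    x = np.asarray(x, dtype=float)
    out = p.a0 + p.a1 * x + p.a2 * expit(-p.a3 * (x - p.a4))
    return float(out) if out.ndim == 0 else out


def _sse(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    p = CalibrationParams(*theta)
    r = y - eval_calibration(x, p)
    return float(r @ r)


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationParams:
    """Least-squares fit of the calibration curve by Nelder-Mead simplex.

    Deterministic: a fixed multi-start grid (a2 in {0.5, 1}, a3 in
    {-20, -5, 5}, a4 at the score quartiles, a0 = min y, a1 = 0) is polished
    with two chained simplex runs each; the start with the lowest SSE wins,
    ties resolved by grid order. The a4 quartile starts matter: with the
    sigmoid midpoint started only at the median, the simplex can stall in a
    local minimum when the precision transition sits off-center.
    """
    if len(points) < 10:
        raise ValueError("need at least 10 window points to fit")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    a4_starts = [float(q) for q in np.quantile(x, [0.25, 0.5, 0.75])]
    a0_0 = float(y.min())

    starts = [
        (a2_0, a3_0, a4_0)
        for a2_0 in (0.5, 1.0)
        for a3_0 in (-20.0, -5.0, 5.0)
        for a4_0 in a4_starts
    ]
    best = None
    best_sse = np.inf
    converged = True
    for a2_0, a3_0, a4_0 in starts:
        theta = np.array([a0_0, 0.0, a2_0, a3_0, a4_0])
        for _ in range(2):  # restarting Nelder-Mead escapes flat simplices
            res = scipy.optimize.minimize(
                _sse,
                theta,
                args=(x, y),
                method="Nelder-Mead",
                options={
                    "maxiter": 10000,
                    "maxfev": 10000,
                    "xatol": 1e-10,
                    "fatol": 1e-12,
                },
            )
            theta = res.x
        if res.fun < best_sse:
            best, best_sse = theta, float(res.fun)
            converged = bool(res.success)
    if not converged:
        warnings.warn("calibration fit did not fully converge; best-so-far returned",
                      stacklevel=2)
    params = CalibrationParams(*best, sse=best_sse, converged=converged)
    fitted = eval_calibration(x, params)
    if fitted.min() < -0.5 or fitted.max() > 1.5:
        warnings.warn(
            "fitted calibration curve leaves the [-0.5, 1.5] sanity band "
            "on the fit domain",
            stacklevel=2,
        )
    return params


def calibrate_network(
    net: ScoredNetwork,
    p: CalibrationParams,
    points: list[CalibrationPoint] | None = None,
    isotonic: bool = False,
) -> ScoredNetwork:
    """Attach posterior probabilities clamp(curve(score), 0, 1) to every pair.

    The conversion preserves the ranking whenever the fitted curve is
    non-decreasing over the observed score range; if it is not, a warning is
    raised (or, with ``isotonic=True`` and the fit's window points supplied,
    the curve is replaced by the isotonic regression of precision on score,
    which is monotone by construction).
    """
    scores = net.table["score"].to_numpy()
    if isotonic:
        if points is None:
            raise ValueError("isotonic calibration needs the fitted window points")
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        iso.fit([pt.x for pt in points], [pt.y for pt in points])
        prob = iso.predict(scores)
    else:
        if not p.is_monotone_on(float(scores.min()), float(scores.max())):
            warnings.warn(
                "fitted calibration curve is not monotone on the observed score "
                "range; probabilities may reorder pairs (consider isotonic=True)",
                stacklevel=2,
            )
        prob = eval_calibration(scores, p)
    n_clamped = int(((prob < 0) | (prob > 1)).sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} probabilities clamped into [0,1]", stacklevel=2)
    table = net.table.copy()
    table["probability"] = np.clip(prob, 0.0, 1.0)
    return ScoredNetwork(canonical_sort(table), list(net.excluded_genes))
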