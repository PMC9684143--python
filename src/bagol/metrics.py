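"""Evaluation metrics: Hungarian-matched Jaccard/RMSE, accuracy curves,
nearest-neighbor distributions and the Hopkins statistic.

The emitter-recovery protocol matches ground-truth and estimated emitter
positions by minimizing the total-distance cost with the Hungarian
algorithm, then discards pairs beyond a precision-based cutoff.  With
TP matched pairs, FP unmatched estimates and FN unmatched truths,
JAC = TP / (TP + FP + FN) and RMSE is the root mean squared pair distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist


@dataclass
class MatchResult:
    """Optimal one-to-one matching between true and estimated emitters."""

    pairs: np.ndarray        # (n_pairs, 2) int: (true index, est index)
    distances: np.ndarray    # (n_pairs,) nm
    n_true: int
    n_est: int
    cost_cutoff: float

    @property
    def n_matched(self):
        return self.pairs.shape[0]


def match_emitters(truth, est_positions, est_precisions=None,
                   cutoff_rule="three_mean_precision", cutoff=None):
    """Hungarian matching of true emitter positions to estimates.

    Parameters
    ----------
    truth : (M, 2) array, nm
    est_positions : (K, 2) array, nm
    est_precisions : (K, 2) or (K,) array, nm
        Grouped precisions of the estimates; required unless an explicit
        ``cutoff`` is given.
    cutoff_rule : {'three_mean_precision', 'three_sigma'}
        'three_mean_precision' keeps pairs with distance no more than three
        times the average returned precision (one global cutoff);
        'three_sigma' keeps a pair if the true position lies within three
        times that estimate's own precision.
    cutoff : float, optional
        Explicit distance cutoff in nm; overrides the rule.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float)) \
        if np.size(truth) else np.empty((0, 2))
    est_positions = np.atleast_2d(np.asarray(est_positions, dtype=float)) \
        if np.size(est_positions) else np.empty((0, 2))
    m, k = truth.shape[0], est_positions.shape[0]
    if m == 0 or k == 0:
        return MatchResult(np.empty((0, 2), dtype=int), np.empty(0), m, k,
                           cost_cutoff=float(cutoff or 0.0))

    if est_precisions is not None:
        est_precisions = np.asarray(est_precisions, dtype=float)
        if est_precisions.ndim == 1:
            est_precisions = np.column_stack([est_precisions, est_precisions])
        per_est_sigma = est_precisions.mean(axis=1)

    cost = cdist(truth, est_positions)
    rows, cols = linear_sum_assignment(cost)
    d = cost[rows, cols]

    if cutoff is not None:
        keep = d <= cutoff
        cut = float(cutoff)
    elif cutoff_rule == "three_mean_precision":
        if est_precisions is None:
            raise ValueError("cutoff_rule needs est_precisions or explicit cutoff")
        cut = 3.0 * float(per_est_sigma.mean())
        keep = d <= cut
    elif cutoff_rule == "three_sigma":
        if est_precisions is None:
            raise ValueError("cutoff_rule needs est_precisions or explicit cutoff")
        cut = float("nan")
        keep = d <= 3.0 * per_est_sigma[cols]
    else:
        raise ValueError(f"unknown cutoff rule {cutoff_rule!r}")

    pairs = np.column_stack([rows[keep], cols[keep]])
    return MatchResult(pairs, d[keep], m, k, cost_cutoff=cut)


def jaccard(match):
    """TP / (TP + FP + FN); two empty sets match vacuously (JAC = 1)."""
    tp = match.n_matched
    fp = match.n_est - tp
    fn = match.n_true - tp
    if tp + fp + fn == 0:
        return 1.0
    return tp / (tp + fp + fn)


def rmse(match):
    """Root mean squared Euclidean distance over matched pairs (nm).

    Returns NaN when no pairs matched.
    """
    if match.n_matched == 0:
        return float("nan")
    return float(np.sqrt(np.mean(match.distances ** 2)))


def accuracy_distribution(distances, sigma, bins=30):
    """Empirical accuracy histogram and the Rayleigh prediction.

    The radial error of an isotropic 2-D Gaussian position estimate with
    standard deviation sigma follows f(r) = r / sigma^2 exp(-r^2 / 2 sigma^2)
    (peak at r = sigma).  The prediction is scaled to have the same area as
    the histogram over the displayed range.

    Returns
    -------
    (hist, bin_edges, predicted)
        ``predicted`` is evaluated at bin centers.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    distances = np.asarray(distances, dtype=float)
    hist, edges = np.histogram(distances, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    f = centers / sigma ** 2 * np.exp(-centers ** 2 / (2.0 * sigma ** 2))
    width = np.diff(edges)
    area_hist = float((hist * width).sum())
    area_f = float((f * width).sum())
    scale = area_hist / area_f if area_f > 0 else 0.0
    return hist, edges, f * scale


def rayleigh_pdf(r, sigma):
    """f(r) = r/sigma^2 exp(-r^2 / 2 sigma^2), the radial accuracy law."""
    r = np.asarray(r, dtype=float)
    return r / sigma ** 2 * np.exp(-r ** 2 / (2.0 * sigma ** 2))


def nnd_distribution(points):
    """First-nearest-neighbor distance of every point (self excluded)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def hopkins(points, m=None, iters=1000, rng=None):
    """Hopkins statistic samples for spatial randomness of a point pattern.

    Each iteration samples ``m`` real points and ``m`` uniform random
    locations inside the data bounding box; with u the nearest-data
    distances from the random locations and w the nearest-other-point
    distances from the sampled points,

        H = sum(u^2) / (sum(u^2) + sum(w^2))

    (squared distances; d = 2 dimensions).  Under complete spatial
    randomness H ~ Beta(m, m), so values near 0.5 indicate random data,
    near 1 clustered data, and near 0 regular spacing.

    Returns an array of ``iters`` draws of H.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if m is None:
        m = max(1, min(n - 1, n // 10))
    if m >= n:
        raise ValueError("m must be smaller than the number of points")
    rng = np.random.default_rng(rng)
    x0, y0 = points.min(axis=0)
    x1, y1 = points.max(axis=0)
    tree = cKDTree(points)
    out = np.empty(iters)
    for it in range(iters):
        probes = np.column_stack([rng.uniform(x0, x1, m),
                                  rng.uniform(y0, y1, m)])
        u, _ = tree.query(probes, k=1)
        idx = rng.choice(n, size=m, replace=False)
        w, _ = tree.query(points[idx], k=2)
        w = w[:, 1]
        su, sw = float(np.sum(u ** 2)), float(np.sum(w ** 2))
        out[it] = su / (su + sw) if su + sw > 0 else 0.5
    return out
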