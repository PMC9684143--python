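"""Pre-analysis cleanup of localization lists.

Three optional stages run before the sampler:

* an intensity filter removing implausibly bright localizations (typically
  double fits of two nearby emitters reported as one high-precision point);
* the NND filter, which counts for every localization the number of
  neighbors within three times the median precision (the statistic ``psi``)
  and removes localizations on the sparse side of the valley of the psi
  histogram.  Suitable for DNA-PAINT only, where every true emitter
  produces many localizations; a dSTORM emitter can blink exactly once and
  would be removed wholesale.
* a simple frame-connection step merging localizations of the same binding
  event across consecutive frames by inverse-variance weighting (plumbing;
  off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data import ConfigurationError, LocalizationSet

logger = logging.getLogger(__name__)


def intensity_filter(locs, mode="relative", factor=2.0, cutoff=None):
    """Remove localizations with implausibly high photon counts.

    mode='relative' removes records with photons > factor * mean(photons);
    mode='absolute' removes records with photons > cutoff.

    Returns
    -------
    (LocalizationSet, int)
        The filtered copy and the number of removed records.
    """
    if locs.photons is None:
        raise ConfigurationError("intensity filter requires a photons column")
    if mode == "relative":
        if factor is None or factor <= 0:
            raise ValueError("relative mode requires factor > 0")
        limit = factor * locs.photons.mean()
    elif mode == "absolute":
        if cutoff is None or cutoff <= 0:
            raise ValueError("absolute mode requires cutoff > 0")
        limit = cutoff
    else:
        raise ConfigurationError(f"unknown intensity filter mode {mode!r}")
    keep = locs.photons <= limit
    removed = int((~keep).sum())
    return locs.select(keep), removed


@dataclass
class NNDFilterReport:
    """Audit record of the NND outlier filter.

    psi[i] is the number of *other* localizations within ``radius`` of
    localization i, where radius = 3 x median of all per-axis precisions.
    """

    psi: np.ndarray
    radius: float
    threshold: int = None
    kept_mask: np.ndarray = None


def compute_psi(locs):
    """Per-localization neighbor counts within 3x the median precision."""
    if len(locs) < 1:
        raise ValueError("need at least one localization")
    radius = 3.0 * np.median(np.concatenate([locs.sigma_x, locs.sigma_y]))
    tree = cKDTree(locs.positions)
    counts = tree.query_ball_point(locs.positions, r=radius, return_length=True)
    psi = np.asarray(counts, dtype=np.int64) - 1  # exclude self
    return NNDFilterReport(psi=psi, radius=float(radius))


def _local_maxima(h):
    """Indices of interior/boundary local maxima of a 1-D array."""
    idx = []
    n = h.size
    for i in range(n):
        left = h[i - 1] if i > 0 else -np.inf
        right = h[i + 1] if i < n - 1 else -np.inf
        if h[i] >= left and h[i] >= right and (h[i] > left or h[i] > right):
            idx.append(i)
    return idx


def find_valley_threshold(psi):
    """Locate the valley between the two leading modes of the psi histogram.

    The integer-binned histogram is smoothed with a 3-bin moving average;
    the threshold is the location of the minimum between the first two local
    maxima.  A unimodal histogram yields threshold 0 (filter disabled, with
    a warning).
    """
    psi = np.asarray(psi)
    if psi.size == 0:
        raise ValueError("psi must be non-empty")
    hist = np.bincount(psi)
    if hist.size < 3:
        logger.warning("psi histogram too narrow for valley detection; "
                       "NND filter disabled")
        return 0
    smooth = np.convolve(hist.astype(float), np.ones(3) / 3.0, mode="same")
    maxima = _local_maxima(smooth)
    if len(maxima) < 2:
        logger.warning("no interior valley in psi histogram; NND filter disabled")
        return 0
    m1, m2 = maxima[0], maxima[1]
    valley = m1 + int(np.argmin(smooth[m1:m2 + 1]))
    return int(valley)


def nnd_filter(locs, threshold_override=None):
    """Remove localizations with fewer neighbors than the valley threshold.

    Returns the filtered set and an :class:`NNDFilterReport` for audit.
    Must not be applied to dSTORM data (enforced at the pipeline level).
    """
    report = compute_psi(locs)
    if threshold_override is not None:
        threshold = int(threshold_override)
    else:
        threshold = find_valley_threshold(report.psi)
    kept = report.psi >= threshold
    report.threshold = threshold
    report.kept_mask = kept
    if not kept.any():
        logger.warning("NND filter removed every localization "
                       "(threshold=%d)", threshold)
    return locs.select(kept), report


def frame_connect(locs, max_gap=1, max_dist_sigma=4.0, drop_singletons=False):
    """Merge localizations of one binding event across consecutive frames.

    Localizations no more than ``max_gap`` frames apart and within
    ``max_dist_sigma`` combined precisions of a running cluster are fused by
    inverse-variance weighting: x' = sum(x_i/s_i^2)/sum(1/s_i^2) and
    1/s'^2 = sum 1/s_i^2 per axis.  The merged record keeps the first frame
    and the summed photon count.  This is deliberately simple connection
    plumbing and is off by default in the pipeline.
    """
    order = np.argsort(locs.frame, kind="stable")
    xs, ys = locs.x[order], locs.y[order]
    wx = 1.0 / locs.sigma_x[order] ** 2
    wy = 1.0 / locs.sigma_y[order] ** 2
    frames = locs.frame[order]
    phot = locs.photons[order] if locs.photons is not None else None

    # open clusters: accumulators of weighted sums
    open_clusters = []  # dicts
    done = []

    def close(c):
        done.append(c)

    for i in range(len(xs)):
        f = frames[i]
        # retire clusters out of reach
        still = []
        for c in open_clusters:
            if f - c["last_frame"] > max_gap:
                close(c)
            else:
                still.append(c)
        open_clusters = still

        best = None
        best_d = np.inf
        for c in open_clusters:
            cx = c["swx_x"] / c["swx"]
            cy = c["swy_y"] / c["swy"]
            d = np.hypot(xs[i] - cx, ys[i] - cy)
            combined = np.sqrt(1.0 / c["swx"] + 1.0 / wx[i]
                               + 1.0 / c["swy"] + 1.0 / wy[i]) / np.sqrt(2.0)
            if d <= max_dist_sigma * combined and d < best_d:
                best, best_d = c, d
        if best is None:
            open_clusters.append({
                "swx": wx[i], "swy": wy[i],
                "swx_x": wx[i] * xs[i], "swy_y": wy[i] * ys[i],
                "first_frame": f, "last_frame": f, "n": 1,
                "photons": (phot[i] if phot is not None else 0.0),
            })
        else:
            best["swx"] += wx[i]
            best["swy"] += wy[i]
            best["swx_x"] += wx[i] * xs[i]
            best["swy_y"] += wy[i] * ys[i]
            best["last_frame"] = f
            best["n"] += 1
            if phot is not None:
                best["photons"] += phot[i]
    for c in open_clusters:
        close(c)

    if drop_singletons:
        done = [c for c in done if c["n"] > 1]
    if not done:
        return locs.select(np.zeros(len(locs), dtype=bool))
    out_x = np.array([c["swx_x"] / c["swx"] for c in done])
    out_y = np.array([c["swy_y"] / c["swy"] for c in done])
    out_sx = np.array([np.sqrt(1.0 / c["swx"]) for c in done])
    out_sy = np.array([np.sqrt(1.0 / c["swy"]) for c in done])
    out_f = np.array([c["first_frame"] for c in done], dtype=np.int64)
    out_p = (np.array([c["photons"] for c in done])
             if locs.photons is not None else None)
    return LocalizationSet(out_x, out_y, out_sx, out_sy, out_f, out_p)
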