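"""Chain post-processing: posterior images, MAPN coordinates, tiling/stitching.

Large fields are split into a grid of subregions so every chain stays
small; each subregion is extended by an overlap margin so emitters near an
edge see their full neighborhood, and after sampling only emitters whose
estimates fall inside the half-open core area of their own box are kept,
so each emitter is reported exactly once.

Two summaries are produced per chain: the *posterior image* (a 2-D
histogram of every emitter position in every sample, a model-averaged
reconstruction whose total mass equals the mean K) and the *MAPN* result —
the maximum a posteriori number of emitters (modal K of the chain, ties
broken toward fewer emitters) with coordinates and grouped precisions
obtained by k-means clustering of the emitter positions pooled from the
modal-K samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .data import LocalizationSet, RenderSpec

logger = logging.getLogger(__name__)

SOFT_MAX_LOCS_PER_BOX = 5000


@dataclass
class MAPNResult:
    """Most-probable-model emitters with grouped precisions."""

    positions: np.ndarray        # (K_map, 2) nm
    precisions: np.ndarray       # (K_map, 2) nm, per-axis
    drifts: np.ndarray = None    # (K_map, 2) nm per acquisition, optional
    n_loc: np.ndarray = None     # (K_map,) mean localizations per emitter
    n_loc_mean: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.precisions = np.asarray(self.precisions, dtype=float).reshape(-1, 2)

    @property
    def K_map(self):
        return self.positions.shape[0]

    def to_dataframe(self):
        import pandas as pd

        d = {"x": self.positions[:, 0], "y": self.positions[:, 1],
             "sx": self.precisions[:, 0], "sy": self.precisions[:, 1]}
        if self.drifts is not None:
            d["drift_x"] = self.drifts[:, 0]
            d["drift_y"] = self.drifts[:, 1]
        d["n_loc"] = (self.n_loc if self.n_loc is not None
                      else np.full(self.K_map, np.nan))
        return pd.DataFrame(d)

    @staticmethod
    def empty():
        return MAPNResult(np.empty((0, 2)), np.empty((0, 2)),
                          drifts=np.empty((0, 2)), n_loc=np.empty(0))

    def as_localizations(self):
        """Treat MAPN emitters as a localization set (for re-grouping)."""
        return LocalizationSet(self.positions[:, 0], self.positions[:, 1],
                               self.precisions[:, 0], self.precisions[:, 1])


@dataclass
class TilingPlan:
    """Grid of analysis subregions with overlap margins.

    cores are half-open boxes [x0, x1) x [y0, y1) partitioning the field;
    boxes are the cores extended by the overlap on every side.  Each
    localization is assigned to every box containing it.
    """

    cores: list              # list of (x0, x1, y0, y1)
    boxes: list              # extended bounds, same order
    overlap: float
    assignments: list        # per box: int index array into the LocalizationSet

    @property
    def n_boxes(self):
        return len(self.cores)


def make_tiling(locs, subregion_size, overlap=None, extent=None):
    """Plan the subregion grid for a localization set.

    The default overlap is twice the median localization precision, capped
    at 45% of the subregion size so cores never vanish.

    ``extent`` (xmin, xmax, ymin, ymax) bounds the tiled field — normally
    the imaged field of view.  Localizations outside all extended boxes
    (e.g. rare very-low-photon events thrown far outside the field) are
    simply not analyzed.  Default: the data bounding box.
    """
    if len(locs) == 0:
        raise ValueError("cannot tile an empty localization set")
    if overlap is None:
        med = float(np.median(np.concatenate([locs.sigma_x, locs.sigma_y])))
        overlap = min(2.0 * med, 0.45 * subregion_size)
    if subregion_size <= 2 * overlap:
        raise ValueError("subregion_size must exceed twice the overlap")
    if extent is not None:
        x0, x1, y0, y1 = extent  # treated as half-open [x0, x1) x [y0, y1)
    else:
        x0, x1, y0, y1 = locs.bounding_box()
        # nudge so max-coordinate points fall inside the last half-open core
        eps = 1e-9 * max(1.0, abs(x1), abs(y1))
        x1 += eps
        y1 += eps
    nx = max(1, int(np.ceil((x1 - x0) / subregion_size - 1e-12)))
    ny = max(1, int(np.ceil((y1 - y0) / subregion_size - 1e-12)))
    cores, boxes, assignments = [], [], []
    for iy in range(ny):
        for ix in range(nx):
            cx0 = x0 + ix * subregion_size
            cy0 = y0 + iy * subregion_size
            cx1 = cx0 + subregion_size
            cy1 = cy0 + subregion_size
            bx0, bx1 = cx0 - overlap, cx1 + overlap
            by0, by1 = cy0 - overlap, cy1 + overlap
            inside = ((locs.x >= bx0) & (locs.x < bx1)
                      & (locs.y >= by0) & (locs.y < by1))
            idx = np.flatnonzero(inside)
            cores.append((cx0, cx1, cy0, cy1))
            boxes.append((bx0, bx1, by0, by1))
            assignments.append(idx)
            if idx.size > SOFT_MAX_LOCS_PER_BOX:
                logger.warning(
                    "subregion %d holds %d localizations; consider a smaller "
                    "subregion_size", len(cores) - 1, idx.size)
    return TilingPlan(cores=cores, boxes=boxes, overlap=float(overlap),
                      assignments=assignments)


def posterior_image(chain, spec):
    """Model-averaged emitter-position histogram on a pixel grid.

    Every emitter position of every post-burn-in sample is binned and the
    image is normalized by the chain length, so the total mass (for
    positions inside the extent) is the posterior mean emitter count.
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    pos = chain.all_positions()
    h, _, _ = np.histogram2d(pos[:, 1], pos[:, 0],
                             bins=[spec.y_edges(), spec.x_edges()])
    return (h / len(chain)).astype(np.float32)


def mapn_extract(chain, max_pool_samples=1500, random_state=None):
    """MAPN emitters from a chain via k-means on the modal-K samples.

    K_map is the modal emitter count (ties toward fewer).  Emitter
    positions pooled from (up to ``max_pool_samples`` evenly thinned)
    modal-K samples are clustered with k-means (k = K_map, best of 10
    seeded restarts); cluster means are the MAPN coordinates and per-axis
    member standard deviations the grouped precisions.  Cluster-mean drift
    vectors and allocation counts ride along.
    """
    k_map = chain.modal_K()
    if k_map == 0:
        return MAPNResult.empty()
    seed = (chain.config.rng_seed if random_state is None else random_state)
    pos, drifts, counts, sample_idx = chain.emitter_samples(K=k_map)
    uniq = np.unique(sample_idx)
    if uniq.size > max_pool_samples:
        keep_samples = uniq[np.linspace(0, uniq.size - 1, max_pool_samples)
                            .astype(int)]
        mask = np.isin(sample_idx, keep_samples)
        pos, drifts, counts = pos[mask], drifts[mask], counts[mask]
    if pos.shape[0] < k_map:  # degenerate; should not happen
        return MAPNResult.empty()
    km = KMeans(n_clusters=k_map, n_init=10, random_state=seed % (2 ** 31))
    labels = km.fit_predict(pos)
    centers = km.cluster_centers_
    prec = np.zeros((k_map, 2))
    dr = np.zeros((k_map, 2))
    nl = np.zeros(k_map)
    for k in range(k_map):
        members = labels == k
        m = int(members.sum())
        if m == 0:
            prec[k] = np.nan
            continue
        if m > 1:
            prec[k] = pos[members].std(axis=0, ddof=1)
        else:
            prec[k] = pos[members].std(axis=0)
        prec[k] = np.maximum(prec[k], 1e-6)  # strictly positive by contract
        dr[k] = drifts[members].mean(axis=0)
        nl[k] = counts[members].mean()
    return MAPNResult(positions=centers, precisions=prec, drifts=dr,
                      n_loc=nl, n_loc_mean=float(nl.mean()))


def _in_core(points, core):
    x0, x1, y0, y1 = core
    return ((points[:, 0] >= x0) & (points[:, 0] < x1)
            & (points[:, 1] >= y0) & (points[:, 1] < y1))


def stitch(results, plan, chains=None, image_spec=None):
    """Combine per-box MAPN results (and optionally posterior images).

    Emitters whose positions fall outside their own box's half-open core
    are dropped (they belong to a neighboring box), the rest concatenated.
    When ``chains`` and ``image_spec`` are given, a global posterior image
    is mosaicked by binning each chain's emitter positions restricted to
    that box's core.

    Returns (MAPNResult, image or None).
    """
    if len(results) != plan.n_boxes:
        raise ValueError("need exactly one result per box")
    pos, prec, dr, nl = [], [], [], []
    for res, core in zip(results, plan.cores):
        if res.K_map == 0:
            continue
        keep = _in_core(res.positions, core)
        if not keep.any():
            continue
        pos.append(res.positions[keep])
        prec.append(res.precisions[keep])
        dr.append(res.drifts[keep] if res.drifts is not None
                  else np.zeros((int(keep.sum()), 2)))
        nl.append(res.n_loc[keep] if res.n_loc is not None
                  else np.full(int(keep.sum()), np.nan))
    if pos:
        merged = MAPNResult(np.vstack(pos), np.vstack(prec),
                            drifts=np.vstack(dr), n_loc=np.concatenate(nl))
        merged.n_loc_mean = float(np.nanmean(merged.n_loc))
    else:
        merged = MAPNResult.empty()

    image = None
    if chains is not None and image_spec is not None:
        image = np.zeros(image_spec.shape, dtype=np.float64)
        for chain, core in zip(chains, plan.cores):
            if len(chain) == 0 or chain.n_data == 0:
                continue
            p = chain.all_positions()
            p = p[_in_core(p, core)]
            if p.size == 0:
                continue
            h, _, _ = np.histogram2d(p[:, 1], p[:, 0],
                                     bins=[image_spec.y_edges(),
                                           image_spec.x_edges()])
            image += h / len(chain)
        image = image.astype(np.float32)
    return merged, image
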