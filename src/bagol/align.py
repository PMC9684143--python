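"""Monte-Carlo rigid alignment of recovered structures to a template.

Used for particle averaging of repeated structures (DNA origami and the
like): every MAPN structure is rigidly aligned to a template by a random
rotation/translation search minimizing the sum of capped nearest-neighbor
distances, malformed copies are rejected, and the pooled aligned emitter
coordinates (treated as localizations, with their grouped precisions)
are re-grouped by the sampler into a consensus structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class RigidTransform:
    """Rotation (about the template center of mass) plus translation."""

    rotation: float           # radians
    translation: np.ndarray   # (2,) nm
    score: float = np.nan     # sum of capped NN distances, nm
    pivot: np.ndarray = None  # rotation center

    def apply(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        pivot = self.pivot if self.pivot is not None else np.zeros(2)
        return (points - pivot) @ R.T + pivot + self.translation

    def inverse(self):
        # inverse of x -> R(x - p) + p + t is the same form with rotation
        # -theta, pivot p and translation -R^T t
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        Rt = np.array([[c, s], [-s, c]])
        return RigidTransform(-self.rotation, -(Rt @ self.translation),
                              pivot=self.pivot)


def _score(points, tree, cutoff):
    d, _ = tree.query(points, k=1)
    return float(np.minimum(d, cutoff).sum())


def align_to_template(structure, template, cutoff=6.0, rng=None,
                      n_steps=3000, coarse_jumps=(1.0, 0.5),
                      fine_jumps=(0.1, 0.05), allow_reflection=False):
    """Rigidly align a structure to a template by Monte-Carlo minimization.

    The structure is first shifted so its center of mass matches the
    template's, then rotated/translated by random jumps for ``n_steps``
    steps (greedy: a proposal is kept only if it lowers the score).  The
    score is the sum over structure points of the distance to the nearest
    template point, capped at ``cutoff`` nm so stray points cannot
    dominate.  The first half of the chain uses coarse jump sizes
    (1 radian, 0.5 nm), the second half fine ones (0.1 radian, 0.05 nm),
    and the best transform seen in the second half is returned.

    Returns (RigidTransform, aligned positions).
    """
    structure = np.atleast_2d(np.asarray(structure, dtype=float))
    template = np.atleast_2d(np.asarray(template, dtype=float))
    if structure.shape[0] < 2 or template.shape[0] < 2:
        raise ValueError("need at least two points in structure and template")
    if np.allclose(structure.std(axis=0), 0):
        raise ValueError("degenerate structure: all points coincide")
    rng = np.random.default_rng(rng)
    pivot = template.mean(axis=0)
    shift0 = pivot - structure.mean(axis=0)
    tree = cKDTree(template)

    reflections = (1.0, -1.0) if allow_reflection else (1.0,)
    best_overall = None
    for refl in reflections:
        pts0 = structure.copy()
        if refl < 0:
            pts0[:, 0] = 2 * structure[:, 0].mean() - pts0[:, 0]
        theta = 0.0
        trans = shift0.copy()
        cur = RigidTransform(theta, trans.copy(), pivot=pivot)
        cur_score = _score(cur.apply(pts0), tree, cutoff)
        best = RigidTransform(theta, trans.copy(), score=cur_score, pivot=pivot)
        for step in range(n_steps):
            rot_j, tr_j = coarse_jumps if step < n_steps // 2 else fine_jumps
            cand = RigidTransform(
                theta + rng.normal(0.0, rot_j),
                trans + rng.normal(0.0, tr_j, size=2),
                pivot=pivot)
            s = _score(cand.apply(pts0), tree, cutoff)
            if s < cur_score:
                theta, trans = cand.rotation, cand.translation
                cur_score = s
            if step >= n_steps // 2 and cur_score < best.score:
                best = RigidTransform(theta, trans.copy(), score=cur_score,
                                      pivot=pivot)
        if best_overall is None or best.score < best_overall[0].score:
            best_overall = (best, pts0)
    best, pts0 = best_overall
    return best, best.apply(pts0)


def filter_malformed(aligned_structures, template, max_sum_nnd=6.0):
    """Keep aligned structures whose summed NN distance to the template
    does not exceed ``max_sum_nnd`` (nm).

    Returns (kept structures, boolean keep mask).
    """
    template = np.atleast_2d(np.asarray(template, dtype=float))
    tree = cKDTree(template)
    kept, mask = [], []
    for s in aligned_structures:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        d, _ = tree.query(s, k=1)
        ok = float(d.sum()) <= max_sum_nnd
        mask.append(ok)
        if ok:
            kept.append(s)
    return kept, np.asarray(mask, dtype=bool)


def regroup_pooled(positions, precisions, lam, n_samples=2000, seed=0,
                   drift=False):
    """Re-group pooled aligned emitter coordinates into a consensus structure.

    The aligned MAPN coordinates and their grouped precisions are treated
    exactly like localizations and run through the sampler with a fixed
    Poisson mean ``lam`` set to the number of pooled structures (each true
    site should collect about one coordinate per aligned copy).

    Returns the consensus MAPNResult.
    """
    from .data import LocalizationSet
    from .model import SamplerConfig
    from .outputs import mapn_extract
    from .sampler import run_chain

    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    precisions = np.atleast_2d(np.asarray(precisions, dtype=float))
    if precisions.shape[1] == 1:
        precisions = np.repeat(precisions, 2, axis=1)
    locs = LocalizationSet(positions[:, 0], positions[:, 1],
                           precisions[:, 0], precisions[:, 1])
    cfg = SamplerConfig(xi=float(lam), xi_mode="fixed", count_model="poisson",
                        n_samples=n_samples, drift_enabled=drift,
                        rng_seed=seed)
    chain = run_chain(locs, cfg)
    return mapn_extract(chain)
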