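"""Chain container and the reversible-jump chain driver.

`run_chain` explores the posterior over (K, mu, a, Z, lambda) for one
localization set (typically one subregion).  Each iteration selects one of
the four jump types with the configured probabilities; in hierarchical
mode a Metropolis step on lambda is interleaved every ``xi_stride``
iterations.  The chain is initialized from k-means with
K0 = max(1, round(N / lambda_init)) cluster centers and is fully
reproducible from the config seed.

Two engines run the same model: ``numba`` (fused kernels, production) and
``python`` (the readable step functions in `model.py`, for small problems
and cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.cluster import KMeans

from . import _kernels, model as _m
from .data import LocalizationSet

_JUMPS = ("move", "allocate", "birth", "death", "xi")


@dataclass
class Chain:
    """Ordered post-burn-in samples of the reversible-jump chain.

    Per-sample arrays use a fixed-width emitter buffer of ``k_cap`` slots;
    for sample s only the first ``K[s]`` slots are meaningful.
    """

    K: np.ndarray            # (n_samples,)
    mu_x: np.ndarray         # (n_samples, k_cap)
    mu_y: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    counts: np.ndarray       # (n_samples, k_cap) int32
    xi: np.ndarray           # (n_samples,)
    proposed: dict
    accepted: dict
    z_last: np.ndarray
    config: _m.SamplerConfig
    box: tuple
    n_data: int

    def __len__(self):
        return self.K.size

    @property
    def mean_K(self):
        return float(self.K.mean()) if len(self) else 0.0

    def occupied_K(self):
        """Per-sample count of *occupied* emitters (>= 1 allocation).

        The sampler may transiently carry emitters with no allocated
        localizations (cheap under heavy-tailed count priors); summaries of
        the inferred structure count occupied emitters only.
        """
        if len(self) == 0:
            return np.zeros(0, dtype=np.int64)
        occ = np.zeros(len(self), dtype=np.int64)
        for s in range(len(self)):
            occ[s] = int((self.counts[s, :self.K[s]] > 0).sum())
        return occ

    def modal_K(self, occupied=True):
        """Most frequent emitter count; ties broken toward the smaller K.

        With ``occupied=True`` (default, used by MAPN extraction) emitters
        without allocations are not counted; ``occupied=False`` gives the
        raw model dimension.
        """
        if len(self) == 0:
            return 0
        ks = self.occupied_K() if occupied else self.K
        vals, freq = np.unique(ks, return_counts=True)
        return int(vals[np.argmax(freq)])  # np.unique sorts, argmax takes first

    def acceptance_rate(self, jump):
        p = self.proposed.get(jump, 0)
        return self.accepted.get(jump, 0) / p if p else float("nan")

    def emitter_samples(self, K=None, occupied=True):
        """Pooled emitter draws, optionally restricted to samples with a given K.

        With ``occupied=True`` only emitters holding at least one
        localization are returned, and ``K`` refers to the occupied count.

        Returns (positions (M, 2), drifts (M, 2), counts (M,), sample_index (M,)).
        """
        ks = self.occupied_K() if occupied else self.K
        sel = np.ones(len(self), dtype=bool) if K is None else ks == K
        idx = np.flatnonzero(sel)
        pos, dr, cnt, smp = [], [], [], []
        for s in idx:
            k = self.K[s]
            if k == 0:
                continue
            live = (self.counts[s, :k] > 0) if occupied \
                else np.ones(k, dtype=bool)
            if not live.any():
                continue
            pos.append(np.column_stack([self.mu_x[s, :k][live],
                                        self.mu_y[s, :k][live]]))
            dr.append(np.column_stack([self.a_x[s, :k][live],
                                       self.a_y[s, :k][live]]))
            cnt.append(self.counts[s, :k][live])
            smp.append(np.full(int(live.sum()), s))
        if not pos:
            return (np.empty((0, 2)), np.empty((0, 2)), np.empty(0, dtype=int),
                    np.empty(0, dtype=int))
        return (np.vstack(pos), np.vstack(dr),
                np.concatenate(cnt).astype(int), np.concatenate(smp))

    def all_positions(self):
        """All occupied-emitter positions from all samples (posterior images)."""
        return self.emitter_samples(K=None)[0]

    def state(self, s):
        """Reconstruct sample s as a :class:`ModelState` (no Z except last)."""
        k = self.K[s]
        z = self.z_last if s == len(self) - 1 else np.zeros(0, dtype=np.int64)
        return _m.ModelState(
            np.column_stack([self.mu_x[s, :k], self.mu_y[s, :k]]),
            np.column_stack([self.a_x[s, :k], self.a_y[s, :k]]),
            z, float(self.xi[s]))

    # -- serialization -----------------------------------------------------
    def to_hdf5(self, path):
        with h5py.File(path, "w") as f:
            g = f.create_group("chain")
            for name in ("K", "mu_x", "mu_y", "a_x", "a_y", "counts", "xi",
                         "z_last"):
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["box"] = np.asarray(self.box)
            g.attrs["n_data"] = self.n_data
            g.attrs["proposed"] = [self.proposed[j] for j in _JUMPS]
            g.attrs["accepted"] = [self.accepted[j] for j in _JUMPS]
        return path

    @staticmethod
    def from_hdf5(path, config=None):
        with h5py.File(path, "r") as f:
            g = f["chain"]
            data = {name: np.asarray(g[name])
                    for name in ("K", "mu_x", "mu_y", "a_x", "a_y", "counts",
                                 "xi", "z_last")}
            box = tuple(g.attrs["box"])
            n_data = int(g.attrs["n_data"])
            proposed = dict(zip(_JUMPS, (int(v) for v in g.attrs["proposed"])))
            accepted = dict(zip(_JUMPS, (int(v) for v in g.attrs["accepted"])))
        return Chain(config=config or _m.SamplerConfig(), box=box,
                     n_data=n_data, proposed=proposed, accepted=accepted,
                     **data)


def _empty_chain(config, box):
    n = config.n_samples
    zeros = np.zeros((n, 1))
    return Chain(K=np.zeros(n, dtype=np.int64), mu_x=zeros, mu_y=zeros.copy(),
                 a_x=zeros.copy(), a_y=zeros.copy(),
                 counts=np.zeros((n, 1), dtype=np.int32), xi=np.full(n, config.xi),
                 proposed={j: 0 for j in _JUMPS}, accepted={j: 0 for j in _JUMPS},
                 z_last=np.zeros(0, dtype=np.int64), config=config, box=box,
                 n_data=0)


def initial_positions(locs, k0, seed):
    """k-means initialization of emitter positions on the localization cloud."""
    k0 = min(k0, len(locs))
    if k0 <= 1:
        return locs.positions.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k0, n_init=1, random_state=seed % (2 ** 31))
    km.fit(locs.positions)
    return km.cluster_centers_


def run_chain(locs, config, box=None, engine="numba", init_positions=None):
    """Sample the grouping posterior for one localization set.

    Parameters
    ----------
    locs : LocalizationSet
    config : SamplerConfig
    box : (xmin, xmax, ymin, ymax) or None
        Support of the flat emitter-position prior; defaults to the data
        bounding box padded by three median precisions.
    engine : {'numba', 'python'}
    init_positions : (K0, 2) array, optional
        Explicit initial emitter positions (otherwise k-means).
    """
    if box is None:
        if len(locs):
            pad = 3.0 * float(np.median(np.concatenate([locs.sigma_x,
                                                        locs.sigma_y])))
            box = locs.bounding_box(pad=pad)
        else:
            box = (0.0, 1.0, 0.0, 1.0)
    box = tuple(float(v) for v in box)
    if len(locs) == 0:
        return _empty_chain(config, box)

    n = len(locs)
    if init_positions is None:
        k0 = max(1, int(round(n / config.xi)))
        init_positions = initial_positions(locs, k0, config.rng_seed)
    init_positions = np.atleast_2d(np.asarray(init_positions, dtype=float))
    k0 = init_positions.shape[0]
    k_cap = config.k_max or min(max(3 * k0 + 20, 40), n + 20)
    k_cap = max(k_cap, k0 + 1)

    if engine == "numba":
        return _run_numba(locs, config, box, init_positions, k0, k_cap)
    if engine == "python":
        return _run_python(locs, config, box, init_positions, k0, k_cap)
    raise ValueError(f"unknown engine {engine!r}")


def _run_numba(locs, config, box, init_positions, k0, k_cap):
    wx = 1.0 / locs.sigma_x ** 2
    wy = 1.0 / locs.sigma_y ** 2
    t = locs.t_normalized()
    res = _kernels.run_chain_kernel(
        locs.x.astype(np.float64), locs.y.astype(np.float64),
        wx.astype(np.float64), wy.astype(np.float64), t.astype(np.float64),
        box[0], box[1], box[2], box[3],
        int(config.rng_seed) % (2 ** 31),
        int(config.burnin), int(config.n_samples),
        config.p_move, config.p_allocate, config.p_birth, config.p_death,
        0 if config.count_model == "poisson" else 1,
        1 if config.xi_mode == "hierarchical" else 0,
        float(config.xi), float(config.xi_prior_eta),
        float(config.xi_prior_gamma), float(config.xi_proposal_sd),
        int(config.xi_stride),
        config.drift_enabled, float(config.drift_prior_sd),
        np.ascontiguousarray(init_positions[:, 0]),
        np.ascontiguousarray(init_positions[:, 1]),
        int(k0), int(k_cap))
    ks, mu_x, mu_y, a_x, a_y, counts, xis, acc, z_last = res
    proposed = {j: int(acc[i, 0]) for i, j in enumerate(_JUMPS)}
    accepted = {j: int(acc[i, 1]) for i, j in enumerate(_JUMPS)}
    return Chain(K=ks, mu_x=mu_x, mu_y=mu_y, a_x=a_x, a_y=a_y, counts=counts,
                 xi=xis, proposed=proposed, accepted=accepted, z_last=z_last,
                 config=config, box=box, n_data=len(locs))


def _run_python(locs, config, box, init_positions, k0, k_cap):
    rng = np.random.default_rng(config.rng_seed)
    n = len(locs)
    state = _m.ModelState(mu=init_positions.copy(),
                          a=np.zeros((k0, 2)),
                          Z=np.zeros(n, dtype=np.int64),
                          xi=config.xi)
    # nearest-emitter initial allocation
    logf = _m._log_density_matrix(state, locs)
    state.Z = np.argmax(logf, axis=1)

    n_samples = config.n_samples
    ks = np.zeros(n_samples, dtype=np.int64)
    mu_x = np.zeros((n_samples, k_cap))
    mu_y = np.zeros((n_samples, k_cap))
    a_x = np.zeros((n_samples, k_cap))
    a_y = np.zeros((n_samples, k_cap))
    counts = np.zeros((n_samples, k_cap), dtype=np.int32)
    xis = np.zeros(n_samples)
    proposed = {j: 0 for j in _JUMPS}
    accepted = {j: 0 for j in _JUMPS}

    cfg = config
    if cfg.k_max is None:
        from dataclasses import replace
        cfg = replace(cfg, k_max=k_cap)
    total = cfg.burnin + n_samples
    for it in range(total):
        u = rng.uniform()
        if u < cfg.p_move:
            proposed["move"] += 1
            accepted["move"] += 1
            state = _m.move_update(state, locs, cfg, box, rng)
        elif u < cfg.p_move + cfg.p_allocate:
            proposed["allocate"] += 1
            state, ok = _m.allocate_update(state, locs, cfg, rng)
            accepted["allocate"] += ok
        elif u < cfg.p_move + cfg.p_allocate + cfg.p_birth:
            proposed["birth"] += 1
            state, ok = _m.birth_update(state, locs, cfg, box, rng)
            accepted["birth"] += ok
        else:
            proposed["death"] += 1
            state, ok = _m.death_update(state, locs, cfg, box, rng)
            accepted["death"] += ok
        if cfg.xi_mode == "hierarchical" and (it + 1) % cfg.xi_stride == 0:
            proposed["xi"] += 1
            state, ok = _m.xi_update(state, cfg, rng)
            accepted["xi"] += ok
        if it >= cfg.burnin:
            s = it - cfg.burnin
            k = state.K
            ks[s] = k
            mu_x[s, :k] = state.mu[:, 0]
            mu_y[s, :k] = state.mu[:, 1]
            a_x[s, :k] = state.a[:, 0]
            a_y[s, :k] = state.a[:, 1]
            counts[s, :k] = state.counts()
            xis[s] = state.xi
    return Chain(K=ks, mu_x=mu_x, mu_y=mu_y, a_x=a_x, a_y=a_y, counts=counts,
                 xi=xis, proposed=proposed, accepted=accepted,
                 z_last=state.Z.copy(), config=config, box=box, n_data=n)
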