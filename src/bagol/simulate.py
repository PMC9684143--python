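"""Synthetic DNA-PAINT and dSTORM localization generators.

Each generator builds a :class:`SimScene` holding ground-truth emitter
positions plus the photophysical parameters of the acquisition, and
:func:`blinks_from_emitters` turns a scene into a localization list:

* DNA-PAINT: the number of binding events per docking strand is Poisson
  with mean ``lam``; every event collects ``I ~ Exponential(mean_photons)``
  photons, yielding a per-axis precision ``sigma = sigma_psf / sqrt(I)``;
  the observed position is a Gaussian draw around the true (possibly
  drifting) emitter position.  Event frames are uniform over the
  acquisition.
* dSTORM: each fluorophore cycles through off/on states with first-order
  kinetics (rates per frame ``k_on``, ``k_off``) until photobleaching
  (``k_b``), simulated exactly with the Gillespie algorithm; each on-period
  contributes one localization with the same photon/precision model.
  The number of blinks per fluorophore is then geometric (support >= 1)
  with mean (k_off + k_b) / k_b.

Defaults follow the synthetic benchmark conditions used throughout:
a 120 nm PSF, 1800 mean photons per event, DNA-PAINT lam = 50, and
dSTORM rates k_on = 2e-4, k_off = 5e-2, k_b = 5e-2 per frame over
100,000 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LocalizationSet


@dataclass
class SimScene:
    """Ground-truth geometry plus kinetic/photophysical parameters."""

    true_positions: np.ndarray       # (K, 2) nm
    geometry: str = "custom"
    lam: float = 50.0                # mean binding events per emitter (PAINT)
    mean_photons: float = 1800.0
    sigma_psf: float = 120.0         # nm
    drift_velocity: float = None     # nm per acquisition (magnitude), optional
    drift_vectors: np.ndarray = None  # (K, 2) explicit per-emitter drifts
    k_on: float = 2e-4               # per frame (dSTORM)
    k_off: float = 5e-2
    k_b: float = 5e-2
    n_frames: int = 10_000
    rng_seed: int = 0
    extent: tuple = None             # (xmin, xmax, ymin, ymax), fields only

    def __post_init__(self):
        self.true_positions = np.atleast_2d(np.asarray(self.true_positions,
                                                       dtype=float))
        if self.lam <= 0 or self.sigma_psf <= 0 or self.mean_photons <= 0:
            raise ValueError("lam, sigma_psf and mean_photons must be positive")
        if min(self.k_on, self.k_off, self.k_b) < 0:
            raise ValueError("kinetic rates must be non-negative")

    @property
    def n_emitters(self):
        return self.true_positions.shape[0]


# ---------------------------------------------------------------------------
# geometries
# ---------------------------------------------------------------------------

def sim_8mer(R, center=(0.0, 0.0), **scene_kw):
    """Eight emitters equally spaced on a circle of radius R (nm).

    The nearest-neighbor spacing is 2 R sin(pi/8) ~ 0.765 R.
    """
    if R <= 0:
        raise ValueError("radius must be positive")
    ang = np.pi / 4.0 * np.arange(8)
    pos = np.column_stack([center[0] + R * np.cos(ang),
                           center[1] + R * np.sin(ang)])
    return SimScene(pos, geometry=f"8mer(R={R})", **scene_kw)


def sim_dimer(d, center=(0.0, 0.0), **scene_kw):
    """Two emitters separated by d nm along x."""
    if d <= 0:
        raise ValueError("separation must be positive")
    pos = np.array([[center[0] - d / 2.0, center[1]],
                    [center[0] + d / 2.0, center[1]]])
    return SimScene(pos, geometry=f"dimer(d={d})", **scene_kw)


def sim_density_field(rho_per_um2, field_size_nm=500.0, rng=None, **scene_kw):
    """Uniform random emitters at areal density rho (emitters per um^2).

    The mean nearest-neighbor separation of such a field is
    <r> = 1 / (2 sqrt(rho)).  The emitter count is the rounded expectation
    rho * area so that the nominal density is met exactly on average.
    """
    if rho_per_um2 <= 0 or field_size_nm <= 0:
        raise ValueError("density and field size must be positive")
    rng = np.random.default_rng(rng)
    rho_nm = rho_per_um2 / 1e6
    n = int(round(rho_nm * field_size_nm ** 2))
    pos = rng.uniform(0.0, field_size_nm, size=(n, 2))
    return SimScene(pos, geometry=f"field(rho={rho_per_um2})",
                    extent=(0.0, field_size_nm, 0.0, field_size_nm), **scene_kw)


def expected_nn_distance(rho_per_um2):
    """Mean nearest-neighbor distance <r> = 1/(2 sqrt(rho)) in nm."""
    return 1.0 / (2.0 * np.sqrt(rho_per_um2 / 1e6))


def sim_line_pair(separation, length=100.0, n_per_line=70, rng=None,
                  **scene_kw):
    """Two parallel lines with emitters at uniform random positions.

    Lines run along y, centered at x = +-separation/2.
    """
    if separation <= 0 or length <= 0:
        raise ValueError("separation and length must be positive")
    rng = np.random.default_rng(rng)
    ys1 = rng.uniform(-length / 2.0, length / 2.0, size=n_per_line)
    ys2 = rng.uniform(-length / 2.0, length / 2.0, size=n_per_line)
    pos = np.vstack([
        np.column_stack([np.full(n_per_line, -separation / 2.0), ys1]),
        np.column_stack([np.full(n_per_line, separation / 2.0), ys2]),
    ])
    return SimScene(pos, geometry=f"lines(sep={separation})", **scene_kw)


def sim_cross(separation, arm_length=100.0, **scene_kw):
    """Two perpendicular lines through a common center, equally spaced emitters.

    Emitters sit every ``separation`` nm along each 100 nm arm; the shared
    center point appears once.
    """
    if separation <= 0 or arm_length <= 0:
        raise ValueError("separation and arm length must be positive")
    s = np.arange(-arm_length / 2.0, arm_length / 2.0 + 1e-9, separation)
    horiz = np.column_stack([s, np.zeros_like(s)])
    vert = np.column_stack([np.zeros_like(s), s])
    pos = np.vstack([horiz, vert])
    # remove the duplicated center
    _, keep = np.unique(np.round(pos, 9), axis=0, return_index=True)
    pos = pos[np.sort(keep)]
    return SimScene(pos, geometry=f"cross(sep={separation})", **scene_kw)


# ---------------------------------------------------------------------------
# photophysics
# ---------------------------------------------------------------------------

def sim_dstorm_kinetics(scene, rng=None):
    """Gillespie simulation of three-state (off/on/bleached) photoswitching.

    Every fluorophore starts in the off state; off->on waiting times are
    Exponential(1/k_on) frames; an on-period ends after
    Exponential(1/(k_off + k_b)) frames and branches to the bleached state
    with probability k_b / (k_off + k_b).  Events after ``n_frames`` are
    discarded.

    Returns
    -------
    list of ndarray
        Per fluorophore, the frame times (float, frames) at which each
        on-period (blink) begins.
    """
    if scene.k_on <= 0 or (scene.k_off + scene.k_b) <= 0:
        raise ValueError("rates must be positive for kinetic simulation")
    rng = np.random.default_rng(rng)
    p_bleach = scene.k_b / (scene.k_off + scene.k_b)
    events = []
    for _ in range(scene.n_emitters):
        t = rng.exponential(1.0 / scene.k_on)
        blinks = []
        while t < scene.n_frames:
            blinks.append(t)
            dwell = rng.exponential(1.0 / (scene.k_off + scene.k_b))
            if rng.random() < p_bleach:
                break
            t += dwell + rng.exponential(1.0 / scene.k_on)
        events.append(np.asarray(blinks))
    return events


def apply_drift(scene, locs, allocation, drift_vectors=None, rng=None):
    """Offset localizations by per-emitter linear drift.

    Each emitter drifts linearly over the acquisition; a localization at
    normalized time t is displaced by ``drift * t``.  Unless explicit
    ``drift_vectors`` are given, each emitter receives an independent vector
    of magnitude ``scene.drift_velocity`` in a uniformly random direction.

    Returns the displaced set and the (K, 2) drift vectors used.
    """
    rng = np.random.default_rng(rng)
    K = scene.n_emitters
    if drift_vectors is None:
        if scene.drift_vectors is not None:
            drift_vectors = np.asarray(scene.drift_vectors, dtype=float)
        else:
            mag = scene.drift_velocity or 0.0
            ang = rng.uniform(0.0, 2 * np.pi, size=K)
            drift_vectors = mag * np.column_stack([np.cos(ang), np.sin(ang)])
    drift_vectors = np.atleast_2d(drift_vectors)
    t = locs.t_normalized()
    dx = drift_vectors[allocation, 0] * t
    dy = drift_vectors[allocation, 1] * t
    out = LocalizationSet(locs.x + dx, locs.y + dy, locs.sigma_x,
                          locs.sigma_y, locs.frame, locs.photons)
    return out, drift_vectors


def blinks_from_emitters(scene, mode="paint", rng=None):
    """Generate a localization list from a scene.

    Parameters
    ----------
    scene : SimScene
    mode : {'paint', 'dstorm'}
        'paint' draws Poisson(lam) binding events per emitter with uniform
        random frames; 'dstorm' draws blink times from the Gillespie
        three-state kinetics.

    Returns
    -------
    (LocalizationSet, ndarray)
        Localizations plus the ground-truth allocation (emitter index of
        each localization).  If the scene specifies drift, positions include
        it and the vectors used are stored on ``scene.drift_vectors``.
    """
    rng = np.random.default_rng(rng if rng is not None else scene.rng_seed)
    K = scene.n_emitters
    if mode == "paint":
        counts = rng.poisson(scene.lam, size=K)
        alloc = np.repeat(np.arange(K), counts)
        frames = rng.integers(0, scene.n_frames, size=alloc.size)
    elif mode == "dstorm":
        events = sim_dstorm_kinetics(scene, rng)
        alloc = np.concatenate([np.full(len(e), k, dtype=np.int64)
                                for k, e in enumerate(events)]) \
            if K else np.empty(0, dtype=np.int64)
        frames = np.concatenate([np.floor(e) for e in events]) \
            if K else np.empty(0)
        frames = frames.astype(np.int64)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = alloc.size
    photons = rng.exponential(scene.mean_photons, size=n)
    photons = np.maximum(photons, 1.0)  # at least one detected photon
    sigma = scene.sigma_psf / np.sqrt(photons)
    true_xy = scene.true_positions[alloc]
    x = true_xy[:, 0] + rng.normal(0.0, sigma)
    y = true_xy[:, 1] + rng.normal(0.0, sigma)
    locs = LocalizationSet(x, y, sigma.copy(), sigma.copy(), frames, photons)
    if scene.drift_velocity is not None or scene.drift_vectors is not None:
        locs, vecs = apply_drift(scene, locs, alloc, rng=rng)
        scene.drift_vectors = vecs
    return locs, alloc
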