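"""Localization data model, file I/O and Gaussian-blob rendering.

The canonical in-memory container is :class:`LocalizationSet`: flat numpy
arrays of positions, per-axis precisions, frame indices and (optionally)
photon counts, all in nanometers / integer frames.  Every downstream stage
(filters, sampler, metrics) consumes this container.  Two on-disk dialects
are supported: a plain CSV with a header row and an HDF5 group of equally
named 1-D datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.special import erf

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = ("x", "y", "sigma_x", "sigma_y", "frame", "photons")


class BagolError(Exception):
    """Base class for package errors."""


class ConfigurationError(BagolError):
    """A user-supplied configuration is inconsistent or incomplete."""


class EmptyInputError(BagolError):
    """An input file or table contains no usable records."""


@dataclass
class LocalizationSet:
    """A set of 2-D localizations with per-axis precisions.

    Parameters
    ----------
    x, y : ndarray, nm
        Localization coordinates.
    sigma_x, sigma_y : ndarray, nm
        Per-axis localization precisions (standard deviations), > 0.
    frame : ndarray of int
        Acquisition frame index of each localization, >= 0.
    photons : ndarray or None
        Detected photon count per localization (optional).
    """

    x: np.ndarray
    y: np.ndarray
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    frame: np.ndarray = None
    photons: np.ndarray = None
    frame_range: tuple = None  # (fmin, fmax) of the parent dataset, if a subset

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma_x = np.asarray(self.sigma_x, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        n = self.x.size
        if self.frame is None:
            self.frame = np.zeros(n, dtype=np.int64)
        else:
            self.frame = np.asarray(self.frame, dtype=np.int64)
        if self.photons is not None:
            self.photons = np.asarray(self.photons, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self):
        n = self.x.size
        arrays = [self.y, self.sigma_x, self.sigma_y, self.frame]
        if self.photons is not None:
            arrays.append(self.photons)
        if any(a.size != n for a in arrays):
            raise ValueError("all localization arrays must have equal length")
        for name in ("x", "y", "sigma_x", "sigma_y"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise ValueError("precisions must be strictly positive")
        if np.any(self.frame < 0):
            raise ValueError("frames must be non-negative")

    def __len__(self):
        return self.x.size

    @property
    def n(self):
        return self.x.size

    @property
    def positions(self):
        """(N, 2) array of coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def sigmas(self):
        """(N, 2) array of per-axis precisions."""
        return np.column_stack([self.sigma_x, self.sigma_y])

    def t_normalized(self):
        """Frames mapped linearly onto [0, 1] over the dataset span.

        A dataset spanning a single frame maps to all zeros.  This is the
        time coordinate consumed by the per-emitter linear drift model, so a
        drift vector expresses total displacement over the acquisition.
        Subsets cut from a larger acquisition (e.g. tiling subregions) keep
        the parent span through ``frame_range`` so drift vectors stay on a
        common time scale.
        """
        f = self.frame.astype(float)
        if self.frame_range is not None:
            f0, f1 = self.frame_range
        elif f.size:
            f0, f1 = f.min(), f.max()
        else:
            return np.zeros(0)
        span = float(f1) - float(f0)
        if span <= 0:
            return np.zeros(f.size)
        return (f - f0) / span

    def select(self, mask_or_index):
        """Return a new set restricted to a boolean mask or index array.

        The parent acquisition's frame span is preserved so normalized
        times stay comparable across subsets.
        """
        ph = None if self.photons is None else self.photons[mask_or_index]
        fr = self.frame_range
        if fr is None and len(self):
            fr = (int(self.frame.min()), int(self.frame.max()))
        return LocalizationSet(
            self.x[mask_or_index], self.y[mask_or_index],
            self.sigma_x[mask_or_index], self.sigma_y[mask_or_index],
            self.frame[mask_or_index], ph, frame_range=fr,
        )

    def bounding_box(self, pad=0.0):
        """(xmin, xmax, ymin, ymax), optionally padded on all sides."""
        return (self.x.min() - pad, self.x.max() + pad,
                self.y.min() - pad, self.y.max() + pad)

    def to_dataframe(self):
        d = {"x": self.x, "y": self.y, "sigma_x": self.sigma_x,
             "sigma_y": self.sigma_y, "frame": self.frame}
        if self.photons is not None:
            d["photons"] = self.photons
        return pd.DataFrame(d)

    @staticmethod
    def from_arrays(x, y, sigma_x, sigma_y, frame=None, photons=None,
                    drop_invalid=True):
        """Build a set, optionally dropping rows that violate invariants.

        Rows with non-finite coordinates/precisions or non-positive
        precisions are removed (with a logged count) rather than raising.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sigma_x = np.asarray(sigma_x, dtype=float)
        sigma_y = np.asarray(sigma_y, dtype=float)
        if frame is None:
            frame = np.zeros(x.size)
        frame = np.asarray(frame, dtype=float)
        if photons is not None:
            photons = np.asarray(photons, dtype=float)
        if drop_invalid:
            ok = (np.isfinite(x) & np.isfinite(y)
                  & np.isfinite(sigma_x) & np.isfinite(sigma_y)
                  & (sigma_x > 0) & (sigma_y > 0)
                  & np.isfinite(frame) & (frame >= 0))
            if photons is not None:
                ok &= np.isfinite(photons)
            n_bad = int((~ok).sum())
            if n_bad:
                logger.warning("dropped %d invalid localization record(s)", n_bad)
            x, y, sigma_x, sigma_y, frame = (a[ok] for a in (x, y, sigma_x, sigma_y, frame))
            if photons is not None:
                photons = photons[ok]
        return LocalizationSet(x, y, sigma_x, sigma_y, frame.astype(np.int64), photons)


def _resolve_dialect(path, dialect):
    if dialect is not None:
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def read_localizations(path, dialect=None, column_map=None, unit="nm",
                       pixel_size_nm=None):
    """Read a localization table from CSV or HDF5.

    Parameters
    ----------
    path : str or Path
    dialect : {'csv', 'hdf5'} or None
        Inferred from the file suffix when None.
    column_map : dict or None
        Maps the canonical names (``x, y, sigma_x, sigma_y, frame, photons``)
        to the names used in the file.
    unit : {'nm', 'pixel'}
        Unit of coordinates *and* precisions in the file.  ``pixel`` requires
        ``pixel_size_nm`` and converts on read; the in-memory representation
        is always nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _resolve_dialect(path, dialect)
    cmap = {name: name for name in DEFAULT_COLUMNS}
    if column_map:
        cmap.update(column_map)

    if dialect == "csv":
        df = pd.read_csv(path)
        cols = {}
        for name in DEFAULT_COLUMNS:
            src = cmap[name]
            if src in df.columns:
                cols[name] = df[src].to_numpy()
            elif name == "photons":
                cols[name] = None
            elif name == "frame":
                cols[name] = None
            else:
                raise ConfigurationError(
                    f"required column {src!r} (for {name!r}) missing from {path}")
    elif dialect == "hdf5":
        cols = {}
        with h5py.File(path, "r") as f:
            grp = f["localizations"] if "localizations" in f else f
            for name in DEFAULT_COLUMNS:
                src = cmap[name]
                if src in grp:
                    cols[name] = np.asarray(grp[src])
                elif name in ("photons", "frame"):
                    cols[name] = None
                else:
                    raise ConfigurationError(
                        f"required dataset {src!r} (for {name!r}) missing from {path}")
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    if cols["x"] is None or np.asarray(cols["x"]).size == 0:
        raise EmptyInputError(f"no localization records in {path}")

    if unit == "pixel":
        if pixel_size_nm is None:
            raise ConfigurationError("unit='pixel' requires pixel_size_nm")
        for name in ("x", "y", "sigma_x", "sigma_y"):
            cols[name] = np.asarray(cols[name], dtype=float) * pixel_size_nm
    elif unit != "nm":
        raise ConfigurationError(f"unknown unit {unit!r}")

    return LocalizationSet.from_arrays(
        cols["x"], cols["y"], cols["sigma_x"], cols["sigma_y"],
        cols["frame"], cols["photons"])


def write_localizations(locs, path, dialect=None):
    """Write a localization table as CSV or HDF5 (lossless round-trip)."""
    path = Path(path)
    dialect = _resolve_dialect(path, dialect)
    if dialect == "csv":
        df = locs.to_dataframe()
        # full float precision so read(write(s)) is exact
        df.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            grp = f.create_group("localizations")
            grp.attrs["units"] = "nm"
            grp.create_dataset("x", data=locs.x)
            grp.create_dataset("y", data=locs.y)
            grp.create_dataset("sigma_x", data=locs.sigma_x)
            grp.create_dataset("sigma_y", data=locs.sigma_y)
            grp.create_dataset("frame", data=locs.frame)
            if locs.photons is not None:
                grp.create_dataset("photons", data=locs.photons)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    return path


def inflate_precisions(locs, delta):
    """Add a constant offset (nm) to every precision on both axes.

    Compensates for under-reported localization precision from upstream
    fitting software; positions are unchanged.
    """
    if delta < 0:
        raise ValueError("precision inflation must be non-negative")
    return replace(locs, sigma_x=locs.sigma_x + delta,
                   sigma_y=locs.sigma_y + delta)


@dataclass
class RenderSpec:
    """Pixel grid for rendering localizations or emitters as an image.

    extent is (xmin, xmax, ymin, ymax) in nm; pixels are half-open
    [edge, edge + pixel_size) bins, row index = y, column index = x.
    """

    pixel_size: float
    extent: tuple

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        x0, x1, y0, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("extent must be non-degenerate")

    @property
    def shape(self):
        x0, x1, y0, y1 = self.extent
        nx = int(np.ceil((x1 - x0) / self.pixel_size))
        ny = int(np.ceil((y1 - y0) / self.pixel_size))
        return (ny, nx)

    def x_edges(self):
        x0 = self.extent[0]
        return x0 + self.pixel_size * np.arange(self.shape[1] + 1)

    def y_edges(self):
        y0 = self.extent[2]
        return y0 + self.pixel_size * np.arange(self.shape[0] + 1)


def render_gaussian_image(points, sigmas, spec):
    """Render points as unit-mass isotropic Gaussian blobs on a pixel grid.

    Each point contributes the exact integral of its Gaussian over every
    pixel (separable erf differences), so total image mass equals the number
    of points whose blobs lie inside the extent.  Points near or outside the
    edge contribute truncated mass.

    Parameters
    ----------
    points : (N, 2) array, nm
    sigmas : (N,) or (N, 2) array, nm
        Blob standard deviation per point (per-axis if 2-D).
    spec : RenderSpec
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ny, nx = spec.shape
    image = np.zeros((ny, nx), dtype=np.float64)
    if points.size == 0:
        return image.astype(np.float32)
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.ndim == 1:
        sigmas = np.column_stack([sigmas, sigmas])
    if np.any(sigmas <= 0):
        raise ValueError("blob sigmas must be positive")
    xe = spec.x_edges()
    ye = spec.y_edges()
    for (px, py), (sx, sy) in zip(points, sigmas):
        # restrict to a +-5 sigma window for speed
        c0 = max(0, int((px - 5 * sx - xe[0]) // spec.pixel_size))
        c1 = min(nx, int((px + 5 * sx - xe[0]) // spec.pixel_size) + 1)
        r0 = max(0, int((py - 5 * sy - ye[0]) // spec.pixel_size))
        r1 = min(ny, int((py + 5 * sy - ye[0]) // spec.pixel_size) + 1)
        if c1 <= c0 or r1 <= r0:
            continue
        fx = 0.5 * (erf((xe[c0:c1 + 1] - px) / (np.sqrt(2) * sx)))
        fy = 0.5 * (erf((ye[r0:r1 + 1] - py) / (np.sqrt(2) * sy)))
        image[r0:r1, c0:c1] += np.outer(np.diff(fy), np.diff(fx))
    return image.astype(np.float32)


def save_image_tiff(image, path):
    """Write an intensity image as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    return Path(path)
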