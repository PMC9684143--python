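"""End-to-end analysis: filter -> tile -> sample -> MAPN -> stitch -> render.

`analyze` is the library entry point operating on an in-memory
:class:`LocalizationSet`; `pipeline_run` wraps it with file I/O, filter
configuration and a JSON run report for the command line.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import preprocess
from .data import (ConfigurationError, LocalizationSet, RenderSpec,
                   inflate_precisions, read_localizations,
                   render_gaussian_image, save_image_tiff)
from .model import SamplerConfig
from .outputs import MAPNResult, make_tiling, mapn_extract, stitch
from .sampler import run_chain

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything produced by one pipeline run."""

    mapn: MAPNResult
    plan: object
    box_results: list
    chains: list
    posterior_image: np.ndarray = None
    report: dict = field(default_factory=dict)


def analyze(locs, sampler_config, subregion_size=None, overlap=None,
            extent=None, image_pixel=None, keep_chains=True):
    """Group a localization set into emitters.

    Parameters
    ----------
    locs : LocalizationSet
    sampler_config : SamplerConfig
        Per-box chains derive their seeds deterministically from
        ``sampler_config.rng_seed`` and the box index.
    subregion_size : float or None, nm
        Tile the field into subregions of this size (None analyzes the
        whole field as a single region).
    overlap : float or None, nm
        Overlap margin; default 2x the median precision.
    image_pixel : float or None, nm
        When set, also build the stitched posterior image at this pixel
        size.
    """
    if len(locs) == 0:
        return AnalysisResult(MAPNResult.empty(), None, [], [],
                              report={"n_localizations": 0})
    t0 = time.time()
    if subregion_size is None:
        x0, x1, y0, y1 = extent if extent is not None else locs.bounding_box()
        subregion_size = max(x1 - x0, y1 - y0) + 1.0
    plan = make_tiling(locs, subregion_size, overlap, extent=extent)
    chains = []
    box_results = []
    for b, idx in enumerate(plan.assignments):
        sub = locs.select(idx)
        cfg = replace(sampler_config,
                      rng_seed=(sampler_config.rng_seed + 1000003 * b) % (2 ** 31))
        chain = run_chain(sub, cfg, box=plan.boxes[b])
        box_results.append(mapn_extract(chain))
        chains.append(chain)
    spec = None
    if image_pixel is not None:
        x0, x1, y0, y1 = locs.bounding_box()
        spec = RenderSpec(pixel_size=image_pixel, extent=(x0, x1 + image_pixel,
                                                          y0, y1 + image_pixel))
    mapn, image = stitch(box_results, plan, chains=chains if spec else None,
                         image_spec=spec)
    report = {
        "n_localizations": len(locs),
        "n_boxes": plan.n_boxes,
        "n_emitters": mapn.K_map,
        "mean_precision_nm": (float(mapn.precisions.mean())
                              if mapn.K_map else float("nan")),
        "runtime_s": time.time() - t0,
        "acceptance": {
            j: float(np.nansum([c.accepted[j] for c in chains])
                     / max(1, np.nansum([c.proposed[j] for c in chains])))
            for j in ("move", "allocate", "birth", "death", "xi")
        },
    }
    return AnalysisResult(mapn, plan, box_results,
                          chains if keep_chains else [], image, report)


@dataclass
class RunConfig:
    """Whole-pipeline configuration (YAML-mappable; CLI flags override)."""

    input_path: str = None
    output_dir: str = "bagol_out"
    mode: str = "paint"                 # 'paint' or 'dstorm'
    column_map: dict = None
    unit: str = "nm"
    pixel_size_nm: float = None
    inflate_sigma: float = 0.0
    # filters
    intensity_mode: str = None          # None, 'relative' or 'absolute'
    intensity_factor: float = 2.0
    intensity_cutoff: float = None
    use_nnd_filter: bool = False
    nnd_threshold: int = None
    use_frame_connect: bool = False
    frame_connect_gap: int = 1
    # sampler
    xi: float = 50.0
    xi_mode: str = "hierarchical"
    xi_prior_eta: float = 1.0
    xi_prior_gamma: float = 5.0
    count_model: str = "poisson"
    drift_enabled: bool = False
    n_samples: int = 1000
    n_burnin: int = None
    seed: int = 0
    # tiling / rendering
    subregion_size: float = None
    overlap: float = None
    image_pixel: float = 2.0
    save_chains: bool = False

    def validate(self):
        if self.mode not in ("paint", "dstorm"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "dstorm" and self.use_nnd_filter:
            raise ConfigurationError(
                "the NND filter must not be used for dSTORM data "
                "(an emitter may blink only once)")

    def sampler_config(self):
        return SamplerConfig(
            xi=self.xi, xi_mode=self.xi_mode,
            xi_prior_eta=self.xi_prior_eta, xi_prior_gamma=self.xi_prior_gamma,
            count_model=self.count_model, drift_enabled=self.drift_enabled,
            n_samples=self.n_samples, n_burnin=self.n_burnin,
            rng_seed=self.seed)

    @staticmethod
    def from_yaml(path, **overrides):
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**raw)


def pipeline_run(config):
    """Execute the full pipeline from files to files.

    Writes MAPN coordinates (CSV), posterior and MAPN images (TIFF),
    optionally per-box chains (HDF5) and a JSON run report; returns the
    :class:`AnalysisResult`.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    locs = read_localizations(config.input_path, column_map=config.column_map,
                              unit=config.unit,
                              pixel_size_nm=config.pixel_size_nm)
    stage_counts = {"input": len(locs)}
    if config.inflate_sigma:
        locs = inflate_precisions(locs, config.inflate_sigma)
    if config.use_frame_connect:
        locs = preprocess.frame_connect(locs, max_gap=config.frame_connect_gap)
        stage_counts["frame_connect"] = len(locs)
    if config.intensity_mode:
        locs, removed = preprocess.intensity_filter(
            locs, mode=config.intensity_mode, factor=config.intensity_factor,
            cutoff=config.intensity_cutoff)
        stage_counts["intensity_filter"] = len(locs)
    if config.use_nnd_filter:
        locs, nnd_report = preprocess.nnd_filter(
            locs, threshold_override=config.nnd_threshold)
        stage_counts["nnd_filter"] = len(locs)
    if len(locs) == 0:
        raise ConfigurationError("no localizations left after filtering")

    result = analyze(locs, config.sampler_config(),
                     subregion_size=config.subregion_size,
                     overlap=config.overlap,
                     image_pixel=config.image_pixel)

    result.mapn.to_dataframe().to_csv(out / "mapn.csv", index=False,
                                      float_format="%.17g")
    if result.posterior_image is not None:
        save_image_tiff(result.posterior_image, out / "posterior.tiff")
        if result.mapn.K_map:
            x0, x1, y0, y1 = locs.bounding_box()
            spec = RenderSpec(config.image_pixel,
                              (x0, x1 + config.image_pixel,
                               y0, y1 + config.image_pixel))
            mapn_img = render_gaussian_image(result.mapn.positions,
                                             result.mapn.precisions, spec)
            save_image_tiff(mapn_img, out / "mapn.tiff")
    if config.save_chains:
        for b, chain in enumerate(result.chains):
            chain.to_hdf5(out / f"chain_{b:04d}.h5")
    from . import __version__

    report = dict(result.report)
    report["stage_counts"] = stage_counts
    report["seed"] = config.seed
    report["version"] = __version__
    report["config"] = {k: v for k, v in asdict(config).items()
                        if not isinstance(v, dict) or v is None}
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=str)
    return result
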