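"""End-to-end quantification: scan + annotation -> sector vessel densities.

Order of operations: canonicalise laterality -> multi-scale Frangi
vesselness -> global Otsu threshold -> binarize -> FoBMOC-aligned sector
partition -> per-sector density.  The effective parameter set is hashed
into every result row so densities are auditable: vessel-density values are
parameter- and device-sensitive and only comparable under identical
settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from . import binarization, density, geometry
from .binarization import DegenerateHistogramError, VesselMask
from .geometry import SectorGrid
from .io_formats import EnFaceScan, ScanAnnotation, VDResult
from .vesselness import FrangiParams, VesselnessMap, frangi_multiscale

__all__ = ["RunConfig", "QuantifyOutput", "quantify"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Effective analysis configuration; defaults are the tool's settings."""

    frangi: FrangiParams = field(default_factory=FrangiParams)
    otsu_bins: int = 256
    outer_radius_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.otsu_bins < 2:
            raise ValueError("otsu_bins must be >= 2")
        if self.outer_radius_mm is not None and self.outer_radius_mm <= 0:
            raise ValueError("outer_radius_mm must be > 0")

    @property
    def params_hash(self) -> str:
        blob = json.dumps(
            {
                "frangi": self.frangi.params_hash,
                "otsu_bins": self.otsu_bins,
                "outer_radius_mm": self.outer_radius_mm,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "frangi": {
                "scale_min": self.frangi.scale_min,
                "scale_max": self.frangi.scale_max,
                "scale_ratio": self.frangi.scale_ratio,
                "beta1": self.frangi.beta1,
                "beta2": self.frangi.beta2,
                "normalize_to": list(self.frangi.normalize_to),
                "polarity": self.frangi.polarity,
                "include_scale_max": self.frangi.include_scale_max,
            },
            "otsu_bins": self.otsu_bins,
            "outer_radius_mm": self.outer_radius_mm,
            "params_hash": self.params_hash,
        }


class QuantifyOutput(NamedTuple):
    result: VDResult
    mask: VesselMask
    grid: SectorGrid
    vesselness: VesselnessMap


def quantify(scan: EnFaceScan, ann: ScanAnnotation, config: RunConfig = RunConfig()) -> QuantifyOutput:
    """Run the full vessel-density pipeline on one scan.

    A degenerate (constant) scan produces an all-background mask with a NaN
    threshold, hence VD = 0 in every sector.
    """
    original_laterality = scan.laterality
    scan_c, ann_c = geometry.mirror_for_laterality(scan, ann)

    vmap = frangi_multiscale(scan_c, config.frangi)
    try:
        threshold = binarization.otsu_threshold(vmap, n_bins=config.otsu_bins)
        mask = binarization.binarize(vmap, threshold, n_bins=config.otsu_bins)
    except DegenerateHistogramError:
        logger.warning("scan %s: constant vesselness map; reporting VD = 0", scan.scan_id)
        mask = VesselMask(np.zeros(vmap.shape, dtype=bool), float("nan"), config.otsu_bins)

    outer_px = None
    if config.outer_radius_mm is not None:
        outer_px = config.outer_radius_mm * 1000.0 / scan.px_size_um
    grid = geometry.sector_partition(ann_c, scan_c.pixels.shape, outer_radius_px=outer_px)

    result = density.sector_vd(
        mask,
        grid,
        params_hash=config.params_hash,
        scan_id=scan.scan_id,
        subject_id=scan.subject_id,
    )
    result.laterality = original_laterality
    return QuantifyOutput(result=result, mask=mask, grid=grid, vesselness=vmap)
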