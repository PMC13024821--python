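"""Vessel-density statistics over the BMO-based sector grid.

Vessel density of a sector is the number of vessel pixels divided by the
total number of pixels in that sector, expressed in percent.  The overall
density ``vd_mean`` is the pixel-weighted ratio over the union of the four
sectors (so it equals the white-to-total pixel fraction of the whole
peripapillary ROI); the arithmetic mean of the sector densities is carried
alongside as ``vd_mean_unweighted``.  ONH-interior pixels contribute to
neither numerator nor denominator.
"""

from __future__ import annotations

import numpy as np

from .binarization import VesselMask
from .geometry import SECTOR_LABELS, SectorGrid
from .io_formats import VDResult

__all__ = ["EmptySectorError", "sector_vd"]


class EmptySectorError(ValueError):
    """Raised when a sector contains no pixels at all."""


def sector_vd(
    mask: VesselMask | np.ndarray,
    grid: SectorGrid,
    params_hash: str = "",
    scan_id: str = "",
    subject_id: str = "",
) -> VDResult:
    """Count vessel and total pixels per sector and build a :class:`VDResult`."""
    mask_arr = np.asarray(mask.mask if isinstance(mask, VesselMask) else mask, dtype=bool)
    if mask_arr.shape != grid.labels.shape:
        raise ValueError(f"mask shape {mask_arr.shape} != grid shape {grid.labels.shape}")
    threshold = mask.threshold if isinstance(mask, VesselMask) else float("nan")

    n_total = []
    n_vessel = []
    for k in SECTOR_LABELS:
        sel = grid.labels == k
        nt = int(sel.sum())
        if nt == 0:
            raise EmptySectorError(f"sector S{k} contains no pixels")
        n_total.append(nt)
        n_vessel.append(int(np.count_nonzero(mask_arr & sel)))

    return VDResult(
        n_vessel=tuple(n_vessel),
        n_total=tuple(n_total),
        threshold_used=threshold,
        params_hash=params_hash,
        scan_id=scan_id,
        subject_id=subject_id,
        laterality=grid.laterality,
    )
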