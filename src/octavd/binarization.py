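"""Otsu thresholding of the vesselness response into a binary vessel map.

The threshold is found on a 256-bin histogram spanning the map's own
[min, max] range; candidate thresholds are the interior bin edges, the
winner maximises the between-class variance

    sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

and ties go to the smallest qualifying edge.  A pixel is vessel iff its
value is strictly greater than the threshold.  The threshold is global for
the whole scan: the tool produces a single binarised vessel map per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vesselness import VesselnessMap

__all__ = ["VesselMask", "DegenerateHistogramError", "otsu_threshold", "binarize"]


class DegenerateHistogramError(ValueError):
    """Raised when a constant map leaves Otsu with a single-class histogram."""


@dataclass
class VesselMask:
    """Binary vessel/background map with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    n_bins: int = 256

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_vessel(self) -> int:
        return int(self.mask.sum())


def _values(map_or_array) -> np.ndarray:
    values = map_or_array.values if isinstance(map_or_array, VesselnessMap) else np.asarray(map_or_array)
    if not np.all(np.isfinite(values)):
        raise ValueError("map contains non-finite values")
    return np.asarray(values, dtype=float)


def otsu_threshold(vmap: VesselnessMap | np.ndarray, n_bins: int = 256) -> float:
    """Between-class-variance-maximising bin-edge threshold.

    Raises :class:`DegenerateHistogramError` for a constant map (for an
    all-zero vesselness map the caller typically reports VD = 0).
    """
    values = _values(vmap)
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateHistogramError("degenerate histogram: constant map has no Otsu threshold")
    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    w = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(w)[:-1]  # class 0 = bins 0..k, cut after bin k
    w1 = 1.0 - w0
    cum_mu = np.cumsum(w * centers)
    total_mu = cum_mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu[:-1] / w0
        mu1 = (total_mu - cum_mu[:-1]) / w1
    sigma_b2 = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    # Ties go to the smallest qualifying threshold.  Cuts that differ only
    # by empty bins give mathematically identical class splits, so ties are
    # detected with a relative tolerance rather than bitwise equality.
    best = sigma_b2.max()
    k = int(np.flatnonzero(sigma_b2 >= best - 1e-12 * abs(best))[0])
    return float(edges[k + 1])


def binarize(vmap: VesselnessMap | np.ndarray, threshold: float, n_bins: int = 256) -> VesselMask:
    """Strict-greater-than binarization: vessel iff value > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = _values(vmap)
    return VesselMask(mask=values > threshold, threshold=float(threshold), n_bins=n_bins)
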