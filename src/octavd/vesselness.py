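"""Multi-scale Frangi vesselness filtering of en-face angiograms.

The filter measures tubularity from the eigenvalues of the Gaussian-scale
Hessian.  With |l1| <= |l2|, the blobness ratio R_B = l1/l2 separates
line-like from blob-like structure and the structureness S = sqrt(l1^2+l2^2)
separates structure from background noise; the single-scale response is

    V_sigma = exp(-R_B^2 / (2 beta1^2)) * (1 - exp(-S^2 / (2 beta2^2)))

set to zero wherever l2 > 0 (vessels are bright on dark in OCT-A: flow is
high decorrelation signal).  The multi-scale response is the pointwise
maximum over a geometric scale ladder; second derivatives are multiplied by
sigma^2 (gamma = 2 normalisation) so responses are comparable across scales.

Defaults are the Erlangen tool settings: scale range [1, 10] with ratio 2
(ladder {1, 2, 4, 8}), beta1 = 0.5, beta2 = 15, input normalised to
[0, 255] so that beta2 has a fixed intensity meaning regardless of the
export bit depth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_formats import EnFaceScan

__all__ = [
    "FrangiParams",
    "HessianField",
    "VesselnessMap",
    "hessian_at_scale",
    "vesselness_single_scale",
    "frangi_multiscale",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrangiParams:
    """Parameters of the multi-scale Frangi filter.

    ``scale_min``/``scale_max``/``scale_ratio`` define the geometric scale
    ladder {scale_min * scale_ratio**k <= scale_max}; with the defaults this
    is {1, 2, 4, 8}.  Set ``include_scale_max`` to append the endpoint
    (10 px) explicitly.  ``normalize_to`` is the intensity range the input
    is linearly mapped onto before filtering; ``beta2`` is meaningful only
    relative to that range.
    """

    scale_min: float = 1.0
    scale_max: float = 10.0
    scale_ratio: float = 2.0
    beta1: float = 0.5
    beta2: float = 15.0
    normalize_to: tuple[float, float] = (0.0, 255.0)
    polarity: str = "bright"  # bright-on-dark vessels (OCT-A flow signal)
    include_scale_max: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.scale_min <= self.scale_max):
            raise ValueError("need 0 < scale_min <= scale_max")
        if self.scale_ratio <= 1:
            raise ValueError("scale_ratio must be > 1")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("beta1 and beta2 must be > 0")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")
        if self.normalize_to[1] <= self.normalize_to[0]:
            raise ValueError("normalize_to must be an increasing range")

    @property
    def scales(self) -> tuple[float, ...]:
        out = []
        s = self.scale_min
        while s <= self.scale_max * (1 + 1e-12):
            out.append(s)
            s *= self.scale_ratio
        if self.include_scale_max and out[-1] < self.scale_max:
            out.append(self.scale_max)
        return tuple(out)

    @property
    def params_hash(self) -> str:
        blob = json.dumps(
            {
                "scale_min": self.scale_min,
                "scale_max": self.scale_max,
                "scale_ratio": self.scale_ratio,
                "beta1": self.beta1,
                "beta2": self.beta2,
                "normalize_to": list(self.normalize_to),
                "polarity": self.polarity,
                "include_scale_max": self.include_scale_max,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class HessianField:
    """Gamma-normalised Hessian of a 2D image at one scale.

    ``hxx``/``hxy``/``hyy`` are Gaussian second derivatives multiplied by
    sigma^2; ``lambda1``/``lambda2`` are the eigenvalues ordered by
    magnitude, |lambda1| <= |lambda2|.
    """

    sigma: float
    hxx: np.ndarray
    hxy: np.ndarray
    hyy: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray

    @property
    def structureness(self) -> np.ndarray:
        """Frobenius norm S = sqrt(lambda1^2 + lambda2^2); always >= 0."""
        return np.sqrt(self.lambda1**2 + self.lambda2**2)

    @property
    def blobness(self) -> np.ndarray:
        """R_B = lambda1/lambda2; NaN where lambda2 == 0 (no structure)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.lambda2 != 0, self.lambda1 / np.where(self.lambda2 != 0, self.lambda2, 1.0), np.nan)


def hessian_at_scale(image: np.ndarray, sigma: float) -> HessianField:
    """Gamma-normalised Hessian by Gaussian-derivative convolution.

    Derivatives use reflect boundary handling so the raster edge does not
    produce a dark-frame halo; x is axis 1, y is axis 0.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    s2 = sigma * sigma
    # order=(dy, dx); gamma = 2 normalisation.  truncate=8 keeps the
    # truncation error of the derivative kernels (which must integrate to
    # zero) far below the responses of interest, so constant regions give
    # an essentially zero Hessian.
    hxx = s2 * ndimage.gaussian_filter(image, sigma, order=(0, 2), mode="reflect", truncate=8.0)
    hyy = s2 * ndimage.gaussian_filter(image, sigma, order=(2, 0), mode="reflect", truncate=8.0)
    hxy = s2 * ndimage.gaussian_filter(image, sigma, order=(1, 1), mode="reflect", truncate=8.0)

    # closed-form eigenvalues of the symmetric 2x2 tensor, ordered by |.|
    mean = 0.5 * (hxx + hyy)
    disc = np.sqrt(((hxx - hyy) * 0.5) ** 2 + hxy**2)
    e_hi = mean + disc
    e_lo = mean - disc
    swap = np.abs(e_hi) < np.abs(e_lo)
    lambda2 = np.where(swap, e_lo, e_hi)
    lambda1 = np.where(swap, e_hi, e_lo)
    return HessianField(sigma=sigma, hxx=hxx, hxy=hxy, hyy=hyy, lambda1=lambda1, lambda2=lambda2)


def vesselness_single_scale(h: HessianField, params: FrangiParams) -> np.ndarray:
    """Frangi response at one scale; values in [0, 1).

    The response is zero where the sign of lambda2 indicates the wrong
    polarity (lambda2 > 0 for bright vessels) and where lambda2 == 0
    (no structure).
    """
    l1, l2 = h.lambda1, h.lambda2
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (l1 / np.where(l2 != 0, l2, 1.0)) ** 2, 0.0)
    s2 = l1**2 + l2**2
    v = np.exp(-rb2 / (2.0 * params.beta1**2)) * (1.0 - np.exp(-s2 / (2.0 * params.beta2**2)))
    if params.polarity == "bright":
        v = np.where(l2 > 0, 0.0, v)
    else:
        v = np.where(l2 < 0, 0.0, v)
    return np.where(l2 == 0, 0.0, v)


@dataclass
class VesselnessMap:
    """Continuous multi-scale vesselness response, values in [0, 1)."""

    values: np.ndarray
    params_hash: str = ""
    scan_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _normalize(image: np.ndarray, lo: float, hi: float) -> Optional[np.ndarray]:
    image = np.asarray(image, dtype=float)
    imin, imax = image.min(), image.max()
    if imax == imin:
        return None
    return lo + (image - imin) * ((hi - lo) / (imax - imin))


def frangi_multiscale(scan: EnFaceScan | np.ndarray, params: FrangiParams = FrangiParams()) -> VesselnessMap:
    """Pointwise maximum of the single-scale responses over the scale ladder.

    A constant (degenerate) image yields an all-zero map with a warning;
    downstream Otsu thresholding of such a map is itself degenerate and the
    caller decides how to proceed.
    """
    if isinstance(scan, EnFaceScan):
        image = scan.pixels
        scan_id = scan.scan_id
    else:
        image = np.asarray(scan)
        scan_id = ""
    norm = _normalize(image, *params.normalize_to)
    if norm is None:
        warnings.warn("constant image: vesselness response is identically zero", stacklevel=2)
        return VesselnessMap(np.zeros(np.asarray(image).shape, dtype=float), params.params_hash, scan_id)
    response = np.zeros_like(norm)
    for sigma in params.scales:
        v = vesselness_single_scale(hessian_at_scale(norm, sigma), params)
        np.maximum(response, v, out=response)
    return VesselnessMap(response, params.params_hash, scan_id)
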