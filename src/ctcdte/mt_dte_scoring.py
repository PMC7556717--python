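"""Per-cell microtubule drug-target engagement (MT-DTE) scoring.

Taxanes stabilize microtubules; in treated cells the tubulin network
reorganizes into thick, bright bundles.  The MT-DTE score captures this on
a single-cell basis from the tubulin channel of a confocal z-stack:

1. maximum-intensity projection of the tubulin channel;
2. export of the projection as an 8-bit image;
3. a dynamic threshold keeping pixels within the top 25% of the image's own
   intensity range — upper bound the image maximum ``M``, lower bound
   ``0.75 * M``;
4. integrated density of the thresholded region of interest: mean ROI
   fluorescence multiplied by ROI area, which equals the summed pixel
   intensity inside the ROI.

The threshold is value-based (``v >= 0.75 * M``, inclusive), computed per
image from its own dynamic range, so the score needs no global calibration
across cells.  The lower bound is kept in real arithmetic — integer images
are compared against ``0.75 * M`` directly, never against a rounded bound.
An all-zero projection has no defined score and raises
:class:`~ctcdte.exceptions.DegenerateImageError`; callers report such cells
as missing rather than scoring them 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .exceptions import ConfigurationError, DegenerateImageError, ValidationError
from .image_io import Image2D, MultichannelStack, max_intensity_projection, to_8bit

#: Fraction of the image maximum used as the lower threshold bound.
THRESHOLD_FRACTION = 0.75

#: Channel scored by default.
TUBULIN_CHANNEL = "TUB"


@dataclass(frozen=True)
class ThresholdBounds:
    """Dynamic threshold bounds: ``upper`` is the image max, ``lower`` is 75% of it."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper):
            raise ValidationError(
                f"require 0 <= lower <= upper, got ({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class MtDteScore:
    """The score bundle for one cell.

    ``integrated_density`` is the MT-DTE value: the summed intensity of the
    super-threshold pixels, identically ``roi_mean_intensity * roi_area_px``.
    ``scale_factor`` is an explicit reporting multiplier (default 1) applied
    in :attr:`scaled_score`; no implicit normalization is ever performed.
    """

    cell_id: str
    bounds: ThresholdBounds
    roi_area_px: int
    roi_mean_intensity: float
    integrated_density: float
    scale_factor: float = 1.0

    @property
    def scaled_score(self) -> float:
        return self.integrated_density * self.scale_factor


def compute_threshold(image: Image2D) -> ThresholdBounds:
    """Compute the per-image dynamic threshold bounds.

    Raises
    ------
    DegenerateImageError
        If the image is all zero: the score is undefined for such cells
        and must be reported as missing, never as 0.
    """
    upper = float(np.max(image.pixels))
    if upper <= 0:
        raise DegenerateImageError(
            "all-zero image: MT-DTE is undefined (report as missing, not 0)"
        )
    return ThresholdBounds(lower=THRESHOLD_FRACTION * upper, upper=upper)


def compute_roi(image: Image2D, bounds: ThresholdBounds) -> Tuple[np.ndarray, int]:
    """Binary ROI mask of pixels with ``lower <= v <= upper`` and its area.

    The ROI is the raw super-threshold pixel set — no connectivity
    filtering or morphological cleanup.  The arg-max pixel always
    satisfies the threshold, so the area is at least 1.
    """
    v = image.pixels
    mask = (v >= bounds.lower) & (v <= bounds.upper)
    return mask, int(mask.sum())


def mt_dte(
    image: Image2D, scale_factor: float = 1.0, cell_id: str = ""
) -> MtDteScore:
    """Score one projection: threshold, ROI, integrated density.

    ``integrated_density`` is computed as the exact sum of the masked
    intensities (in float64), and ``roi_mean_intensity`` as that sum over
    the area, so the product identity holds to floating precision and
    integer inputs are scored exactly.
    """
    if scale_factor <= 0:
        raise ValidationError(f"scale_factor must be > 0, got {scale_factor}")
    bounds = compute_threshold(image)
    mask, area = compute_roi(image, bounds)
    total = float(image.pixels[mask].sum(dtype=np.float64))
    return MtDteScore(
        cell_id=cell_id,
        bounds=bounds,
        roi_area_px=area,
        roi_mean_intensity=total / area,
        integrated_density=total,
        scale_factor=scale_factor,
    )


def score_ctc(
    stack: MultichannelStack,
    channel: str = TUBULIN_CHANNEL,
    conversion_mode: str = "scale_zero_max",
    scale_factor: float = 1.0,
    cell_id: str = "",
) -> MtDteScore:
    """Full per-cell workflow: tubulin MIP -> 8-bit image -> MT-DTE.

    Raises
    ------
    ConfigurationError
        If the stack has no tubulin channel.
    DegenerateImageError
        If the tubulin projection is all zero (missing score).
    """
    if channel not in stack.channel_names:
        raise ConfigurationError(
            f"stack has no {channel!r} channel (channels: {stack.channel_names})"
        )
    mip = max_intensity_projection(stack, channel)
    img8 = to_8bit(mip, mode=conversion_mode)
    return mt_dte(img8, scale_factor=scale_factor, cell_id=cell_id)


__all__ = [
    "THRESHOLD_FRACTION",
    "TUBULIN_CHANNEL",
    "ThresholdBounds",
    "MtDteScore",
    "compute_threshold",
    "compute_roi",
    "mt_dte",
    "score_ctc",
]
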