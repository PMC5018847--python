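"""Three-region scene decomposition from a clutch mask.

The clutch mask (all eggs as one binary raster) is split by morphological
operations into: the internal egg region (mask eroded by 4 px), the egg
contour band (from the eroded outline out to the mask dilated by 8 px — a
12-px-wide band at the defaults), and the background substrate (everything
beyond the dilated outline).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk, erosion, footprint_rectangle

logger = logging.getLogger(__name__)


class EmptyRegionError(ValueError):
    """A region required for measurement is empty."""


@dataclass
class ClutchMask:
    """Binary clutch raster; True marks egg pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("clutch mask has no egg pixels")


@dataclass
class RegionSet:
    """Disjoint pixel sets partitioning the ROI.

    internal  = erosion(mask, erode_px)
    contour_band = dilation(mask, dilate_px) minus internal
    background   = complement of dilation(mask, dilate_px)
    """

    internal: np.ndarray
    contour_band: np.ndarray
    background: np.ndarray
    erode_px: int = 4
    dilate_px: int = 8

    def __post_init__(self) -> None:
        for name in ("internal", "contour_band", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.internal.shape == self.contour_band.shape == self.background.shape):
            raise ValueError("region arrays must share dimensions")
        if (
            (self.internal & self.contour_band).any()
            or (self.internal & self.background).any()
            or (self.contour_band & self.background).any()
        ):
            raise ValueError("regions must be pairwise disjoint")

    def to_labels(self) -> np.ndarray:
        """0 = background, 1 = contour band, 2 = internal (audit export)."""
        out = np.zeros(self.internal.shape, dtype=np.uint8)
        out[self.contour_band] = 1
        out[self.internal] = 2
        return out


def _footprint(radius: int, shape: str) -> np.ndarray | None:
    if radius == 0:
        return None
    if shape == "disk":
        return disk(radius)
    if shape == "square":
        side = 2 * radius + 1
        return footprint_rectangle((side, side))
    raise ValueError(f"unknown structuring element shape {shape!r}")


def derive_regions(
    mask: ClutchMask,
    erode_px: int = 4,
    dilate_px: int = 8,
    se_shape: str = "disk",
    nominal_band_px: int = 12,
) -> RegionSet:
    """Split the ROI into internal egg, contour band, and background.

    Erosion and dilation each apply a single structuring element of radius
    ``erode_px`` / ``dilate_px`` (a Euclidean disk by default; ``square``
    gives the Chebyshev ball).  The band width is the consequence of the
    two radii; a combination not summing to ``nominal_band_px`` is allowed
    but logged.

    Raises EmptyRegionError if dilation covers the whole ROI (no substrate
    left to measure); an internal region emptied by erosion is only
    warned about, since the band and background remain measurable.
    """
    if erode_px < 0 or dilate_px < 0:
        raise ValueError("morphology radii must be non-negative")
    if erode_px + dilate_px != nominal_band_px:
        logger.info(
            "band radii (%d erode + %d dilate) do not sum to the nominal %d px band",
            erode_px,
            dilate_px,
            nominal_band_px,
        )
    m = mask.mask
    fe = _footprint(erode_px, se_shape)
    fd = _footprint(dilate_px, se_shape)
    # grayscale morphology on bool rasters == binary morphology; the
    # footprints here are always odd and symmetric, so no pixel shift
    internal = erosion(m, fe).astype(bool) if fe is not None else m.copy()
    dilated = dilation(m, fd).astype(bool) if fd is not None else m.copy()
    band = dilated & ~internal
    background = ~dilated
    if not internal.any():
        msg = "erosion emptied the clutch: too small for the requested band radii"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not background.any():
        raise EmptyRegionError("dilated clutch covers the entire ROI; no background substrate")
    return RegionSet(
        internal=internal,
        contour_band=band,
        background=background,
        erode_px=erode_px,
        dilate_px=dilate_px,
    )
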