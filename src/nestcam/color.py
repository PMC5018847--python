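"""Color-managed image handling: RGB -> CIE XYZ -> CIELAB, and ROI cropping.

Input photographs are assumed to be color-calibrated upstream (a custom
camera profile applied before export), in either Adobe RGB (1998) or sRGB.
Conversion decodes the transfer curve, applies the colorspace's RGB->XYZ
primaries matrix (D65 reference white by default), then the CIE L*a*b*
formula.  All camouflage metrics downstream operate on the CIELAB scene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: D65 reference white, 2 degree observer, Y normalized to 1.
D65_WHITE = (0.95047, 1.0, 1.08883)

# Column-order [R,G,B] -> [X,Y,Z] matrices for D65-referenced spaces.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_ADOBE_TO_XYZ = np.array(
    [
        [0.5767309, 0.1855540, 0.1881852],
        [0.2973769, 0.6273491, 0.0752741],
        [0.0270343, 0.0706872, 0.9911085],
    ]
)

# rescale rows so RGB (1,1,1) maps exactly onto the D65 white: the
# published 7-digit matrices are imbalanced by ~4e-6, which would leak a
# spurious chroma onto the gray axis
for _M in (_SRGB_TO_XYZ, _ADOBE_TO_XYZ):
    _M *= (np.array(D65_WHITE) / _M.sum(axis=1))[:, None]

#: Adobe RGB (1998) decoding exponent, exactly 563/256.
ADOBE_GAMMA = 563.0 / 256.0

KNOWN_COLORSPACES = ("adobe-rgb-1998", "srgb")


class ColorConfigError(ValueError):
    """Unknown colorspace tag or invalid conversion configuration."""


@dataclass(frozen=True)
class ColorTriple:
    """A single CIELAB coordinate (also used for XYZ white points)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.L, self.a, self.b])):
            raise ValueError("color components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass
class RgbScene:
    """Calibrated RGB photograph with its pixel scale.

    pixels are H x W x 3 floats in [0, 1]; ``colorspace_tag`` names the
    encoding (``adobe-rgb-1998`` or ``srgb``); ``pixels_per_cm`` is the
    spatial calibration recorded at photography time.
    """

    pixels: np.ndarray
    colorspace_tag: str
    pixels_per_cm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if np.nanmin(self.pixels) < 0 or np.nanmax(self.pixels) > 1:
            raise ValueError("RGB components must lie in [0, 1]")
        if self.colorspace_tag not in KNOWN_COLORSPACES:
            raise ColorConfigError(
                f"unknown colorspace_tag {self.colorspace_tag!r}; "
                f"expected one of {KNOWN_COLORSPACES}"
            )
        if not self.pixels_per_cm > 0:
            raise ValueError("pixels_per_cm must be positive")


@dataclass
class LabScene:
    """Scene in CIELAB: L in [0, 100], a/b signed chromatic axes."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    pixels_per_cm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L, a, b must share dimensions")
        if not self.pixels_per_cm > 0:
            raise ValueError("pixels_per_cm must be positive")

    @property
    def shape(self) -> tuple:
        return self.L.shape

    def stack(self) -> np.ndarray:
        """H x W x 3 array of (L, a, b)."""
        return np.stack([self.L, self.a, self.b], axis=-1)


def _decode_gamma(rgb: np.ndarray, colorspace_tag: str) -> np.ndarray:
    """Encoded RGB in [0,1] -> linear RGB."""
    if colorspace_tag == "srgb":
        low = rgb <= 0.04045
        out = np.where(low, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
        return out
    if colorspace_tag == "adobe-rgb-1998":
        return rgb**ADOBE_GAMMA
    raise ColorConfigError(f"unknown colorspace_tag {colorspace_tag!r}")


def _encode_gamma(linear: np.ndarray, colorspace_tag: str) -> np.ndarray:
    if colorspace_tag == "srgb":
        low = linear <= 0.0031308
        return np.where(low, linear * 12.92, 1.055 * np.maximum(linear, 0) ** (1 / 2.4) - 0.055)
    if colorspace_tag == "adobe-rgb-1998":
        return np.maximum(linear, 0) ** (1.0 / ADOBE_GAMMA)
    raise ColorConfigError(f"unknown colorspace_tag {colorspace_tag!r}")


def _xyz_matrix(colorspace_tag: str) -> np.ndarray:
    if colorspace_tag == "srgb":
        return _SRGB_TO_XYZ
    if colorspace_tag == "adobe-rgb-1998":
        return _ADOBE_TO_XYZ
    raise ColorConfigError(f"unknown colorspace_tag {colorspace_tag!r}")


# CIE L*a*b* companding: cube root above the linear-segment knee.
_LAB_EPS = (6.0 / 29.0) ** 3
_LAB_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear segment


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_EPS, np.cbrt(t), _LAB_KAPPA * t + 4.0 / 29.0)


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > 6.0 / 29.0, ft**3, (ft - 4.0 / 29.0) / _LAB_KAPPA)


def xyz_to_lab(xyz: np.ndarray, white_point=D65_WHITE) -> np.ndarray:
    """XYZ (…x3) -> CIELAB (…x3) relative to ``white_point``."""
    wp = np.asarray(white_point, dtype=float)
    if np.any(wp <= 0):
        raise ColorConfigError("white point components must be positive")
    f = _lab_f(np.asarray(xyz, dtype=float) / wp)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab: np.ndarray, white_point=D65_WHITE) -> np.ndarray:
    """Inverse CIELAB transform (used for round-trip validation)."""
    lab = np.asarray(lab, dtype=float)
    wp = np.asarray(white_point, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack(
        [_lab_f_inv(fx) * wp[0], _lab_f_inv(fy) * wp[1], _lab_f_inv(fz) * wp[2]],
        axis=-1,
    )


def rgb_to_lab(scene: RgbScene, white_point=D65_WHITE) -> LabScene:
    """Convert a calibrated RGB scene to CIELAB.

    Path: decode transfer curve -> linear RGB -> XYZ via the colorspace's
    primaries matrix -> CIELAB against ``white_point`` (D65 by default,
    the reference white of both supported RGB spaces).
    """
    linear = _decode_gamma(scene.pixels, scene.colorspace_tag)
    xyz = linear @ _xyz_matrix(scene.colorspace_tag).T
    lab = xyz_to_lab(xyz, white_point)
    return LabScene(
        L=lab[..., 0],
        a=lab[..., 1],
        b=lab[..., 2],
        pixels_per_cm=scene.pixels_per_cm,
        provenance={"colorspace": scene.colorspace_tag, "white_point": tuple(white_point)},
    )


def lab_scene_to_rgb(scene: LabScene, colorspace_tag: str = "srgb", white_point=D65_WHITE) -> np.ndarray:
    """Render a LabScene back to encoded RGB in [0,1] (for audit images)."""
    xyz = lab_to_xyz(scene.stack(), white_point)
    linear = xyz @ np.linalg.inv(_xyz_matrix(colorspace_tag)).T
    return np.clip(_encode_gamma(np.clip(linear, 0, None), colorspace_tag), 0, 1)


def delta_e(c1: ColorTriple, c2: ColorTriple) -> float:
    """CIE76 color difference: Euclidean distance in CIELAB."""
    return float(np.linalg.norm(c1.as_array() - c2.as_array()))


def crop_roi(scene: LabScene, clutch_centroid: tuple, side_cm: float = 13.3) -> LabScene:
    """Crop a square window of ``side_cm`` centimeters centered on the clutch.

    The window is round(side_cm * pixels_per_cm) pixels on a side, clamped
    to the image bounds; clamping that shrinks the nominal window is
    logged as a warning.  ``clutch_centroid`` is (row, col) in 0-based
    pixel coordinates and must fall inside the image.
    """
    if not side_cm > 0:
        raise ValueError("side_cm must be positive")
    H, W = scene.shape
    r, c = (int(round(clutch_centroid[0])), int(round(clutch_centroid[1])))
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"clutch centroid {clutch_centroid} outside image of shape {(H, W)}")
    side_px = int(round(side_cm * scene.pixels_per_cm))
    if side_px < 1:
        raise ValueError("crop window is empty at this pixel scale")
    half_lo = side_px // 2
    half_hi = side_px - half_lo
    r0, r1 = max(0, r - half_lo), min(H, r + half_hi)
    c0, c1 = max(0, c - half_lo), min(W, c + half_hi)
    if (r1 - r0, c1 - c0) != (side_px, side_px):
        msg = (
            f"crop clamped to image bounds: nominal {side_px}x{side_px}, "
            f"actual {(r1 - r0)}x{(c1 - c0)}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    prov = dict(scene.provenance)
    prov["crop"] = {"rows": (r0, r1), "cols": (c0, c1), "side_cm": side_cm}
    return LabScene(
        L=scene.L[r0:r1, c0:c1].copy(),
        a=scene.a[r0:r1, c0:c1].copy(),
        b=scene.b[r0:r1, c0:c1].copy(),
        pixels_per_cm=scene.pixels_per_cm,
        provenance=prov,
    )


def estimate_correction_matrix(measured_linear: np.ndarray, target_linear: np.ndarray) -> np.ndarray:
    """Least-squares 3x3 linear correction from a color chart.

    Convenience for roughly color-managing inputs from a 24-patch chart
    shot: rows of ``measured_linear`` and ``target_linear`` are linear-RGB
    patch values.  Not part of the measurement path; calibrated inputs are
    a documented precondition of the pipeline.
    """
    measured_linear = np.asarray(measured_linear, dtype=float)
    target_linear = np.asarray(target_linear, dtype=float)
    if measured_linear.shape != target_linear.shape or measured_linear.ndim != 2:
        raise ValueError("patch arrays must be matching N x 3")
    M, *_ = np.linalg.lstsq(measured_linear, target_linear, rcond=None)
    return M.T
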