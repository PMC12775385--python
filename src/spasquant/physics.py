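"""Display windowing and the small analytic acquisition-physics quantities.

Covers the 8-bit lung-window conversion that precedes binarization, the
compression-percentage definition, plunger kinematics (compression
velocity, per-image motion blur for CT and for an optical camera),
circle-equivalent diameters, and the dose-length-product conversion to
effective dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DisplayWindow:
    """Linear CT display window: level and (positive) width in HU.

    The default is the conventional lung window (level -650, width 1500).
    """

    level_hu: float = -650.0
    width_hu: float = 1500.0

    def __post_init__(self) -> None:
        if self.width_hu <= 0:
            raise ValueError("window width must be positive")

    @property
    def low_hu(self) -> float:
        return self.level_hu - self.width_hu / 2.0

    @property
    def high_hu(self) -> float:
        return self.level_hu + self.width_hu / 2.0


LUNG_WINDOW = DisplayWindow()


@dataclass(frozen=True)
class PhysicsParams:
    """Compression-device and acquisition constants.

    stroke_mm: plunger travel per half cycle (15 mm device stroke).
    rotation_s: CT tube rotation time; a half-reconstruction image
    integrates over half a rotation.
    camera_fps: frame rate of the optical reference camera.
    dose_factor: DLP -> effective dose conversion coefficient.
    """

    stroke_mm: float = 15.0
    rotation_s: float = 0.35
    recon: str = "half"
    camera_fps: float = 30.0
    dose_factor: float = 0.014

    def __post_init__(self) -> None:
        if min(self.stroke_mm, self.rotation_s, self.camera_fps,
               self.dose_factor) < 0:
            raise ValueError("physics parameters must be non-negative")
        if self.recon not in ("half", "full"):
            raise ValueError("recon must be 'half' or 'full'")


def window_to_8bit(pixels: np.ndarray, win: DisplayWindow = LUNG_WINDOW) -> np.ndarray:
    """Map HU linearly onto [0, 255] under a display window.

    Values at or below ``level - width/2`` map to 0, at or above
    ``level + width/2`` to 255; rounding is half-up for platform
    reproducibility.  Accepts a bare array or anything with a
    ``pixels`` attribute (e.g. ``CTImage``).
    """
    hu = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    scaled = (hu - win.low_hu) / win.width_hu * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def compression_percentage(length_mm: float, length0_mm: float) -> float:
    """Percent compression from current and uncompressed longitudinal extents."""
    if length0_mm <= 0 or length_mm <= 0:
        raise ValueError("lengths must be positive")
    if length_mm > length0_mm:
        raise ValueError("current length exceeds uncompressed length")
    return (1.0 - length_mm / length0_mm) * 100.0


def compression_velocity(params: PhysicsParams, cycle_s: float) -> float:
    """Plunger speed (mm/s): full stroke traversed in half a cycle."""
    if cycle_s <= 0:
        raise ValueError("cycle_s must be positive")
    return params.stroke_mm / (cycle_s / 2.0)


def motion_blur_ct(params: PhysicsParams, cycle_s: float) -> float:
    """Phantom travel (mm) during one CT image's temporal window.

    Half reconstruction integrates over half a tube rotation, full
    reconstruction over a whole one.
    """
    window_s = params.rotation_s / 2.0 if params.recon == "half" else params.rotation_s
    return compression_velocity(params, cycle_s) * window_s


def motion_blur_camera(params: PhysicsParams, cycle_s: float) -> float:
    """Phantom travel (mm) during one camera frame."""
    if params.camera_fps <= 0:
        raise ValueError("camera_fps must be positive")
    return compression_velocity(params, cycle_s) / params.camera_fps


def circle_equivalent_diameter(area_mm2: float) -> float:
    """Diameter of the circle with the given area."""
    if area_mm2 < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area_mm2 / math.pi)


def effective_dose(dlp: float, params: PhysicsParams = PhysicsParams()) -> float:
    """Effective dose as dose-length product times the conversion factor."""
    if dlp < 0:
        raise ValueError("dlp must be non-negative")
    return dlp * params.dose_factor
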