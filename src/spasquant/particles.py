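"""Moment-preserving binarization and size-gated particle counting.

The windowed 8-bit image is thresholded with the moment-preserving
(Tsai) rule — the binary two-level image keeps the first three
gray-level moments of the original histogram — air becomes the white
foreground phase, connected components are labeled, and components are
counted inside a physical size gate with half-open sub-bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .physics import DisplayWindow, LUNG_WINDOW, window_to_8bit

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def build_histogram(img8: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram of an 8-bit image."""
    img8 = np.asarray(img8)
    if img8.size == 0:
        raise ValueError("empty image")
    if img8.dtype != np.uint8:
        if img8.min() < 0 or img8.max() > 255:
            raise ValueError("image values outside [0, 255]")
        img8 = img8.astype(np.uint8)
    return np.bincount(img8.ravel(), minlength=256).astype(np.int64)


def _histogram_moments(hist: np.ndarray) -> tuple[float, float, float]:
    p = hist / hist.sum()
    g = np.arange(256.0)
    return float((p * g).sum()), float((p * g**2).sum()), float((p * g**3).sum())


def moments_threshold(hist: np.ndarray) -> int:
    """Moment-preserving (Tsai) threshold of a 256-bin histogram.

    A threshold ``t`` splits gray levels into the dark class ``g <= t``
    and bright class ``g > t``.  Replacing each class by a single
    representative level that preserves the histogram's mean and
    variance exactly leaves one degree of freedom: the returned ``t``
    minimizes the resulting third-moment mismatch (ties broken toward
    the smaller threshold).  Degenerate histograms (zero variance) fall
    back to the mean gray level.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,) or hist.sum() <= 0 or (hist < 0).any():
        raise ValueError("hist must be 256 non-negative counts with positive sum")
    m1, m2, m3 = _histogram_moments(hist)
    cd = m2 - m1 * m1
    if cd < 1e-12:
        return int(round(m1))
    q = np.cumsum(hist) / hist.sum()
    valid = (q > 1e-12) & (q < 1.0 - 1e-12)
    if not valid.any():
        return int(round(m1))
    qv = q[valid]
    # two-point support matching mean m1 and variance cd at mass split qv
    za = m1 - np.sqrt(cd * (1.0 - qv) / qv)
    zb = m1 + np.sqrt(cd * qv / (1.0 - qv))
    mismatch = np.abs(qv * za**3 + (1.0 - qv) * zb**3 - m3)
    idx = np.flatnonzero(valid)
    # np.argmin returns the first minimum: ties go to the smaller threshold
    return int(idx[np.argmin(mismatch)])


@dataclass
class BinaryImage:
    """Boolean mask with air/SPAS as the foreground (white) phase."""

    pixels: np.ndarray
    pixel_mm: float
    threshold_used: int | None = None
    polarity: str = "air-as-foreground"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")


def binarize(img8: np.ndarray, t: int, pixel_mm: float = 1.0) -> BinaryImage:
    """Foreground = gray level strictly below ``t`` (air is dark).

    Note ``moments_threshold`` defines the dark class as ``g <= t``; to
    apply it here pass ``t + 1`` (as :func:`count_spas_image` does).
    """
    if not 0 <= t <= 255:
        raise ValueError("threshold must be in [0, 255]")
    img8 = np.asarray(img8)
    return BinaryImage(img8 < t, pixel_mm, threshold_used=int(t))


@dataclass
class Particle:
    label: int
    pixel_count: int
    area_mm2: float
    centroid: tuple[float, float]      # (row, col) in pixel coordinates
    bbox: tuple[int, int, int, int]    # (rmin, cmin, rmax, cmax), exclusive max


@dataclass
class ParticleSet:
    particles: list[Particle]
    source_threshold: int | None
    pixel_mm: float

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.array([p.area_mm2 for p in self.particles])


def label_particles(binary: BinaryImage, connectivity: int = 8) -> ParticleSet:
    """Connected components of the foreground (default 8-connectivity)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, n = ndimage.label(binary.pixels, structure=structure)
    particles: list[Particle] = []
    if n:
        counts = np.bincount(labels.ravel())[1:]
        centroids = ndimage.center_of_mass(binary.pixels, labels, range(1, n + 1))
        slices = ndimage.find_objects(labels)
        px2 = binary.pixel_mm**2
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            particles.append(Particle(
                label=lab,
                pixel_count=int(counts[lab - 1]),
                area_mm2=float(counts[lab - 1]) * px2,
                centroid=tuple(float(c) for c in centroids[lab - 1]),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            ))
    return ParticleSet(particles, binary.threshold_used, binary.pixel_mm)


@dataclass(frozen=True)
class SizeGate:
    """Physical area gate with half-open sub-bins [lo, hi) in mm^2."""

    bins: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 7.0)

    def __post_init__(self) -> None:
        if len(self.bins) < 2 or any(b <= a for a, b in zip(self.bins, self.bins[1:])):
            raise ValueError("bin edges must be strictly increasing, length >= 2")

    @property
    def min_area_mm2(self) -> float:
        return self.bins[0]

    @property
    def max_area_mm2(self) -> float:
        return self.bins[-1]

    @property
    def bin_labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(self.bins, self.bins[1:])]


@dataclass
class SpasCounts:
    total: int
    per_bin: dict[str, int]
    gate: SizeGate

    def as_series(self) -> pd.Series:
        return pd.Series({"total": self.total, **self.per_bin})


def count_spas(particles: ParticleSet, gate: SizeGate = SizeGate()) -> SpasCounts:
    """Count particles inside ``[min, max)`` overall and per half-open bin."""
    areas = particles.areas_mm2
    edges = np.asarray(gate.bins)
    total = int(((areas >= edges[0]) & (areas < edges[-1])).sum())
    per_bin = {
        lab: int(((areas >= lo) & (areas < hi)).sum())
        for lab, lo, hi in zip(gate.bin_labels, edges[:-1], edges[1:])
    }
    return SpasCounts(total, per_bin, gate)


def count_spas_image(
    image,
    window: DisplayWindow = LUNG_WINDOW,
    gate: SizeGate = SizeGate(),
    connectivity: int = 8,
) -> tuple[SpasCounts, int]:
    """Window -> moments threshold -> binarize -> label -> gate, in one call.

    ``image`` is a ``CTImage`` (or a bare HU array plus ``pixel_mm``
    attribute).  Returns the counts and the threshold used.  The dark
    class of the moments rule (``g <= t``) is the foreground, hence the
    ``t + 1`` when binarizing with the strictly-below convention.
    """
    img8 = window_to_8bit(image, window)
    t = moments_threshold(build_histogram(img8))
    binary = binarize(img8, min(t + 1, 255), pixel_mm=image.pixel_mm)
    return count_spas(label_particles(binary, connectivity), gate), t
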