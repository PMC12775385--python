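"""Multi-threshold Betti-number quantification of grayscale images.

For a binary image, ``b0`` counts foreground components (8-connected)
and ``b1`` counts holes — background components (4-connected) that do
not touch the image border.  The complementary connectivity pair avoids
the digital-topology paradox.  Sweeping the binarization threshold over
all 256 gray levels ("continuous binarization") yields per-threshold
curves; the peak ``b0`` summarizes the total number of resolvable air
spaces independent of any single display threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .particles import BinaryImage, _STRUCT_4, _STRUCT_8
from .physics import DisplayWindow, LUNG_WINDOW, window_to_8bit


def betti_numbers(binary: BinaryImage, min_area_mm2: float | None = None) -> tuple[int, int]:
    """(b0, b1) of a binary image.

    ``b0``: foreground components under 8-connectivity, optionally
    ignoring components smaller than ``min_area_mm2``.
    ``b1``: background components under 4-connectivity that do not touch
    the border (holes).
    """
    fg = binary.pixels
    labels, n_fg = ndimage.label(fg, structure=_STRUCT_8)
    if min_area_mm2 and n_fg:
        counts = np.bincount(labels.ravel())[1:]
        b0 = int((counts * binary.pixel_mm**2 >= min_area_mm2).sum())
    else:
        b0 = n_fg

    bg_labels, n_bg = ndimage.label(~fg, structure=_STRUCT_4)
    if n_bg:
        border = np.concatenate([
            bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]
        ])
        touching = np.unique(border)
        b1 = n_bg - int((touching > 0).sum())
    else:
        b1 = 0
    return b0, b1


@dataclass
class HomologyCurve:
    """Per-threshold (b0, b1) over the full 8-bit sweep."""

    thresholds: np.ndarray
    b0: np.ndarray
    b1: np.ndarray

    @property
    def peak_b0(self) -> int:
        return int(self.b0.max())

    @property
    def peak_threshold(self) -> int:
        """Smallest threshold attaining the b0 maximum."""
        return int(self.thresholds[int(np.argmax(self.b0))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "b0": self.b0, "b1": self.b1}
        )


def homology_curve(
    img8: np.ndarray,
    pixel_mm: float = 1.0,
    min_area_mm2: float | None = None,
) -> HomologyCurve:
    """Sweep all 256 thresholds with air (dark) as foreground.

    At threshold ``t`` the foreground is ``gray < t``, so ``t = 0``
    gives an empty image with ``b0 = b1 = 0`` and the sweep is a
    filtration: the foreground only grows with ``t``.
    """
    img8 = np.asarray(img8)
    if img8.size == 0:
        raise ValueError("empty image")
    thresholds = np.arange(256)
    b0 = np.zeros(256, dtype=int)
    b1 = np.zeros(256, dtype=int)
    for t in thresholds:
        if t == 0:
            continue  # empty foreground
        binary = BinaryImage(img8 < t, pixel_mm)
        b0[t], b1[t] = betti_numbers(binary, min_area_mm2)
    return HomologyCurve(thresholds, b0, b1)


def peak_b0_series(
    images,
    window: DisplayWindow = LUNG_WINDOW,
    min_area_mm2: float | None = None,
) -> pd.DataFrame:
    """Peak b0 per image, tabulated against compression percentage.

    ``images`` is an iterable of ``CTImage``.  Returns one row per image
    with columns mode, compression_pct, peak_b0, peak_threshold.
    """
    rows = []
    for img in images:
        curve = homology_curve(window_to_8bit(img, window), img.pixel_mm,
                               min_area_mm2)
        rows.append(dict(
            mode=img.mode,
            compression_pct=img.compression_pct,
            peak_b0=curve.peak_b0,
            peak_threshold=curve.peak_threshold,
        ))
    if not rows:
        raise ValueError("no images supplied")
    return pd.DataFrame(rows)
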