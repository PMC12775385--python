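"""Profile-based FWHM sizing of individual air spaces.

Each air space appears as an intensity trough on lines drawn through
its center along the longitudinal (compression) and transverse axes.
The lumen diameter along a line is the full width at half maximum of
the trough: the distance between the two half-depth crossings relative
to a local baseline.  The elliptical area follows as
``pi/4 * d_long * d_trans``.  Comparing CT measurements with the
high-resolution reference rendering gives per-dimension deviations;
repeating the measurement across compression phases gives per-SPAS size
trajectories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import CTImage, PhantomTruth, Spas

logger = logging.getLogger(__name__)

LONGITUDINAL = "longitudinal"
TRANSVERSE = "transverse"

#: minimum trough depth (HU) for a measurable lumen
DEFAULT_CONTRAST_FLOOR_HU = 50.0


@dataclass
class ProfileLine:
    """Intensity samples along a line through an air-space center."""

    center_mm: tuple[float, float]   # (y, x) physical
    direction: str                   # LONGITUDINAL (axis 0) or TRANSVERSE
    half_length_mm: float
    sampling_mm: float
    positions_mm: np.ndarray         # signed offsets from the center
    values: np.ndarray


def extract_profile(
    img: CTImage,
    center_mm: tuple[float, float],
    direction: str,
    half_length_mm: float,
) -> ProfileLine:
    """Bilinearly sampled profile at a quarter-pixel step.

    ``center_mm`` is (y, x) with y along the longitudinal axis.  The
    sample count is odd with the center sample exactly at the center.
    Lines extending outside the image are rejected.
    """
    if direction not in (LONGITUDINAL, TRANSVERSE):
        raise ValueError(f"unknown direction {direction!r}")
    if half_length_mm <= 0:
        raise ValueError("half_length_mm must be positive")
    sampling = img.pixel_mm / 4.0
    # floor: samples never extend beyond the requested half length
    n_half = max(2, int(math.floor(half_length_mm / sampling)))
    offsets = np.arange(-n_half, n_half + 1) * sampling
    cy, cx = center_mm
    if direction == LONGITUDINAL:
        ys, xs = cy + offsets, np.full_like(offsets, cx)
    else:
        ys, xs = np.full_like(offsets, cy), cx + offsets
    ny, nx = img.shape
    tol = 1e-9
    if (ys.min() < -tol or xs.min() < -tol
            or ys.max() > ny * img.pixel_mm + tol
            or xs.max() > nx * img.pixel_mm + tol):
        raise ValueError("profile line extends outside the image")
    # pixel centers at (i + 0.5) * pixel_mm
    rows = ys / img.pixel_mm - 0.5
    cols = xs / img.pixel_mm - 0.5
    values = ndimage.map_coordinates(
        img.pixels, np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return ProfileLine((cy, cx), direction, half_length_mm, sampling,
                       offsets, values)


def fwhm_width(
    profile: ProfileLine,
    contrast_floor: float = DEFAULT_CONTRAST_FLOOR_HU,
    search_half_mm: float | None = None,
) -> float | None:
    """Full width at half maximum of an intensity trough, in mm.

    In a porous section the flanks of the window often dip into
    neighbouring air spaces, so quantile-based baselines fail; instead
    the baseline is the wall level that both flanks actually reach: the
    smaller of the two per-side maxima of a lightly median-smoothed
    profile.  The half level sits midway between the baseline and the
    trough minimum.  Walking outward from the minimum, the first
    crossings of the half level on each side are located by linear
    interpolation.  Returns ``None`` (not measurable) when the trough
    depth is below ``contrast_floor`` or a crossing is missing.

    ``search_half_mm`` restricts the minimum search to that distance
    from the profile center, so a deeper neighbouring air space inside
    the window cannot hijack the trough.
    """
    v = np.asarray(profile.values, dtype=float)
    n = v.size
    if n < 5:
        return None
    if search_half_mm is not None:
        inside = np.abs(profile.positions_mm) <= search_half_mm
        if not inside.any():
            inside = np.abs(profile.positions_mm) <= profile.sampling_mm
        cand = np.where(inside)[0]
        imin = int(cand[np.argmin(v[cand])])
    else:
        imin = int(np.argmin(v))
    if imin == 0 or imin == n - 1:
        return None
    # median-of-5 smoothing suppresses single-sample noise spikes before
    # the per-side maxima are taken
    vs = ndimage.median_filter(v, size=5, mode="nearest")
    baseline = min(vs[:imin].max(), vs[imin + 1:].max())
    depth = baseline - v[imin]
    if depth < contrast_floor:
        return None
    half = baseline - depth / 2.0

    def cross(idx_range) -> float | None:
        prev = imin
        for i in idx_range:
            if v[i] >= half:
                # linear interpolation between samples prev and i
                frac = (half - v[prev]) / (v[i] - v[prev])
                return profile.positions_mm[prev] + frac * (
                    profile.positions_mm[i] - profile.positions_mm[prev])
            prev = i
        return None

    left = cross(range(imin - 1, -1, -1))
    right = cross(range(imin + 1, n))
    if left is None or right is None:
        return None
    return float(right - left)


@dataclass
class SpasMeasurement:
    """FWHM diameters and elliptical area of one SPAS on one image."""

    spas_id: int
    mode: str
    compression_pct: float
    d_long_mm: float | None
    d_trans_mm: float | None
    measurable: bool

    @property
    def area_mm2(self) -> float | None:
        if not self.measurable:
            return None
        return math.pi / 4.0 * self.d_long_mm * self.d_trans_mm

    def as_dict(self) -> dict:
        return dict(
            spas_id=self.spas_id, mode=self.mode,
            compression_pct=self.compression_pct,
            d_long_mm=self.d_long_mm, d_trans_mm=self.d_trans_mm,
            area_mm2=self.area_mm2, measurable=self.measurable,
        )


def measure_spas(
    img: CTImage,
    spas: Spas,
    half_length_mm: float | None = None,
    contrast_floor: float = DEFAULT_CONTRAST_FLOOR_HU,
) -> SpasMeasurement:
    """Longitudinal and transverse FWHM diameters of one air space.

    The profile half-length defaults to twice the true diameter along
    each axis, capped at 6 mm, and is clipped to the image bounds.  The
    center comes from ground truth, standing in for manual placement.
    """
    center = (spas.center_y_mm, spas.center_x_mm)
    ny, nx = img.shape
    widths = {}
    for direction, d_true in ((LONGITUDINAL, spas.d_long_mm),
                              (TRANSVERSE, spas.d_trans_mm)):
        hl = half_length_mm if half_length_mm is not None else min(
            2.0 * max(d_true, 0.5), 6.0)
        # clip to stay inside the image
        if direction == LONGITUDINAL:
            hl = min(hl, center[0], ny * img.pixel_mm - center[0])
        else:
            hl = min(hl, center[1], nx * img.pixel_mm - center[1])
        if hl <= img.pixel_mm:
            widths[direction] = None
            continue
        prof = extract_profile(img, center, direction, hl)
        # the trough belongs to this SPAS: search near its true center
        widths[direction] = fwhm_width(prof, contrast_floor,
                                       search_half_mm=max(d_true / 2.0,
                                                          img.pixel_mm))
    measurable = widths[LONGITUDINAL] is not None and widths[TRANSVERSE] is not None
    return SpasMeasurement(
        spas_id=spas.id, mode=img.mode, compression_pct=img.compression_pct,
        d_long_mm=widths[LONGITUDINAL], d_trans_mm=widths[TRANSVERSE],
        measurable=measurable,
    )


def measurements_frame(measurements) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in measurements])


def deviation_table(ct_meas: pd.DataFrame, ref_meas: pd.DataFrame) -> pd.DataFrame:
    """CT-minus-reference deviations per (SPAS, dimension).

    Inputs are measurement tables (``measurements_frame`` layout) paired
    on ``spas_id`` and ``phase`` (falling back to exact
    ``compression_pct`` when no phase column exists).  Unpaired or
    unmeasurable rows are logged and skipped.  The compression-percentage
    mismatch between the CT and reference images is carried as a
    covariate column.
    """
    key = ["spas_id", "phase"] if "phase" in ct_meas and "phase" in ref_meas \
        else ["spas_id", "compression_pct"]
    merged = ct_meas.merge(ref_meas, on=key, how="outer",
                           suffixes=("_ct", "_ref"), indicator=True)
    unpaired = merged[merged["_merge"] != "both"]
    if len(unpaired):
        logger.warning("deviation_table: %d unpaired measurement rows skipped",
                       len(unpaired))
    merged = merged[merged["_merge"] == "both"]
    rows = []
    for _, r in merged.iterrows():
        if not (r["measurable_ct"] and r["measurable_ref"]):
            continue
        if "compression_pct" in key:
            comp_dev = 0.0
        else:
            comp_dev = r["compression_pct_ct"] - r["compression_pct_ref"]
        for dim, col in (("longitudinal", "d_long_mm"),
                         ("transverse", "d_trans_mm"),
                         ("area", "area_mm2")):
            rows.append(dict(
                spas_id=r["spas_id"], mode=r["mode_ct"], dimension=dim,
                ct_value=r[f"{col}_ct"], reference_value=r[f"{col}_ref"],
                deviation=r[f"{col}_ct"] - r[f"{col}_ref"],
                compression_pct_deviation=comp_dev,
            ))
    return pd.DataFrame(rows)


def select_trackable_spas(truths: list[PhantomTruth],
                          gate_min: float = 0.5, gate_max: float = 7.0,
                          max_spas: int = 10) -> list[int]:
    """Ground-truth-driven stand-in for the visual selection of SPAS.

    Returns ids of air spaces that are open at every phase and inside
    the size gate at the uncompressed phase, largest-first, at most
    ``max_spas``.
    """
    open_at_all = set(s.id for s in truths[0].spas)
    for t in truths:
        open_at_all &= {s.id for s in t.open_spas}
    phase0 = {s.id: s for s in truths[0].spas}
    eligible = [sid for sid in open_at_all
                if gate_min <= phase0[sid].area_mm2 < gate_max]
    eligible.sort(key=lambda sid: -phase0[sid].area_mm2)
    return eligible[:max_spas]


def trajectory_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-SPAS size trajectories across compression.

    Expects a measurement table with one row per (spas_id, mode, phase).
    SPAS that stop being measurable mid-series are truncated at the
    first failure and flagged.  Requires >= 2 phases per SPAS.
    """
    df = measurements.sort_values(["spas_id", "mode", "compression_pct"])
    rows = []
    for (sid, mode), grp in df.groupby(["spas_id", "mode"], sort=False):
        if len(grp) < 2:
            raise ValueError(f"SPAS {sid} ({mode}) has fewer than 2 phases")
        truncated = False
        for phase, (_, r) in enumerate(grp.iterrows()):
            if not r["measurable"]:
                truncated = True
                break
            rows.append(dict(
                spas_id=sid, mode=mode, phase=phase,
                compression_pct=r["compression_pct"],
                d_long_mm=r["d_long_mm"], d_trans_mm=r["d_trans_mm"],
                area_mm2=r["area_mm2"], truncated=False,
            ))
        if truncated and rows:
            for row in rows:
                if row["spas_id"] == sid and row["mode"] == mode:
                    row["truncated"] = True
    return pd.DataFrame(rows)
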