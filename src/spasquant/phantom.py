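"""Synthetic sponge-phantom cross-sections and their CT renderings.

A phantom is a rectangular sponge cross-section containing elliptical
simulated peripheral air spaces (SPAS).  The section is compressed
uniaxially along the *longitudinal* axis (array axis 0); air spaces
shrink faster than the bulk so that small lumens close at high
compression, mimicking the disappearance of peripheral air spaces at
end-expiration.  Renderings emulate an ultra-high-resolution (UHR) CT
mode, a normal-resolution (NR) mode, and a near-ideal high-resolution
reference ("smartphone" stand-in).

Coordinate convention: physical coordinates in mm, ``y`` along the
longitudinal/compression axis (array axis 0), ``x`` transverse (axis 1);
pixel centers sit at ``(i + 0.5) * pixel_mm``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

AIR_HU_DEFAULT = -1000.0

#: sigma (mm) of a Gaussian PSF whose MTF falls to 5% at frequency f:
#: MTF(f) = exp(-2 pi^2 sigma^2 f^2) = 0.05  =>  sigma = sqrt(ln 20 / 2 pi^2) / f
_MTF5_SIGMA_COEF = math.sqrt(math.log(20.0) / (2.0 * math.pi**2))


def mtf5_to_sigma_mm(mtf5_cyc_per_mm: float) -> float:
    """PSF Gaussian sigma (mm) from the 5% MTF frequency (cycles/mm)."""
    if mtf5_cyc_per_mm <= 0:
        raise ValueError("mtf5_cyc_per_mm must be positive")
    return _MTF5_SIGMA_COEF / mtf5_cyc_per_mm


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an uncompressed sponge cross-section.

    Defaults emulate a ~60 x 35 mm cellulose sponge slice whose mean CT
    density sits near -776 HU, with air-space areas spanning the size
    gate (0.5-7 mm^2) plus out-of-gate sizes on both ends.
    """

    width_mm: float = 60.0            # transverse extent
    height_mm: float = 35.0           # longitudinal (compression) extent
    n_spas: int = 110
    area_range_mm2: tuple[float, float] = (0.2, 15.0)
    aspect_range: tuple[float, float] = (1.0, 3.0)  # d_trans / d_long >= 1
    min_gap_mm: float = 0.4
    matrix_hu: float | None = None    # None -> calibrated to target_mean_hu
    air_hu: float = AIR_HU_DEFAULT
    target_mean_hu: float = -776.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("section extents must be positive")
        if self.area_range_mm2[0] <= 0 or self.area_range_mm2[0] > self.area_range_mm2[1]:
            raise ValueError("area_range_mm2 must be positive and ordered")
        if self.aspect_range[0] < 1.0 or self.aspect_range[0] > self.aspect_range[1]:
            raise ValueError("aspect_range must be >= 1 and ordered")
        if self.min_gap_mm < 0:
            raise ValueError("min_gap_mm must be non-negative")
        if self.n_spas < 0:
            raise ValueError("n_spas must be non-negative")
        if self.matrix_hu is not None and self.air_hu >= self.matrix_hu:
            raise ValueError("air_hu must be below matrix_hu")


@dataclass
class Spas:
    """One elliptical air space; axes aligned with the section."""

    id: int
    center_x_mm: float   # transverse
    center_y_mm: float   # longitudinal
    d_long_mm: float
    d_trans_mm: float
    area_mm2: float
    closed: bool = False

    def recompute_area(self) -> None:
        self.area_mm2 = math.pi / 4.0 * self.d_long_mm * self.d_trans_mm


@dataclass
class PhantomTruth:
    """Ground-truth geometry of one cross-section at one compression state."""

    spas: list[Spas]
    section_length_mm: float
    compression_pct: float
    parent_spec: PhantomSpec
    matrix_hu: float
    truth_id: str = ""

    @property
    def open_spas(self) -> list[Spas]:
        return [s for s in self.spas if not s.closed]

    def air_fraction(self) -> float:
        """Open-SPAS area over current section area."""
        area = self.section_length_mm * self.parent_spec.width_mm
        return sum(s.area_mm2 for s in self.open_spas) / area

    def mean_hu(self) -> float:
        """Analytic section-mean CT number of the two-level field."""
        f = self.air_fraction()
        return f * self.parent_spec.air_hu + (1.0 - f) * self.matrix_hu


@dataclass(frozen=True)
class ImagingMode:
    """One rendering chain: pixel grid, PSF, motion blur, noise.

    ``mtf5_cyc_per_mm`` is the frequency at which the modulation
    transfer function falls to 5%; the PSF is the Gaussian with that
    cutoff.  Noise defaults are the 20 mA noise magnitudes of the two
    scanner modes.  ``blur_mm`` is the per-image travel of the phantom
    during the reconstruction window, applied as a box kernel along the
    longitudinal axis.
    """

    name: str
    pixel_mm: float
    mtf5_cyc_per_mm: float
    noise_sd_hu: float = 0.0
    blur_mm: float = 0.0
    slice_label: str = ""

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.noise_sd_hu < 0 or self.blur_mm < 0:
            raise ValueError("noise_sd_hu and blur_mm must be non-negative")
        if self.name == "REFERENCE":
            if self.noise_sd_hu != 0:
                raise ValueError("REFERENCE mode is noiseless")
            if self.psf_sigma_mm >= self.pixel_mm:
                raise ValueError("REFERENCE PSF must be narrower than one pixel")

    @property
    def psf_sigma_mm(self) -> float:
        return mtf5_to_sigma_mm(self.mtf5_cyc_per_mm)

    @staticmethod
    def uhr(noise_sd_hu: float = 14.6, blur_mm: float = 0.0) -> "ImagingMode":
        """Ultra-high-resolution CT: 0.25 mm pixels, MTF5% = 1.26 cyc/mm."""
        return ImagingMode("UHR", 0.25, 1.26, noise_sd_hu, blur_mm)

    @staticmethod
    def nr(noise_sd_hu: float = 17.8, blur_mm: float = 0.0) -> "ImagingMode":
        """Normal-resolution CT: 0.5 mm pixels, MTF5% = 0.61 cyc/mm."""
        return ImagingMode("NR", 0.5, 0.61, noise_sd_hu, blur_mm)

    @staticmethod
    def reference() -> "ImagingMode":
        """Idealized optical reference: 0.05 mm grid, near-delta PSF, no noise."""
        return ImagingMode("REFERENCE", 0.05, 20.0, 0.0, 0.0)


@dataclass
class CTImage:
    """2-D CT-number image with physical spacing and provenance."""

    pixels: np.ndarray
    pixel_mm: float
    mode: str
    compression_pct: float = 0.0
    truth_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 16:
            raise ValueError("image must be 2-D with both dimensions >= 16")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _calibrate_matrix_hu(spec: PhantomSpec, total_spas_area: float) -> float:
    """Matrix HU so that the two-level section mean equals target_mean_hu."""
    f = total_spas_area / (spec.width_mm * spec.height_mm)
    if f >= 1.0:
        raise ValueError("air spaces exceed the section area")
    matrix = (spec.target_mean_hu - f * spec.air_hu) / (1.0 - f)
    if matrix <= spec.air_hu:
        raise ValueError("calibrated matrix HU not above air HU; "
                         "check target_mean_hu / area settings")
    return matrix


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Sample an uncompressed cross-section satisfying ``spec``.

    Areas are drawn log-uniformly over ``area_range_mm2`` and aspect
    ratios uniformly over ``aspect_range`` (long axis transverse).
    Placement uses rejection sampling with a conservative bounding-circle
    criterion so that walls between neighbouring ellipses are at least
    ``min_gap_mm`` thick.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.area_range_mm2
    areas = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n_spas))
    aspects = rng.uniform(*spec.aspect_range, spec.n_spas)
    # place big ones first: improves packing without changing the law
    order = np.argsort(-areas)

    placed: list[Spas] = []
    budget = 10 * spec.n_spas
    rejections = 0
    for k in order:
        area, aspect = float(areas[k]), float(aspects[k])
        d_long = math.sqrt(4.0 * area / (math.pi * aspect))
        d_trans = aspect * d_long
        r = d_trans / 2.0  # bounding-circle radius (d_trans >= d_long)
        while True:
            cx = rng.uniform(r, spec.width_mm - r)
            cy = rng.uniform(d_long / 2.0, spec.height_mm - d_long / 2.0)
            ok = all(
                math.hypot(cx - s.center_x_mm, cy - s.center_y_mm)
                >= r + s.d_trans_mm / 2.0 + spec.min_gap_mm
                for s in placed
            )
            if ok:
                placed.append(Spas(int(k), cx, cy, d_long, d_trans, area))
                break
            rejections += 1
            if rejections > budget:
                raise RuntimeError(
                    f"could not place {spec.n_spas} air spaces in "
                    f"{budget} rejection attempts; reduce n_spas, the "
                    f"area range, or min_gap_mm"
                )
    placed.sort(key=lambda s: s.id)
    total_area = float(np.sum([s.area_mm2 for s in placed])) if placed else 0.0
    matrix_hu = (spec.matrix_hu if spec.matrix_hu is not None
                 else _calibrate_matrix_hu(spec, total_area))
    return PhantomTruth(
        spas=placed,
        section_length_mm=spec.height_mm,
        compression_pct=0.0,
        parent_spec=spec,
        matrix_hu=matrix_hu,
        truth_id=f"seed{spec.seed}-c0",
    )


def compress_phantom(
    truth: PhantomTruth,
    compression_pct: float,
    kappa: float = 1.5,
    closure_mm: float = 0.75,
) -> PhantomTruth:
    """Uniaxially compress an uncompressed truth by ``compression_pct``.

    The bulk shrinks by ``1 - c/100`` along the longitudinal axis (SPAS
    centers move with it); each air space's longitudinal diameter shrinks
    by ``1 - kappa*c/100`` with ``kappa >= 1``, so lumens close faster
    than the bulk.  Air spaces whose longitudinal diameter drops below
    ``closure_mm`` are flagged closed (kept in the truth, excluded from
    rendering).  Transverse diameters are unchanged.
    """
    if not 0.0 <= compression_pct <= 45.0:
        raise ValueError("compression_pct must be in [0, 45]")
    if kappa < 1.0:
        raise ValueError("kappa must be >= 1")
    if truth.compression_pct != 0.0:
        raise ValueError("compress_phantom expects an uncompressed truth")
    if compression_pct == 0.0:
        return truth
    bulk = 1.0 - compression_pct / 100.0
    lumen = 1.0 - kappa * compression_pct / 100.0
    new_spas = []
    for s in truth.spas:
        ns = Spas(s.id, s.center_x_mm, s.center_y_mm * bulk,
                  s.d_long_mm * lumen, s.d_trans_mm, 0.0, s.closed)
        if ns.d_long_mm < closure_mm:
            ns.d_long_mm = max(ns.d_long_mm, 0.0)
            ns.closed = True
        ns.recompute_area()
        new_spas.append(ns)
    base = truth.truth_id.rsplit("-c", 1)[0] if truth.truth_id else "truth"
    return PhantomTruth(
        spas=new_spas,
        section_length_mm=truth.section_length_mm * bulk,
        compression_pct=compression_pct,
        parent_spec=truth.parent_spec,
        matrix_hu=truth.matrix_hu,
        truth_id=f"{base}-c{compression_pct:g}",
    )


def _rasterize(truth: PhantomTruth, pixel_mm: float, supersample: int) -> np.ndarray:
    """Area-weighted rasterization of the two-level HU field."""
    spec = truth.parent_spec
    ny = max(16, round(truth.section_length_mm / pixel_mm))
    nx = max(16, round(spec.width_mm / pixel_mm))
    ss = supersample
    sub = pixel_mm / ss
    img = np.full((ny * ss, nx * ss), truth.matrix_hu, dtype=float)
    for s in truth.open_spas:
        ry, rx = s.d_long_mm / 2.0, s.d_trans_mm / 2.0
        if ry <= 0 or rx <= 0:
            continue
        i0 = max(0, int((s.center_y_mm - ry) / sub) - 1)
        i1 = min(img.shape[0], int((s.center_y_mm + ry) / sub) + 2)
        j0 = max(0, int((s.center_x_mm - rx) / sub) - 1)
        j1 = min(img.shape[1], int((s.center_x_mm + rx) / sub) + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        yy = (np.arange(i0, i1) + 0.5) * sub - s.center_y_mm
        xx = (np.arange(j0, j1) + 0.5) * sub - s.center_x_mm
        mask = (yy[:, None] / ry) ** 2 + (xx[None, :] / rx) ** 2 <= 1.0
        block = img[i0:i1, j0:j1]
        block[mask] = spec.air_hu
    # block-average down to the acquisition grid
    return img.reshape(ny, ss, nx, ss).mean(axis=(1, 3))


def render_image(
    truth: PhantomTruth,
    mode: ImagingMode,
    seed: int | np.random.SeedSequence | None = None,
    supersample: int = 4,
) -> CTImage:
    """Render a truth through one imaging chain.

    Pipeline: area-weighted supersampled rasterization -> isotropic
    Gaussian PSF fixed by the mode's 5% MTF frequency -> longitudinal
    box motion blur of length ``blur_mm`` -> additive white Gaussian
    noise of ``noise_sd_hu``.  Deterministic given (truth, mode, seed).
    """
    if supersample < 4:
        raise ValueError("supersample must be >= 4 for area weighting")
    img = _rasterize(truth, mode.pixel_mm, supersample)

    sigma_px = mode.psf_sigma_mm / mode.pixel_mm
    if sigma_px < 0.25:
        logger.info("PSF sigma %.3f px < 1/4 px for mode %s: applied as identity",
                    sigma_px, mode.name)
    else:
        img = ndimage.gaussian_filter(img, sigma_px, mode="nearest")

    blur_px = round(mode.blur_mm / mode.pixel_mm)
    if blur_px >= 2:
        img = ndimage.uniform_filter1d(img, blur_px, axis=0, mode="nearest")

    if mode.noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, mode.noise_sd_hu, img.shape)

    return CTImage(img, mode.pixel_mm, mode.name,
                   truth.compression_pct, truth.truth_id)


DEFAULT_PHASES = (0.0, 12.0, 24.0, 35.0)


def make_phase_series(
    spec: PhantomSpec,
    phases: tuple[float, ...] | list[float] = DEFAULT_PHASES,
    modes: tuple[ImagingMode, ...] | list[ImagingMode] = (),
    kappa: float = 1.5,
    closure_mm: float = 0.75,
) -> list[tuple[CTImage, PhantomTruth]]:
    """One geometry rendered at several compression phases and modes.

    The default phases {0, 12, 24, 35}% stand for peak inspiration and
    early/middle/late expiration.  Noise seeds are derived from
    ``spec.seed`` and the (phase, mode) cell, so adding a mode never
    perturbs existing renders.
    """
    phases = list(phases)
    if not phases or phases[0] != 0.0:
        raise ValueError("phases must start at 0")
    if any(b <= a for a, b in zip(phases, phases[1:])):
        raise ValueError("phases must be strictly increasing")
    if phases[-1] > 45.0:
        raise ValueError("phases must not exceed 45%")
    if not modes:
        modes = (ImagingMode.uhr(), ImagingMode.nr(), ImagingMode.reference())

    truth0 = generate_phantom(spec)
    out: list[tuple[CTImage, PhantomTruth]] = []
    for pi, pct in enumerate(phases):
        truth = compress_phantom(truth0, pct, kappa=kappa, closure_mm=closure_mm)
        for mi, mode in enumerate(modes):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(1009, pi, mi))
            out.append((render_image(truth, mode, seed=ss), truth))
    return out


def truths_to_frame(truths: list[PhantomTruth]):
    """Long-format table: one row per SPAS per phase."""
    import pandas as pd

    rows = []
    for phase_idx, t in enumerate(truths):
        for s in t.spas:
            rows.append(dict(
                id=s.id, phase=phase_idx, compression_pct=t.compression_pct,
                cx_mm=s.center_x_mm, cy_mm=s.center_y_mm,
                d_long_mm=s.d_long_mm, d_trans_mm=s.d_trans_mm,
                area_mm2=s.area_mm2, closed=s.closed,
            ))
    return pd.DataFrame(rows)
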