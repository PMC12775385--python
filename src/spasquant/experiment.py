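"""End-to-end experiment driver and image file I/O.

Reproduces the study design on synthetic phantoms: ``n_sections``
cross-sections x 4 compression phases x 2 CT modes (UHR, NR) x 2
compression-cycle durations (4 s, 5 s), plus one noiseless reference
rendering per (section, phase).  The cycle duration enters the imaging
chain only through the per-image motion-blur length.  Every stage is
deterministic from ``master_seed``; per-cell noise seeds are derived by
spawn keys so adding modes or cycles never perturbs existing cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import homology as hm
from . import particles as pt
from . import sizing as sz
from . import stats as st
from .phantom import (CTImage, ImagingMode, PhantomSpec, PhantomTruth,
                      compress_phantom, generate_phantom, render_image,
                      truths_to_frame, DEFAULT_PHASES)
from .physics import DisplayWindow, PhysicsParams, motion_blur_ct

logger = logging.getLogger(__name__)

HU_OFFSET = 32768
POSITIONS = ("upper", "median", "lateral")


def write_image(img: CTImage, path: str | Path) -> None:
    """16-bit TIFF (HU + 32768) with a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    stored = np.round(img.pixels + HU_OFFSET)
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError("HU values outside the storable 16-bit range")
    tifffile.imwrite(path, stored.astype(np.uint16))
    sidecar = dict(pixel_mm=img.pixel_mm, mode=img.mode,
                   compression_pct=img.compression_pct, truth_id=img.truth_id)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path) -> CTImage:
    """Read a TIFF + sidecar pair back into a ``CTImage``."""
    import tifffile

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_mm", "mode", "compression_pct"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    if not isinstance(meta["pixel_mm"], (int, float)) or meta["pixel_mm"] <= 0:
        raise ValueError("sidecar field pixel_mm must be a positive number")
    pixels = tifffile.imread(path).astype(float) - HU_OFFSET
    return CTImage(pixels, meta["pixel_mm"], meta["mode"],
                   meta["compression_pct"], meta.get("truth_id"))


@dataclass(frozen=True)
class ExperimentConfig:
    """Full design of one synthetic run."""

    n_sections: int = 14
    phases: tuple[float, ...] = DEFAULT_PHASES
    cycles_s: tuple[float, ...] = (4.0, 5.0)
    master_seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    window: DisplayWindow = field(default_factory=DisplayWindow)
    gate: pt.SizeGate = field(default_factory=pt.SizeGate)
    homology_min_area_mm2: float | None = None
    kappa: float = 1.5
    closure_mm: float = 0.75
    uhr_noise_sd_hu: float = 14.6
    nr_noise_sd_hu: float = 17.8
    n_tracked_spas: int = 10
    output_dir: str | None = None
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if not self.phases or self.phases[0] != 0:
            raise ValueError("phases must start at 0")

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, cls in (("phantom", PhantomSpec), ("physics", PhysicsParams),
                         ("window", DisplayWindow)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                for tup_key in ("area_range_mm2", "aspect_range"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = cls(**sub)
        if "gate" in kwargs and isinstance(kwargs["gate"], (list, tuple)):
            kwargs["gate"] = pt.SizeGate(tuple(kwargs["gate"]))
        for tup_key in ("phases", "cycles_s"):
            if tup_key in kwargs:
                kwargs[tup_key] = tuple(kwargs[tup_key])
        return ExperimentConfig(**kwargs)


@dataclass
class ExperimentResult:
    truths: pd.DataFrame
    counts: pd.DataFrame
    homology: pd.DataFrame
    measurements: pd.DataFrame
    deviations: pd.DataFrame
    trajectories: pd.DataFrame
    summary: dict
    n_ct_images: int


def _section_seed(master_seed: int, section: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(101, section))
    return int(ss.generate_state(1)[0] % (2**31))


def _cell_seed(master_seed: int, section: int, phase_i: int,
               mode_i: int, cycle_i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        master_seed, spawn_key=(202, section, phase_i, mode_i, cycle_i))


def _ct_modes(cfg: ExperimentConfig, cycle_s: float) -> list[ImagingMode]:
    blur = motion_blur_ct(cfg.physics, cycle_s)
    return [ImagingMode.uhr(cfg.uhr_noise_sd_hu, blur),
            ImagingMode.nr(cfg.nr_noise_sd_hu, blur)]


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline over every design cell.

    Stages per cell: phantom generation -> rendering -> lung-window
    8-bit conversion -> moments binarization + gated particle counts ->
    Betti-number threshold sweep (peak b0) -> per-SPAS FWHM sizing
    against the reference rendering -> mixed-model comparisons of UHR
    vs NR.  Stage failures are logged with their design-cell coordinates
    and the run continues.
    """
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    truth_rows, count_rows, hom_rows, meas_rows = [], [], [], []
    dev_frames, traj_frames = [], []
    n_ct_images = 0

    for sec in range(cfg.n_sections):
        position = POSITIONS[sec % len(POSITIONS)]
        spec = replace(cfg.phantom, seed=_section_seed(cfg.master_seed, sec))
        truth0 = generate_phantom(spec)
        truths = [compress_phantom(truth0, c, cfg.kappa, cfg.closure_mm)
                  for c in cfg.phases]
        tf = truths_to_frame(truths)
        tf.insert(0, "section", sec)
        tf.insert(1, "position", position)
        truth_rows.append(tf)

        ref_mode = ImagingMode.reference()
        ref_images = [render_image(t, ref_mode) for t in truths]
        tracked = sz.select_trackable_spas(
            truths, cfg.gate.min_area_mm2, cfg.gate.max_area_mm2,
            cfg.n_tracked_spas)
        spas_by_id = [{s.id: s for s in t.spas} for t in truths]

        # reference measurements per tracked SPAS per phase
        ref_meas = []
        for pi, (img, truth) in enumerate(zip(ref_images, truths)):
            for sid in tracked:
                m = sz.measure_spas(img, spas_by_id[pi][sid])
                row = m.as_dict()
                row.update(section=sec, phase=pi, cycle_s=np.nan)
                ref_meas.append(row)
                meas_rows.append(row)
        ref_df = pd.DataFrame(ref_meas)

        for ci, cycle_s in enumerate(cfg.cycles_s):
            for mi, mode in enumerate(_ct_modes(cfg, cycle_s)):
                ct_meas = []
                for pi, truth in enumerate(truths):
                    cell = (sec, pi, mode.name, cycle_s)
                    try:
                        seed = _cell_seed(cfg.master_seed, sec, pi, mi, ci)
                        img = render_image(truth, mode, seed=seed)
                        n_ct_images += 1
                        if out_dir and cfg.write_images:
                            write_image(img, out_dir /
                                        f"s{sec}_p{pi}_{mode.name}_{cycle_s:g}s.tiff")
                        img8 = pt.window_to_8bit(img, cfg.window)
                        counts, thr = pt.count_spas_image(
                            img, cfg.window, cfg.gate)
                        count_rows.append(dict(
                            section=sec, position=position, cycle_s=cycle_s,
                            mode=mode.name, phase=pi,
                            compression_pct=truth.compression_pct,
                            threshold=thr, total=counts.total,
                            **counts.per_bin))
                        curve = hm.homology_curve(
                            img8, mode.pixel_mm, cfg.homology_min_area_mm2)
                        hom_rows.append(dict(
                            section=sec, position=position, cycle_s=cycle_s,
                            mode=mode.name, phase=pi,
                            compression_pct=truth.compression_pct,
                            peak_b0=curve.peak_b0,
                            peak_threshold=curve.peak_threshold))
                        for sid in tracked:
                            m = sz.measure_spas(img, spas_by_id[pi][sid])
                            row = m.as_dict()
                            row.update(section=sec, phase=pi, cycle_s=cycle_s)
                            ct_meas.append(row)
                            meas_rows.append(row)
                    except Exception:
                        logger.exception("stage failure at cell %s", cell)
                if ct_meas:
                    ct_df = pd.DataFrame(ct_meas)
                    dev = sz.deviation_table(ct_df, ref_df.drop(columns="cycle_s"))
                    if len(dev):
                        dev.insert(0, "section", sec)
                        dev["cycle_s"] = cycle_s
                        dev_frames.append(dev)
                    try:
                        traj = sz.trajectory_table(ct_df)
                        traj.insert(0, "section", sec)
                        traj["cycle_s"] = cycle_s
                        traj_frames.append(traj)
                    except ValueError:
                        logger.warning("trajectory skipped at (%d, %s, %g s)",
                                       sec, mode.name, cycle_s)

    result = ExperimentResult(
        truths=pd.concat(truth_rows, ignore_index=True),
        counts=pd.DataFrame(count_rows),
        homology=pd.DataFrame(hom_rows),
        measurements=pd.DataFrame(meas_rows),
        deviations=(pd.concat(dev_frames, ignore_index=True)
                    if dev_frames else pd.DataFrame()),
        trajectories=(pd.concat(traj_frames, ignore_index=True)
                      if traj_frames else pd.DataFrame()),
        summary={},
        n_ct_images=n_ct_images,
    )
    result.summary = summarize(result, cfg)
    if out_dir:
        _write_bundle(result, out_dir)
    return result


def _fit_count_model(df: pd.DataFrame, response: str) -> st.LMMResult | None:
    spec = st.ModelSpec(
        response=response, group="section",
        categorical=("mode", "position", "cycle_s"),
        continuous=("compression_pct",),
        interactions=(("mode", "compression_pct"),),
        reference_levels={"mode": "NR"},
    )
    try:
        return st.fit_lmm(df.assign(cycle_s=df["cycle_s"].astype(str)), spec)
    except ValueError as exc:
        logger.warning("mixed model for %s not fitted: %s", response, exc)
        return None


def summarize(result: ExperimentResult, cfg: ExperimentConfig) -> dict:
    """Ensemble slopes, contrasts, and qualitative ordering checks."""
    summary: dict = {"n_ct_images": result.n_ct_images}

    counts, hom = result.counts, result.homology
    if len(counts):
        lines = st.group_regression_lines(
            counts, "compression_pct", "total", "mode")
        summary["count_slope_by_mode"] = dict(
            zip(lines["mode"], lines["slope"]))
        by_phase = counts.pivot_table(index="phase", columns="mode",
                                      values="total", aggfunc="mean")
        if {"UHR", "NR"} <= set(by_phase.columns):
            summary["count_uhr_gt_nr_all_phases"] = bool(
                (by_phase["UHR"] > by_phase["NR"]).all())
        model = _fit_count_model(counts, "total")
        if model is not None:
            contrast = st.slope_contrast(model, "mode[UHR]:compression_pct")
            summary["count_slope_contrast"] = dict(
                difference=contrast.difference, ci95=list(contrast.ci95),
                p_value=contrast.p_value)
    if len(hom):
        lines = st.group_regression_lines(
            hom, "compression_pct", "peak_b0", "mode")
        summary["peak_b0_slope_by_mode"] = dict(
            zip(lines["mode"], lines["slope"]))
        by_phase = hom.pivot_table(index="phase", columns="mode",
                                   values="peak_b0", aggfunc="mean")
        if {"UHR", "NR"} <= set(by_phase.columns):
            summary["peak_b0_uhr_gt_nr_all_phases"] = bool(
                (by_phase["UHR"] > by_phase["NR"]).all())
        model = _fit_count_model(hom, "peak_b0")
        if model is not None:
            contrast = st.slope_contrast(model, "mode[UHR]:compression_pct")
            summary["peak_b0_slope_contrast"] = dict(
                difference=contrast.difference, ci95=list(contrast.ci95),
                p_value=contrast.p_value)

    dev = result.deviations
    if len(dev):
        mad = (dev[dev["dimension"] == "longitudinal"]
               .groupby("mode")["deviation"]
               .apply(lambda s: float(np.mean(np.abs(s)))))
        summary["mean_abs_long_deviation_by_mode"] = mad.to_dict()

    traj = result.trajectories
    if len(traj):
        slopes = {}
        for mode, grp in traj.groupby("mode"):
            grp = grp.dropna(subset=["d_long_mm"])
            grp = grp.assign(
                spas_uid=grp["section"].astype(str) + ":" +
                grp["spas_id"].astype(str))
            if grp["spas_uid"].nunique() >= 2 and \
                    grp["compression_pct"].nunique() >= 2:
                mspec = st.ModelSpec(response="d_long_mm", group="spas_uid",
                                     continuous=("compression_pct",))
                try:
                    fit = st.fit_lmm(grp, mspec)
                    i = fit.names.index("compression_pct")
                    slopes[mode] = dict(slope=float(fit.beta[i]),
                                        p_value=float(fit.p_values[i]),
                                        ci95=fit.ci95[i].tolist())
                except ValueError as exc:
                    logger.warning("trajectory model (%s) not fitted: %s",
                                   mode, exc)
        summary["d_long_trajectory_slope_by_mode"] = slopes
    return summary


def _write_bundle(result: ExperimentResult, out_dir: Path) -> None:
    for name in ("truths", "counts", "homology", "measurements",
                 "deviations", "trajectories"):
        getattr(result, name).to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, default=float))
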