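# spasquant

Quantification of simulated peripheral air spaces (SPAS) in
dynamic-ventilation CT of compressible sponge phantoms — as a fully
synthetic, tested pipeline.

## The problem

Dynamic-ventilation CT (DVCT) images the lung continuously while it
moves. Ultra-high-resolution CT (UHR, 0.25 mm pixels, 1024 matrix)
should depict small peripheral air spaces — airways, cysts,
honeycombing — better than normal-resolution CT (NR, 0.5 mm pixels,
512 matrix), but during motion it also suffers more from noise and
blur. A standard way to study this trade-off is a deformable sponge
phantom: a porous slab compressed uniaxially to mimic expiration,
whose internal air spaces stand in for peripheral lung structure.

`spasquant` builds that whole experiment in software, for researchers
in quantitative CT and medical image analysis who want a controlled,
ground-truth-complete testbed. It generates sponge cross-sections
with known elliptical air spaces, compresses them (lumens close faster
than the bulk), renders them through UHR / NR / idealized-reference
imaging chains, and quantifies the results four ways:

1. **Size-gated particle counts** — lung-window 8-bit conversion,
   moment-preserving (Tsai) binarization, 8-connected components,
   counts in the half-open gate `[0.5, 7)` mm² with sub-bins
   `[0.5,1), [1,2), [2,4), [4,7)`.
2. **Betti-number threshold sweep** — per-threshold `(b0, b1)` over
   all 256 gray levels (foreground 8-connected, holes 4-connected);
   the peak `b0` summarizes total detectable air spaces without
   committing to one threshold.
3. **FWHM sizing** — longitudinal/transverse lumen diameters as the
   full width at half maximum of profile troughs, elliptical areas
   `π/4·d_long·d_trans`, and deviations from the reference rendering.
4. **Mixed-model inference** — a random-intercept (compound-symmetry)
   linear mixed model fitted by profiled REML, with cluster-robust
   (sandwich) standard errors, Wald tests, and the mode×compression
   interaction as the slope-difference contrast:

   y = Xβ + u_g + ε,  u_g ~ N(0, σ_b²),  ε ~ N(0, σ_e²)

The imaging physics is parameterized by measured scanner numbers:
Gaussian PSFs fixed by the 5% MTF frequencies (UHR 1.26, NR 0.61
cycles/mm), additive noise at the 20 mA noise magnitudes (14.6 /
17.8 HU), and per-image motion blur derived from the compression
kinematics (15 mm stroke over a half cycle, 0.35 s rotation, half
reconstruction → 1.31 mm/image at a 4-s cycle, 1.05 mm at 5 s).
See `docs/methods.md` for the full model description.

## Worked example

```python
import spasquant as sq

spec = sq.PhantomSpec(seed=1)
truth = sq.generate_phantom(spec)
print(f"{len(truth.spas)} air spaces, matrix {truth.matrix_hu:.1f} HU, "
      f"section mean {truth.mean_hu():.1f} HU")

for c in (0.0, 12.0, 24.0, 35.0):
    t = sq.compress_phantom(truth, c)
    row = [f"{c:4.0f}%"]
    for mode in (sq.ImagingMode.uhr(blur_mm=1.3125),
                 sq.ImagingMode.nr(blur_mm=1.3125)):
        img = sq.render_image(t, mode, seed=int(c))
        counts, thr = sq.count_spas_image(img)
        row.append(f"{mode.name}: {counts.total:3d} (threshold {thr})")
    print("  ".join(row))
```

prints

```
110 air spaces, matrix -724.4 HU, section mean -776.0 HU
   0%  UHR:  49 (threshold 97)  NR:  32 (threshold 100)
  12%  UHR:  41 (threshold 98)  NR:  28 (threshold 102)
  24%  UHR:  41 (threshold 99)  NR:  18 (threshold 104)
  35%  UHR:  31 (threshold 102)  NR:   9 (threshold 106)
```

Reading the output: the section mean is calibrated to −776 HU (the
density of the physical sponges); of the 110 ground-truth air spaces
about 65 fall in the counting gate when uncompressed. At every
compression phase the UHR render resolves more in-gate air spaces than
the NR render, and both counts fall as compression closes lumens —
the central resolution effect, emerging from the imaging physics
rather than being scripted. The per-image Moments threshold (an 8-bit
gray level) adapts to each image's histogram.

The full study design — 14 cross-sections × 4 phases × 2 CT modes ×
2 cycle durations = 224 CT images, with counts, homology curves,
sizing, deviations, trajectories and mixed-model summaries — runs as:

```python
result = sq.run_experiment(sq.ExperimentConfig(master_seed=0))
print(result.summary)
```

A thin CLI wraps the same stages (`spasquant simulate / physics /
count / homology / run`), e.g.:

```
$ spasquant physics --what blur-ct --cycle 4
1.312 mm/image
```

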