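# Methods

This note documents the models, parameter choices and numerical conventions
behind `cherimatch`, and what the synthetic validation can and cannot say
about real acquisitions.

## Scene model

Both fields share the accelerator isocenter, which projects to the image
centre. The image X axis is the superior–inferior match axis (X increases
toward inferior; a "superior" couch shift is a negative X translation); the
photon field occupies X ∈ [−50, 0] mm and the electron field X ∈ [0, 50] mm,
so the match line runs through X = 0. The default raster is 432 × 576 px at
3.6 px/mm (120 × 160 mm), large enough for a 10 mm shift of an obliquely
stretched field plus a 4σ penumbra margin; a field that does not fit raises
an error naming the overflow.

A noiseless image is `A · fx(x) · fy(y)`, where each factor is a smoothed
indicator of the field interval — a step convolved with a Gaussian of width
σ_edge (an erf-shaped penumbra). Couch shifts translate the field
analytically (edge coordinates move; no image resampling), so ground truth
is exact to machine precision.

### Edge width

σ_edge defaults to **0.6 mm (photon)** and **0.65 mm (electron)**. The
difference of two erf edges separated by k mm is the convolution of a k-wide
boxcar with a Gaussian, whose FWHM exceeds k by an amount that grows with
σ/k; in closed form the over-read at k = 2 mm is ≈ 0.27σ-to-0.47σ for the σ
range of interest. The defaults keep the noiseless over-read below one pixel
(0.28 mm) at the smallest tested shift — 0.16 mm and 0.20 mm respectively —
while preserving the characteristic positive bias at small shifts that the
measurement principle produces. Real beam penumbras are broader than this at
depth; the value here describes the *optical surface* edge sharpness needed
for the junction band to track the shift at the camera's resolution, and is
a deliberate calibration of the generator, not a measured beam property.

### Oblique incidence

The tangential fields (gantry 330°/150°) are 30° off normal incidence. The
in-field extent along X is stretched by 1/cos 30° away from the match line
and the X-edge width becomes σ_edge/cos 30°, reproducing the known effect
that oblique delivery extends the high-intensity area along the beam
direction and blurs the field edge. The gantry-150 field is imaged from the
radiation exit side and its yield carries an extra factor 0.6.

### Relative yield

No absolute grayscale-per-MU calibration exists; all intensities are
relative. The yield model encodes the empirically established orderings:

| parameter | default | meaning |
|---|---|---|
| `electron_intercept`, `electron_slope_per_mev` | 0.5, 0.05/MeV | electron yield linear in energy (superficial dose ≈ linear in energy) |
| `photon_base` | 0.45 | conventional photon yield, below every electron field (dose maximum centimetres deep) |
| `dose_rate_exponent` | 1.0 | FFF yield = base × (MU/min ÷ 600)^exp; exposed because the reported enhancement (2.33–3.66×) differs from the nominal 2×/4× ratios |
| `exit_side_factor` | 0.6 | gantry-150 light collection deficit |
| tissue absorption | yellow 1.0, black 0.05 | multiplicative optical absorption of the visible emission |

The grayscale amplitude is `yield × signal_scale × integration_time`, with
`signal_scale` = 6000 counts per unit yield per second on the 16-bit range.

### Camera and noise

Gain 36 dB; integration times follow the experimental protocol (photon 1 s,
electron 1.2 s on light tissue; 2 s / 2.5 s on dark tissue). Per frame the
simulator adds a Gaussian background (mean 200, SD 300 counts per second of
integration — dark/readout noise accumulates with integration time),
Poisson shot noise on the signal, and a Poisson(30)-distributed number of
near-saturation sparkle pixels (direct high-energy hits on the CCD), then
clips to [0, 65535]. Three irradiation frames and three radiation-off
background frames form one acquisition. These levels were fixed once so that
the stated study conditions reproduce the qualitative findings on both
tissue colours: light tissue yields difference bands far above the
detection threshold at every tested shift, while dark tissue (5% optical
transmission, even at doubled integration) stays below it.

## Preprocessing

1. subtract the per-pixel **temporal median of the background frames** from
   each irradiation frame, clamping at zero (the median mirrors the signal
   path and rejects background sparkles);
2. per-pixel **temporal median across the three frames**, which removes any
   sparkle present in a single frame;
3. **10×10 spatial median filter**, window anchored at offsets [−5, +4]
   with the upper order statistic (rank 50) and edge replication — the
   standard rank-filter convention for even windows.

An even median window evaluates a locally monotone profile at a sub-pixel
offset (rising edges exactly, falling edges one pixel over), and any 2-D
median rounds field corners where both axes ramp. Both effects act
identically on the reference and shifted composites, so difference-band
widths — the measured quantity — are unaffected; tests assert the roundtrip
contract in that form rather than as exact identity.

## Matching measurement

Composites are clipped at the bit-depth maximum (clipped fraction
recorded). The difference is **absolute**, since a width is measured, not a
direction. The ROI profile is the per-column mean over the ROI rows. The
FWHM rule is fully automated for testability (the original procedure used a
manual data cursor): baseline = median of the lowest quartile of profile
values, half level midway between baseline and global peak, width between
the outermost linearly interpolated crossings around the peak.

The junction ROI defaults to **30 mm (X) × 30 mm (Y)** centred on the match
line: a 10 mm shift puts the whole band on one side of the junction, so the
window must span the largest tested shift plus penumbra on both sides; a
20 mm window clips the outer crossing and truncates the width.

Detectability: SNR = (profile peak − baseline) ÷ SD of the temporally
median-combined background frames inside the ROI, threshold 2.0. Below
threshold the result is "not detectable" — except when the introduced shift
is declared zero, where an absent band is the correct answer and the
measurement reports 0 (this avoids conflating "no band" with "zero shift").
An optional correction flag subtracts a constant systematic offset
(default 0.55 mm, off by default) from the measured value.

Zero-shift controls are evaluated against an independently simulated
zero-shift acquisition, not by differencing a composite with itself, so the
null path sees real residual noise.

## Experiment grids

The AP grid pairs each photon beam (6/10 MV, 6/10 FFF; shift applied to the
photon field) with a fixed 10 MeV electron partner, and each electron energy
(4–15 MeV; shift applied to the electron field) with a fixed 6 MV photon
partner — the protocol does not fix the partner, only that one field of
each modality is matched. Shifts 0/2/5/10 mm × superior/inferior give 80
scenarios per seed; the oblique grid covers the four photon beams at both
tangential gantry angles (64 scenarios). Preprocessed zero-shift references
are cached per (beam, tissue, seed), as in the experiment where one
reference pair serves every shift. Reported summaries use the absolute
discrepancy: mean ± SD, fraction within 1 mm, maximum. The validation runs
use three seeds per scenario and the default 432 × 576 raster, sizes at
which each grid completes in a couple of minutes on one core.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that the *measurement chain* recovers known
displacements to well under a millimetre under the modelled noise, that
oblique edge broadening degrades precision in the expected direction, that
high-dose-rate fields tighten the error spread, and that dark tissue is
correctly flagged unmonitorable. The generator does not model tissue
anatomy or curvature (the flat-phantom default), lens distortion or
perspective, wavelength-dependent optics, beam spectra, or intra-fraction
motion; surface roughness exists only as an optional smooth modulation for
robustness checks. Quantitative agreement with errors measured on real
tissue phantoms therefore cannot be claimed from these tests — only that
the algorithm is a faithful, correctly calibrated implementation of the
procedure.

## Numerical conventions

- 0-based pixel indices; pixel centres at integer coordinates; millimetre
  origin at the image centre (isocenter projection).
- 16-bit synthesis; 8-bit images are promoted to float on read.
- Ruler ticks are rendered with exact area weighting, so sub-pixel tick
  positions are represented without aliasing; calibration fits a
  least-squares line through tick centroids (insensitive to global
  intensity scaling and constant offsets) and reports the RMS residual,
  warning above 0.5 px.
- All randomness flows through `numpy.random.default_rng` seeds recorded in
  stack metadata; batch runs derive per-acquisition sub-seeds via CRC32 of
  the scenario description, so results are reproducible across processes.
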