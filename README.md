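# cherimatch

Quantitative monitoring of the match line between adjacent photon and
electron radiotherapy fields from Cherenkov luminescence images.

## The problem

In breast and chest-wall radiotherapy, a photon field and an adjacent
electron field must join on the patient surface. Respiratory or involuntary
motion displaces the junction; an overlap overdoses the skin, a gap
underdoses the target. Cherenkov luminescence imaging (CLI) — a CCD camera
imaging the faint optical emission excited on the tissue surface during
beam-on — shows exactly where each field lands without extra dose, so a
displacement of one field relative to the other can be measured directly
from the images.

`cherimatch` implements the analysis for physicists doing field-junction QA:

- a **synthetic acquisition generator** that emulates the phantom
  experiments (erf-edged 5×5 cm² fluence maps; a relative Cherenkov yield
  model ordered by electron energy, photon dose rate and tissue colour; CCD
  background, Poisson shot noise and sparkle impulses from direct x-ray
  hits; repeated frames with radiation-off backgrounds; a calibration
  ruler), so every stage is testable against known ground truth;
- the **measurement pipeline**: background subtraction, temporal median
  over the 3-frame stack, 10×10 median smoothing, reference/shifted
  composites, difference image, ROI profile, FWHM, and pixel-to-millimetre
  conversion;
- **intensity metrics** (mean grayscale value, averaged ROI profiles) and a
  **batch experiment runner** with summary statistics.

## The measurement

Let `P₀`, `E₀` be the preprocessed zero-shift photon and electron images and
`P_k` the photon image acquired with a couch shift of `k` mm along the
superior–inferior axis. The reference composite is `R = P₀ + E₀` and the
shifted composite `S = P_k + E₀`. Their absolute difference

```
D = |S − R|
```

is a bright band at the junction whose width equals the displacement. The
band is averaged over a rectangular ROI into a 1-D profile along the
superior–inferior axis; the full width at half maximum (baseline = median of
the lowest quartile; half level midway to the global peak; crossings
linearly interpolated) converted with the ruler-calibrated pixel scale
(36 px per 10 mm at the isocenter plane) is the **measured matching value**,
and its difference from `|k|` is the **matching error**. A band whose
signal-to-noise ratio (profile peak over the background-frame SD in the
ROI) falls below 2 is declared undetectable — which is the correct verdict
for dark tissue, where the visible Cherenkov emission is almost entirely
absorbed.

## Worked example

```bash
python examples/measure_shift.py
```

```
introduced shift : +5.0 mm (+ = inferior)
measured matching: 5.02 mm
discrepancy      : +0.02 mm
band SNR         : 14.2
```

A 6 MV photon field was simulated with a known 5 mm inferior couch shift at
default noise; the difference-band FWHM reads the shift back as 5.02 mm, an
error of 0.02 mm, with the band 14 standard deviations above the background
noise. Other examples: `calibrate_ruler.py` (pixel-scale calibration),
`intensity_metrics.py` (MGV orderings across energies and dose rates),
`run_grid.py` (a reduced validation grid with summary statistics).

A thin CLI wraps the same functions for shell use:

```bash
cherimatch simulate --config scenario.yaml --out data/ --seed 1
cherimatch calibrate data/ruler.tiff
cherimatch analyze --photon p.tiff --electron e.tiff --shifted-photon ps.tiff
cherimatch run --grid group-a --seeds 0,1,2 --out results/
```

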