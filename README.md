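# focikit

Quantitative image analysis of fluorescent protein foci in bacterial
microcolonies, built for studies of Type VI secretion system (T6SS) sheath
dynamics. When the contractile TssB/TssC sheath polymerises, a GFP fusion to
the sheath appears as a diffraction-limited bright focus inside the cell;
counting these foci, measuring their brightness, and following them through
time-lapse movies is how T6SS assembly and its post-translational control
(the PpkA kinase / PppA phosphatase / Fha module) are quantified at the
single-cell level.

`focikit` provides the full analysis chain as a tested, reusable library
plus CLI:

- **Focus segmentation** — within each region of interest (ROI) drawn around
  a group of cells, a pixel is classified "focus" when its intensity exceeds
  the ROI mean by more than *k* = 2.2 standard deviations; connected
  components larger than 6 pixels become focus objects.
- **Intensity quantification** — each focus is measured as the mean over its
  pixels, minus the mean of a 1-pixel annulus around it (local background),
  giving a camera-offset-invariant corrected intensity; foci-per-cell
  frequencies combine detected counts with supplied (manually counted) cell
  numbers.
- **Strain statistics** — box summaries (median, 25/75 percentile box,
  10/90 percentile whiskers) and the Kruskal–Wallis rank test
  ("ANOVA on ranks", H with midrank tie correction, χ² p with k−1 df) with
  Dunn–Holm post-hoc comparisons.
- **Time-lapse dynamics** — rigid-body drift correction (phase correlation
  plus least-squares refinement of translation and rotation), temporal
  colour-coded projections (red → blue hue sweep, per-channel maximum blend,
  rendering window 400–5500 counts) in which persistent foci blend toward
  white, and greedy nearest-neighbour tracking with gap closing that scores
  each focus track's *site persistence* — the quantitative counterpart of a
  "white spot" that distinguishes same-site sheath reassembly from
  relocation across the cell.
- **Synthetic microcolonies** — a seeded generator of rod-shaped cells with
  planted foci (configurable per-cell frequency, lognormal brightness,
  assembly/disassembly kinetics, relocation probability, stage drift, PSF,
  Poisson + read noise) and full ground truth, so every stage is validated
  by parameter recovery rather than by eye.

## Worked example

```python
from focikit import SceneSpec, generate_microcolony, foci_per_cell, box_summary
from focikit.validate import analyze_scene

spec = SceneSpec(n_cells=150, n_z=3, focus_prob_per_cell=0.55, seed=17)
stack, truth = generate_microcolony(spec)
analysis = analyze_scene(stack, truth)    # z-selection -> threshold -> measure

est = foci_per_cell(len(analysis.foci), truth.n_cells)
summary = box_summary([m.corrected_intensity for m in analysis.measurements])
print(f"analysed z-section: {analysis.z_selected}")
print(f"detected foci: {est.n_foci} in {est.n_cells} cells "
      f"-> {est.foci_per_cell:.2f} foci per cell")
print(f"corrected focus intensity (au): median {summary.median:.0f}, "
      f"IQR {summary.p25:.0f}-{summary.p75:.0f}")
```

prints

```
analysed z-section: 1
detected foci: 79 in 150 cells -> 0.53 foci per cell
corrected focus intensity (au): median 858, IQR 685-1015
```

i.e. on a scene with a planted per-cell focus probability of 0.55 the
pipeline detects 0.53 foci per cell, and reports the background-corrected
brightness distribution of the detected foci in arbitrary fluorescence
units.

The same stages are available from the shell:

```sh
focikit simulate --outdir sim --seed 1            # synthetic scene + truth
focikit segment  --outdir seg --images sim/scene.tif --rois rois.tsv --n-cells 150
focikit compare  --outdir cmp --measurements wt=a.csv --measurements mut=b.csv
focikit dynamics --outdir dyn --stack timelapse.tif --rois rois.tsv
focikit validate --outdir val --seed 1            # simulate -> analyse -> truth
```

Every command writes a manifest (config hash, seed, version); identical
inputs and seed give byte-identical outputs.

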