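# Methods

This note documents the models and procedures implemented in `focikit`,
their assumptions, the defaults and why they were chosen, and what the
synthetic validation does and does not demonstrate.

## Image model and conventions

Stacks are 5-D arrays ordered `(t, z, channel, y, x)` in 16-bit camera
counts; missing axes are size-1. Pixel coordinates are `(y, x)` with origin
at the top-left pixel centre, 0-based everywhere. Physical metadata travels
with the stack: pixel size (default 0.065 µm/px — an assumption typical of
a 100×/1.4 NA widefield system with a CCD camera, not a measured value),
z-step (0.25 µm static, 0.2 µm time lapse) and frame interval (90 s; the
default time lapse is 21 frames ≈ 30 min).

For 2-D analysis the plane is the *highest-contrast* z-section, defined as
the slice with the largest intensity standard deviation. SD is invariant
under additive offsets and equivariant under gain, so the choice is
independent of camera offset; ties break to the lowest index. An optional
3-D mode thresholds an ROI's inclusive z-range as a volume with 26-connected
components instead.

## Focus detection

Within one ROI (polygon or rectangle; a pixel belongs to the ROI iff its
centre is inside under the even-odd rule, boundary included), the threshold
is `mean + k·SD` over **all** ROI pixels, with population SD (divisor N)
and the strict inequality `I > threshold`, so a uniform ROI yields nothing.
Defaults: `k = 2.2`; components must be strictly larger than 6 pixels
(area ≥ 7); 8-connectivity in 2-D so diffraction-limited spots are not
split on diagonals. Foci touching the ROI boundary are kept by default (a
flag enables exclusion). All of these are exposed in `SegmentationParams`.

Two caveats follow directly from the rule and are worth knowing:

- The threshold is *relative to the ROI population*. If the ROI is drawn
  loosely around sparse cells so that most ROI pixels are dark background,
  the threshold can fall below the cytoplasmic level and whole cells are
  then segmented as "foci" (diffuse-fluorescence false positives). The
  procedure assumes ROIs drawn tightly around groups of cells —
  microcolonies — and the validation scenarios honour that.
- Whether the reference software computed SD per z-slice or per volume is
  not specified anywhere; the 2-D default computes it per analysed plane.

## Intensity quantification

A focus is measured as the arithmetic mean over its pixel set. Local
background is the mean over an annulus: the object dilated by a 3×3 square
element (once per unit of annulus width, default width 1 px), minus the
object, minus pixels of any *other* segmented focus (prevents bright-
neighbour contamination), clipped to the image. Corrected intensity =
object mean − annulus mean; it is exactly invariant under a global additive
offset, scales linearly with gain, and may be negative under noise (it is
reported as-is, never clipped). A focus whose clipped neighbourhood leaves
no annulus pixel is a contract error, not a silent zero.

Foci-per-cell frequency is the exact ratio of detected foci to a supplied
cell count; cell counting is manual input by design, mirroring how such
data are produced, and no automatic cell counter is in scope.

## Strain statistics

Box summaries use the median, 25/75 percentile box and 10/90 percentile
whiskers, with linear interpolation between order statistics (any numpy
percentile method can be selected; the method is part of the report).
Whiskers are *percentiles*, not standard errors — the two are sometimes
conflated in figure legends, and this implementation draws percentiles.

The omnibus comparison is the Kruskal–Wallis rank test with midranks and
tie correction (delegated to `scipy.stats.kruskal`; an independent direct
evaluation of the H formula guards it in the test suite). The degenerate
all-identical case returns (H, p) = (0, 1) by documented convention. For
small samples a seeded permutation p-value is available. Because no
post-hoc procedure is standard for this assay, pairwise Dunn z-tests on the
pooled midranks with Holm step-down adjustment were chosen; the report
records whether raw or background-corrected intensities were compared.

## Time-lapse dynamics

**Drift correction.** Stage drift is modelled as rigid motion (translation
+ rotation about the image centre). Frame-to-previous translations are
estimated by phase correlation, composed to frame 0, and each composed
transform is refined by Powell minimisation of the mean squared intensity
difference against frame 0 over valid (in-frame) pixels, with rotation
bounded to ±10°. Estimation runs on intensities clipped at the 95th
percentile of frame 0: foci assemble, move and vanish between frames, and
unclipped they dominate the least-squares criterion and drag the alignment,
whereas the static cell bodies are the true stationary reference. On
planted drifts of a few pixels and degrees per sequence the recovery error
is below 0.25 px and 0.3°. Featureless frames register as identity with a
warning. Warping is bilinear; out-of-frame pixels take the frame median.

**Temporal projection.** Each frame is rendered into [0, 1] through a
display window (defaults 400–5500 counts, a window in which foci remain
visible throughout), tinted with a time-indexed colour from an evenly
spaced hue sweep red (0°) → blue (240°) at full saturation/value, and
superimposed by per-channel maximum (an additive-with-clip blend is
available for comparison). A pixel fluorescent through most of the movie
accumulates hues across the sweep and blends toward white; a transient
focus keeps its frame's hue. The implementation guarantees: if a pixel is
rendered ≥ 0.8 in ≥ 80% of frames, fewer than 20% of the hue range can be
missing from its blend, so every RGB channel reaches ≥ 0.8 and the pixel
reads as white.

**Tracking and site persistence.** Detections are linked frame-to-frame by
greedy nearest-neighbour assignment (closest pair first, each detection
used once) within a link radius, bridging up to `max_gap = 1` missing
frames — chosen because disassembled sheaths can vanish for a single frame
before reassembling. Default link radius is 15 px ≈ half a cell length, so
a within-cell relocation stays inside one track while cross-cell captures
stay rare. Each track's detections are clustered into sites (greedy,
running-mean centres, radius 3 px); *site persistence* is the fraction of
the track's spanned frames with a detection within the site radius of the
most-visited site, and a relocation is a linked jump larger than the site
radius. Single-detection tracks have persistence 1.0 by convention and are
excluded from summary fractions (they carry no information).

A track is classified **static** when its persistence is ≥ 0.7. The
threshold sits deliberately above 0.5: a track that visits two sites splits
its detections at best evenly, so its modal-site share almost never falls
below one half and a cut at 0.5 cannot separate one-relocation tracks from
true same-site tracks. Same-site tracks have persistence near the assembly
duty cycle (mean lifetime / (mean lifetime + mean dark period) ≈ 0.85 at
the synthetic defaults), and 0.7 lies between that and the two-site
ambiguity point. The static-track fraction per strain is this package's
quantitative operationalisation of the "white spot" phenotype; it is a
defined statistic of the tracking output, not a measurement that exists in
the source imagery.

## Synthetic microcolonies

The generator emulates widefield acquisition of rod-shaped bacteria:
non-overlapping spherocylinders (default 2.5 × 0.8 µm) placed either as a
central colony (the imaging unit of interest) or uniformly; each cell
carries at most one focus with probability `focus_prob_per_cell` (regimes
0.55 and 0.76 are the observed wild-type-like and phosphatase-mutant-like
frequencies). The fluorescence image is background + PSF-blurred cytoplasm
+ Gaussian spots (σ = 1.3 px), with off-focus z-sections blurred and
attenuated by a defocus that grows with distance from the central section
(2 px of extra σ per µm), then Poisson shot noise (gain 1) and Gaussian
read noise (SD 5) quantised to 16 bits. Photometric defaults were chosen
once for consistency with the rendering window used for the real data:
background 120 + cytoplasm 280 = 400 counts (the window floor) and
lognormal spot amplitudes (median 2500, σ 0.3) whose peaks reach the
window ceiling; the implied spot SNR ≈ 40, comfortably inside the
"high-SNR" regime the recovery tolerances assume. A flat DIC placeholder
channel is included.

In time-lapse mode each focus alternates geometric assembled periods
(mean 5 frames) and dark periods (mean 1.3 frames — prompt reassembly,
consistent with single-frame gap bridging), with optional independent
one-frame dropouts (3%); on each reassembly it relocates with probability
`relocation_prob` to a new intracellular site at least 6 px away, else
reuses its site. Cumulative rigid drift transforms the scene coordinates
before rendering (no interpolation artefacts), and ground truth records
cells, per-frame focus positions (both undrifted and as-rendered),
amplitudes, relocation events and the drift trajectory.

What the generator does *not* model: photobleaching, cell growth or
division within the 30-min window, 3-D PSF structure, sheath
extension/contraction intermediates, camera fixed-pattern noise, or real
DIC contrast. Passing recovery tests therefore demonstrates that the
analysis is a faithful implementation of its stated rules and is unbiased
under this noise model — not that it is robust to every artefact of real
microscopy.

## Validation problem sizes

The acceptance checks run, per seed: 10 colony scenes × 200 cells per
frequency regime (2000 cells each, matching detections to planted foci
within 3 px); 3 scenes for intensity recovery; one 21-frame drifted and one
undrifted sequence for registration; 20 replicates per dynamics regime on
416×416 fields of 64 cells (the per-replicate static fraction then averages
over ~35 foci, which stabilises the regime AUC); and 2000 null replicates
of 3 × 50 draws for the rank-test type-I rate. Scene sizes are the
package's own choice of statistical power versus runtime; densities match
the colony regime the thresholding rule assumes.

## Known limitations

- The SD-threshold rule has no contrast floor: in a field with no true
  foci it will segment the brightest diffuse patches if they clear the
  ROI statistics (observable as low corrected intensities).
- Merged foci in adjacent cells are counted once (no watershed splitting).
- Tracking is 2-D and greedy; it does not solve a global assignment, and
  dense fields with long link radii can cross-link neighbouring cells'
  foci.
- The registration refinement assumes the scene is dominated by stationary
  structure; movies in which most intensity relocates every frame would
  need the clipping percentile lowered.
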