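# stmotility

Video spatiotemporal (ST) mapping of smooth-muscle motility in hollow organs
— gut segments, stomach, bladder — from plain video, plus a synthetic
motility-video simulator with exact ground truth for validation.

ST maps compress a motility video into a 2-D image whose rows are time and
whose columns are position along the organ, so that propagating contractions
appear as angled bands whose slope is the propagation velocity, whose breadth
on the time axis is the contraction duration, and whose breadth on the
distance axis is its spatial extent. The package implements the full family
of mapping techniques used in the field:

- **D-maps** — organ diameter per pixel column per frame, from sub-pixel
  half-maximum edge detection. Variants: **R-maps** (radius from each edge to
  a midline structure such as a colonic taenia, resolving independent upper
  and lower wall behavior) and **arcuate-axis D-maps** (wall chords along
  rays fanned from a center, for organs like the stomach whose propagation
  axis is curved).
- **L-maps** — longitudinal strain rate (%·s⁻¹) along a user-defined line of
  interest (LOI), from speckle/marker tracking. Local motion is found by
  minimizing the mean-removed sum of squared differences between a 21×21 px
  window in frame *P* and displaced windows in frame *Q*,

  C(x, y) = Σᵢ Σⱼ ((P(i,j) − μ_P) − (Q(i+x, j+y) − μ_Q))²,

  evaluated over an integer search grid (±15 px by default; an SAD variant
  is available) and refined to sub-pixel precision by minimizing a 2-D cubic
  spline fitted to the cost surface. The strain rate is the arc-length
  derivative of the tangential velocity; negative = local shortening.
- **A-maps** — two-dimensional area strain rate: the product of the
  lengthwise and diametric stretch ratios of a tracked grid,
  (λ_L·λ_D − 1)/Δt, overlaid on the video; plus stacked contraction-density
  plots (per-pixel % of sampled frames below a contraction threshold,
  default −4 %·s⁻¹), patch morphometrics (count, area, CV, shape index,
  perimeter–area fractal dimension, FRAGSTATS raster conventions) and
  core-area-% time series.
- **I-maps** — light intensity along a LOI, for tracking passive structures
  and luminous phenomena.
- **Analytics** — transects, FFT frequency estimation and per-column
  frequency maps (phase-dislocation candidates), auto-/cross-correlograms,
  map subtraction, contraction-event detection (onset, duration, extent,
  velocity, amplitude), phase offsets between synchronous transects, and
  displacement maps by time-integration of tracked velocity, used to resample
  D-maps into material coordinates ("shunt correction" — undoing the passive
  lengthwise displacement of uncontracted wall by contractions elsewhere).

The **simulator** renders deforming tubes (peristalsis, mass peristalsis,
segmentation, pendular motion, with optional incompressible or prescribed
longitudinal coupling and bulk drift) and sacculate organs with localized
contracting patches, over closed-form diameter/displacement/strain-rate
fields that are returned as ground truth.

## Worked example

```python
import numpy as np
import stmotility as sm

scene = sm.TubeScene(length_px=256, n_frames=900, seed=7)     # 60 s at 15 fps
prog = sm.ContractionProgram(pattern="peristalsis", amplitude=0.5,
                             wave_speed=30.0, temporal_frequency=0.25)
stack, truth = sm.simulate_tube(scene, prog)

dmap = sm.build_dmap(stack)
events = sm.detect_events(dmap, threshold_fraction=0.2, min_area=40)
freq, _, _ = sm.dominant_frequency(dmap.values[:, 128], dmap.row_interval_s)
print(len(events), round(float(np.median([e.velocity_px_s for e in events])), 2), freq)
```

prints

```
15 29.83 0.25
```

— 15 contraction waves detected over 60 s (the program launches one wave
every 4 s), a median propagation velocity of 29.83 px·s⁻¹ against the
programmed 30 px·s⁻¹, and a dominant contraction frequency of exactly
0.25 Hz at mid-organ.

The same pipelines run from the shell:

```
stmotility simulate --pattern peristalsis --amplitude 0.5 --speed 30 \
    --freq 0.25 --frames 900 --seed 7 --out run/
stmotility dmap --input 'run/frames/frame_*.tif' --out run/maps
stmotility events --map run/maps/dmap --min-area 40 --out run/events
```

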