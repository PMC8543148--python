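# embryotrace

Quantification of live-imaged *Drosophila* blastoderm movies during nuclear
cycle 14 (nc14), the interphase in which the syncytial embryo cellularizes and
Notch-dependent transcription switches on in the mesectoderm. The package
re-implements, as a tested and reusable pipeline, the image-quantification
chain used for such movies:

* **3-D nucleus segmentation and tracking** from a histone channel: median
  filtering, per-frame contrast rescaling, frequency-domain blob enhancement,
  fixed-threshold segmentation with hole filling and size filtering, a
  marker-based 3-D watershed on the *anisotropic* (physical-distance) Euclidean
  distance transform to split fused nuclei, and nearest-centroid linking
  (6 µm gate, two-frame lookback; contested links start new tracks).
* **MS2/MCP transcription traces**: the maximum MCP-GFP intensity over each
  nucleus is the spot-fluorescence proxy. Nuclei tracked >10 frames are
  classified in two passes: a straight-line baseline is fitted to the cohort
  mean, a frame is ON when the median-filtered trace exceeds 1.2× baseline,
  nuclei with ≥5 ON frames are active, and the baseline is refitted on the
  inactive pool. Traces are baseline-subtracted and divided by the relative
  decay of the inactive pool to undo photobleaching. Onset = first ON frame
  at/after 15 min into nc14 (30 min under maternal Gal4); total output = sum
  of normalized values over 30–50 min, split into high/low at the median.
* **Nuclear-envelope segmentation** (nucleoporin-marker channels): isotropic
  resampling, Gaussian smoothing, histogram matching to frame 0, a 10%
  threshold seed refined by a region-based active contour, inversion so
  enclosed interiors become objects, vitelline-membrane removal by slice
  footprint, watershed, and a 10–200 µm³ size range; tracked with a 4 µm
  gate and five-frame lookback.
* **Morphology**: volume, marching-cubes surface area, solidity,
  principal-axis lengths, and 2-D area/perimeter/eccentricity at 25/50/75%
  of the embryo-wide apico-basal nuclear extent.
* **Cellularization front**: Otsu-thresholded orthogonal sections give the
  membrane length over time (slow then fast ingression phase); landmark
  times (front reaching apical/mid/basal nuclear depths) are correlated
  across embryos against the first quartile of transcription onsets by
  pooled ordinary least squares (R²).
* **FRAP**: 20 px circular ROIs, double normalization against six control
  ROIs (cancels acquisition bleaching exactly), zero-scaling so the first
  post-bleach value is 0 and the plateau reads out the mobile fraction.
* A **synthetic embryo-movie generator** that renders all of the above with
  full ground truth — elongating, wrinkling ellipsoidal nuclei in a
  monolayer, telegraph-bursting MS2 puncta with defined onsets, a biphasic
  membrane front, global photobleaching, and read/shot noise — so every
  stage is testable without external data.

## Worked example

```python
import numpy as np
from embryotrace import EmbryoSpec, PipelineConfig, generate_movie, run_pipeline

spec = EmbryoSpec(nx=3, ny=3, shape_zyx=(32, 96, 96),
                  duration_min=40, frame_interval_s=120,
                  front_breakpoint_min=35, onset_mean_min=20,
                  onset_sd_min=2, onset_floor_min=15, seed=13)
stack, truth = generate_movie(spec)          # 2-channel movie + ground truth
cfg = PipelineConfig(output_window_min=(20, 35))
run_pipeline(stack, cfg, "out/", landmarks_um={"basal": 12.0})

import pandas as pd
print(pd.read_csv("out/nuclei.csv"))
```

```
   track_id  active  onset_min  output_au class
0         0    True       22.0   1.924240   low
1         1   False        NaN   0.028915   NaN
2         2   False        NaN   0.115917   NaN
3         3   False        NaN   0.074339   NaN
4         4    True       22.0   2.066990  high
5         5   False        NaN   0.086913   NaN
6         6   False        NaN   0.068754   NaN
7         7    True       24.0   1.782600   low
8         8   False        NaN   0.101532   NaN
```

The three active nuclei are the central grid column — the generator's
mesectoderm-like stripe — with onsets recovered at 22–24 min against true
onsets drawn around 20 min (2-min frames), and their summed bleach-corrected
output over the 20–35 min window classified as high or low relative to the
cohort median. `out/` also contains the per-frame trace table, the cohort
mean ± s.e.m. profile, an onset-sorted heat-map matrix, per-nucleus
morphology, the front-length series with landmark times, and a run manifest.

The same stages are available from the shell:

```bash
embryotrace synth --config spec.yaml --seed 1 --out synth/
embryotrace run synth/movie.ome.tif --out results/
embryotrace correlate --onsets onsets.csv --landmarks landmarks.csv --out corr/
```

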