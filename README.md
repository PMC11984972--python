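# traceridges

Automatic tracing and quantification of fibre-like structures —
collagen, fibronectin and other extracellular-matrix fibres — in 2-D
microscopy images and maximum-intensity projections of stacks.

Biologists quantifying matrix remodelling need each fibre delineated as
a one-pixel-wide centreline before lengths, orientations, gaps or
densities mean anything. Manual delineation does not scale, and the two
obvious automatic routes both fail alone: the watershed transform of
the intensity landscape puts its divide lines on fibre crests but
drowns them in over-segmentation noise, while Canny edge detection
finds two flank lines per fibre and no centreline at all. This package
implements a tracer that plays the two against each other: watershed
divide lines give candidate ridges, the Canny edges crossing the
spurious minor ridges break them off, rule-based morphology (segment
size, brightness, Euler-characteristic double-ridge repair) cleans the
network, fibres the watershed missed are rebuilt from pairs of orphan
edges, and the result is fused into disjoint thin traces, preferring
longer and brighter fibres.

Around the core tracer the package provides:

- an **edge-detection baseline** tracer (Canny components as traces),
  which reproduces the characteristic two-lines-per-fibre over-tracing
  and serves as the comparison point;
- **distance-map evaluation** against ground truth: the exact Euclidean
  distance transform of one trace set sampled at the other's pixels
  yields total, average-per-trace and maximum distance errors in both
  directions — the metrics that discriminate where pixel-overlap scores
  cannot;
- **per-fibre morphology** (length, width, orientation, eccentricity,
  mean intensity) and inter-fibre **gap analysis**;
- a **synthetic fibre-image generator** with exact ground-truth
  centrelines emulating four imaging regimes (clean SHG-like collagen,
  bright fibronectin, wavy filamentous sections, noisy low-contrast
  matrices), so the whole system is testable without any external
  dataset.

See `docs/methods.md` for the full pipeline description, parameter
table and design rationale.

## Worked example

Simulate a clean five-fibre scene, trace it, and score the traces
against the exact generating centrelines:

```sh
$ traceridges simulate --preset clean_shg --seed 7 \
      --out-image scene.tif --out-gt gt
5 fibres -> scene.tif, GT -> gt.csv

$ traceridges trace scene.tif --out out/
5 traces -> out/scene_traces.tif

$ traceridges evaluate --result out/scene_traces.csv --gt gt.csv --out ev/
total=448.31 mean_per_trace=44.83 max=3.00

$ traceridges metrics out/scene_traces.csv --image scene.tif --out met/
5 fibres, 0 gaps (largest 0 px^2)
```

All five generated fibres are recovered as five traces. The evaluation
line reads: summed over both comparison directions, trace pixels sit a
total of 448 px of distance away from the opposite set (about 0.3 px
per pixel here), 44.8 px per trace on average, and no traced pixel is
farther than 3 px from a true centreline. `out/` also receives a label
TIFF (0 = background, k = trace k), a per-pixel CSV, a JSON sidecar of
per-trace fields, and a JSON record of the full effective
configuration.

The same from Python:

```python
from traceridges import (regime_preset, generate_fibre_image,
                         trace_ridges, compare)

img, gt = generate_fibre_image(regime_preset("clean_shg", seed=7))
traces = trace_ridges(img)
report = compare(traces, gt)
print(len(traces), round(report.total, 2))   # 5 448.31
```

`traceridges compare-methods scene.tif --gt gt.csv` evaluates every
method × pre-filter pair (ridge tracer and edge baseline; no filter,
Gaussian, or a registered denoiser plug-in) and writes one CSV row per
pair.

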