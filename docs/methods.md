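# Methods

## The tracing model

The tracer targets bright, elongated, curvilinear structures — collagen
and fibronectin fibres of the extracellular matrix as seen in
second-harmonic generation, fluorescence or stained-section microscopy —
and delineates each fibre as a one-pixel-wide trace along its intensity
crest.

The core observation is that two classical operators make complementary
errors on such images. The watershed transform of the intensity
landscape, flooded from its regional minima, places its divide lines
exactly on intensity ridges, but it over-segments: image noise breaks
the background into many small catchment basins, and spurious *minor*
ridge lines run down the fibre flanks and criss-cross the background. A
Canny edge detector, conversely, does not find the crest at all — it
fires on the two steep flanks of each fibre — but those flank edges
cross every minor ridge that descends through them. The pipeline
therefore:

1. **Watershed ridge lines.** Flood the image from its regional minima
   (8-connectivity, deterministic flooding order) and keep the divide
   pixels. Bright crests become divide lines; so does a mesh of minor
   divides in the background.
2. **Canny edges.** Standard Gaussian smoothing, gradient,
   non-maximum suppression and hysteresis.
3. **Break minor ridges.** Delete every ridge pixel that coincides with
   an edge pixel. Because two thin 8-connected curves can also cross
   *between* pixel centres (a diagonal ridge pair threaded by the
   opposite diagonal edge pair shares no pixel), those diagonal
   crossings are cut as well by removing one ridge pixel of the pair,
   chosen deterministically. Without this the divide network stays one
   connected component and the later per-segment filters cannot act.
4. **Remove small segments.** Delete 8-connected components whose
   ellipse-equivalent major axis is below 5 px.
5. **Remove dark segments.** Delete components whose mean underlying
   intensity falls below a global threshold (Otsu by default) — divides
   between background basins, not fibres.
6. **Repair double ridges.** A fibre occasionally yields two parallel
   divide lines with a sliver of a hole between them; these components
   are flagged by an Euler characteristic below one, their holes up to
   5 px² are filled, and the component is re-thinned to a single
   centre line. Larger holes are genuine loops of the network and are
   left alone.
7. **Recover missed ridges.** A ridge whose two flanks drain into a
   single surrounding basin produces no divide at all, but its two
   flank edges survive. Edges within the closing radius of an already
   traced ridge are attributed to that ridge; the remaining "orphan"
   edges are morphologically closed (disk of radius 5 px, half the
   maximal recovered minor axis), hole-filled and thinned to centre
   lines, with short corner spurs pruned. A candidate is kept only if
   flanking edge material remains on at least two sides after
   discounting the centre line's own vicinity — a candidate built from
   a single edge is noise and is discarded. Surviving candidates pass
   an axis filter: with fewer than 100 candidates, major axis > 15 px
   and minor axis < 10 px; with 100 or more, the stricter major axis
   ≥ 25 px applies. The minor-axis bound deliberately discards strongly
   curved candidates: the method prefers long, straight, bright fibres.
8. **Fuse.** Main and recovered masks are thinned and split into
   components; where they conflict, the component with the larger
   product of major-axis length and mean intensity — longer and
   brighter — keeps the contested pixels and the other is broken there.
   Every emitted trace is a single 8-connected, thinning-idempotent
   curve, tagged with its provenance (`main_ridge` or
   `recovered_edge`).

Three-dimensional stacks are collapsed with a maximum-intensity
projection before tracing; there is no native 3-D mode.

### Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `min_segment_major_axis` | 5 | px | minimum segment size after breaking |
| `relaxed_min_major` | 15 | px | recovered-candidate length bound, < 100 candidates |
| `strict_min_major` | 25 | px | recovered-candidate length bound, ≥ 100 candidates |
| `recovered_max_minor` | 10 | px | curvature bound on recovered candidates |
| `recovered_count_switch` | 100 | count | switch between the two bounds |
| `max_hole_area` | 5 | px² | largest hole filled in double-ridge repair |
| `dark_threshold_mode` | otsu | — | dark-segment criterion |
| `canny_sigma` | 1.0 | px | smoothing scale of the internal edge stage |
| `canny_low`, `canny_high` | auto | fraction | hysteresis thresholds |

The segment-size and recovered-candidate thresholds are the method's
defining constants. The Canny scale and hysteresis defaults, the Otsu
dark threshold and the 5 px² hole bound are this implementation's
choices where the method itself fixes no value; all are exposed in
`TraceRidgesConfig` and overridable from the CLI and config file.

### Numerical conventions

- Coordinates are 0-based `(row, col)`, row increasing downward; all
  mask work uses 8-connectivity.
- Images are normalised per image to [0, 1] by min-max, because
  microscopy sources differ wildly in dynamic range; RGB input is
  reduced with BT.601 luminance weights; integer files are rescaled by
  their maximum value.
- "Major/minor axis length" is everywhere the ellipse-equivalent axis
  from normalised second central moments, with the 1/12 per-pixel
  variance term, so a single pixel has axes ≈ 1.15 px — matching the
  regionprops convention of the major analysis environments.
- Orientation is reported in degrees in (−90, 90], 0 horizontal,
  positive counter-clockwise (upward in image coordinates); a vertical
  trace reports 90.
- The pre-filter Gaussian is a normalised kernel truncated to its 3×3
  support with sigma 0.5 px and reflective borders; the denoiser slot
  accepts any registered callable that preserves shape (a learned
  denoiser can be plugged in; none is bundled).
- The watershed tie-breaking follows the deterministic priority-queue
  order of the underlying flooding implementation, so repeated runs are
  bit-identical.
- Degenerate inputs: constant images yield an empty trace set with a
  warning; images smaller than 8×8 are rejected; an empty trace set is
  a hard error for distance evaluation (the distance map is undefined).

## Evaluation metrics

Pixel-overlap scores cannot grade a tracing: a delineation crossing the
truth at one pixel scores the same whether it hugs the truth or veers
away. The distance metrics used here take the exact Euclidean distance
transform of one trace set and sample it at the pixels of the other
(the product map). Its sum (total distance error), the sum divided by
the number of traces in the sampled set (average per trace), and its
maximum are reported in both directions, together with combined
summaries: the totals add, the combined mean divides by the combined
trace count, and the combined maximum takes the larger direction. The
combined total is symmetric under swapping result and ground truth;
ranking-style conclusions should use it, and both directed values are
always available because single-direction reporting is ambiguous.

Per-trace denominators use the trace count of the sampled (source) set
of each direction.

## The synthetic generator

The generator emulates the four qualitative imaging regimes the tracer
is aimed at: clean well-separated collagen (SHG-like), bright
fluorescent fibronectin, wavy filamentous stained sections, and noisy
low-contrast disease-mimicking matrices. Centrelines are constrained
random walks — per-step heading change bounded by the curvature
parameter — grown in both directions from an interior anchor and
clipped at the image border, emulating long fibres truncated by the
field of view, as in real ECM imagery. Each centreline is rendered with
a Gaussian transverse profile whose peak sits exactly on the
(thinned, 8-connected) centreline; amplitudes are drawn per fibre from
the regime's intensity range; i.i.d. Gaussian noise is added and the
image clipped to [0, 1]. The exact centrelines are returned as the
ground-truth trace set. A single generator seed governs all
randomness; identical specs produce bit-identical scenes. When
crossings are disallowed, fibres are kept apart by three profile sigmas
and placement failure after bounded retries is an error.

What the generator does **not** emulate: optical point-spread blur,
correlated (structured) noise, photobleaching, intensity variation
along a fibre, stain colour, and genuinely three-dimensional fibre
geometry. Tests passing on these scenes therefore demonstrate the
algorithmic behaviour of the pipeline — crest localisation, breaking,
recovery, the baseline's two-edges-per-fibre over-tracing — not
performance on any particular instrument's data.

Default scene scale is 160×160 px with five fibres (clean regime),
nominal arc lengths 240–340 px, profile sigma 1.5 px and noise sigma
0.015. The test suite and the reproduction script run 20 such scenes;
these sizes keep a full run in tens of seconds while leaving dozens of
background basins per scene, which is the regime the breaking and
dark-segment stages exist for.

## Design choices on open points

- **Watershed polarity.** The image is flooded as-is (dark background
  = basins), which is the only polarity that places divides on bright
  crests.
- **Edge-detection baseline scale.** The baseline's "filter size" maps
  to a Gaussian sigma of size/3, so the conventional 2-px filter gives
  sigma ≈ 0.67 px; each 8-connected edge component, thinned, is one
  trace.
- **Overlap breaking.** Exact overlap pixels plus deterministic
  diagonal-crossing cuts, no wider neighbourhood: a full 1-px dilation
  of the edges destroys the crest lines of narrow fibres.
- **Fusion priority.** Length × brightness as the priority score; the
  relative weighting is not prescribed by the method, and the product
  is the simplest score that prefers both.
- **Gap definition.** Gaps are 8-connected background components that
  do not touch the image border; border-touching background is open
  space, not an enclosed gap.
- **Width of a thinned trace.** Reported as twice the mean distance
  from the centreline to the boundary of the pre-thinning support
  (minus the centre pixel), clipped below at 1 px; 1 px when no support
  is available.

## Known limitations

- Fibres darker than the Otsu threshold of the image are removed as
  background divides; on images dominated by bright structures this can
  discard genuinely dim fibres.
- The recovery stage's minor-axis bound rejects strongly curved missed
  fibres by design; such fibres stay untraced, and the corresponding
  ground-truth error is charged to the result. This is the method's
  documented preference for long, straight, bright fibres.
- Crossing fibres are deliberately separated at junctions; a fibre
  crossing a brighter one is emitted as two traces.
- Volumes are handled only by maximum-intensity projection; crossing
  fibres at different depths merge in the projection.
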