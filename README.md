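# capsloc

Capsule-endoscope localization in the alimentary tract from per-frame
organ-classification probability streams.

A capsule endoscope films its own passage stomach → small intestine →
large intestine, and clinical staff currently find the two organ
transitions by visually scanning hours of video. Given the output of
any frame classifier — one probability vector per frame over
(stomach, small intestine, large intestine) — `capsloc` estimates the
two transition frames automatically. The classifier itself is not
part of the package; anything that writes the simple CSV/TSV/JSON-lines
stream format can feed it.

## Method

1. **CPV encoding.** Each frame's probabilities collapse to a scalar
   composite predicted value on the positional-code scale,

   CPV = 1·p(stomach) + 2·p(small intestine) + 3·p(large intestine) ∈ [1, 3],

   so a confident video traces a noisy staircase 1 → 2 → 3.
2. **Windowed 2-means outlier correction.** Boxes of 200 consecutive
   frames are split into two scalar clusters (exact 1-D 2-means);
   a minority cluster of at most 10% of the box, with centroids at
   least 0.5 apart, is treated as misclassification spikes and snapped
   to the dominant centroid. Balanced clusters — genuine transitions —
   are preserved. The corrected series is the NCPV.
3. **Sliding-window threshold localization.** Waiting areas of
   WAS = 200 frames advancing by WASS = 100 average the NCPV into the
   WAAV trajectory. A transition is declared at the first window where
   the WAAV crosses a threshold from below and the mean of the next 8
   windows stays above it: threshold ST = 1.35 (continuity SCT = 8)
   for the stomach→small-intestine intersection, LT = 2.4 (LCT = 8)
   for the small-intestine→large-intestine intersection, searched
   after the first. Errors are reported as NEF = |annotated −
   detected| frames, aggregated as MAEF (mean) and MdAEF (median).

Because no public capsule-endoscopy probability streams exist, the
package ships a synthetic generator (three-segment layout, confusion-
matrix noise, ambiguous boundary zones, sustained misclassification
bursts) that exercises the whole pipeline against known ground truth.

## Worked example

```python
from capsloc import CapsuleLocalizer
from capsloc.simulate import SimulationConfig, generate_stream, uniform_confusion

cfg = SimulationConfig(n_frames=12_000, confusion=uniform_confusion(0.05), seed=7)
case = generate_stream(cfg, video_id="demo")

results = CapsuleLocalizer(case.stream).fit()
print(results.summary())
print("truth:", case.truth.stp_stomach_si, case.truth.stp_si_li)
print("nef:", results.nef_against(case.truth))
```

```
Capsule localization results
============================================================
video_id:          demo
frames:            12000
waiting areas:     119 (WAS=200, WASS=100)
resolution:        ±100 frames (one window slide)
------------------------------------------------------------
stomach -> small intestine: frame 1000 (window 9, threshold 1.35, continuity 8)
small -> large intestine  : frame 10600 (window 105, threshold 2.4, continuity 8)
============================================================
truth: 1200 10680
nef: (200, 80)
```

At 5% uniform misclassification noise the detections land within one
or two window slides of the true boundaries: the stomach→SI estimate
is 200 frames early (the 100-frame ambiguous boundary zone plus the
earliest-consistent-frame reporting convention), the SI→LI estimate
80 frames off. `results.decisions` holds the per-window threshold
audit trail, and `capsloc.viz.render_results(results, "timeline.png",
truth=case.truth)` draws the red→yellow→blue timeline bars with the
detected intersections marked.

The same stages are available from the shell:

```sh
capsloc simulate --out data/ --seed 7
capsloc locate --input data/sim7.csv --output result.json
capsloc evaluate --results result.json --annotations data/sim7_truth.csv --output report.json
capsloc visualize --input data/sim7.csv --truth data/sim7_truth.csv --out timeline.png
capsloc ablation --output ablation.csv   # 4-variant post-processing comparison
```

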