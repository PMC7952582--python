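# organoquant

Bright-field organoid segmentation and treatment-effect analysis.

Patient-derived organoids (PDOs) are 3-D micro-tissues grown from tumour
cells.  In transmitted-light (bright-field) micrographs they appear as
roughly elliptical bodies with darker rims on a bright background,
sometimes with a dark centre.  A standard desk workflow for drug-response
experiments is to segment every organoid in every well image, measure its
pixel area, and test whether drug-treated wells contain smaller organoids
than controls.  `organoquant` implements that workflow end to end:

* **`organoquant.synth`** — a synthetic bright-field scene generator with
  *exact* ground truth (per-object label masks and areas), plus a cohort
  generator producing multi-arm, multi-timepoint image sets in which the
  treated arm's organoid size is shrunk by a known multiplicative factor.
  Because the truth is known by construction, every downstream stage can
  be validated quantitatively.
* **`organoquant.segment`** — the segmentation chain: greyscale
  conversion, Gaussian blur, Canny edge detection, edge smearing
  (blur + re-binarize, to thicken and connect edge fragments),
  morphological closing and opening, border-reachability hole filling,
  connected-component labelling, per-object measurement, and a
  large-area tail filter that discards segmented objects above
  40,000 px (bubbles, well walls and other large artefacts live in the
  sparse upper tail of the area histogram).
* **`organoquant.stats`** — treated/untreated labelling by dose
  (1 mM and 3 mM count as treated by default), a per-timepoint ordinary
  least-squares regression of object size on the binary treatment
  indicator (the coefficient is the treated-minus-control mean size
  difference, with its t test and 95% CI), small/medium/large size-class
  summaries, boxplot five-number summaries, and a xenograft
  tumour-volume utility (`0.5 × L × S`).
* **`organoquant.evaluate`** — object-level scoring of predicted against
  true segmentations by greedy one-to-one IoU matching (precision,
  recall, per-object relative area error).
* **`organoquant.pipeline` / `organoquant.cli`** — one-shot end-to-end
  runs and a CLI with `simulate`, `segment`, `analyze`, `evaluate` and
  `run` subcommands.  Every run is seeded and byte-reproducible.

## Worked example

Segment one synthetic scene and score it against its own ground truth:

```python
from organoquant import SceneParams, render_scene, segment_organoids, match_objects

scene = render_scene(SceneParams(seed=7))
labels, objects = segment_organoids(scene.image)
print(f"ground truth organoids: {len(scene.objects)}")
print(f"objects retained after the 40,000 px tail filter: {len(objects)}")

report = match_objects(scene.label_mask, labels, iou_min=0.5)
print(f"recall={report.recall:.2f}  precision={report.precision:.2f}  "
      f"median relative area error={report.median_relative_area_error():.3f}")
```

Output:

```
ground truth organoids: 20
objects retained after the 40,000 px tail filter: 20
recall=1.00  precision=1.00  median relative area error=0.136
```

Run a full two-arm, two-timepoint experiment from the command line.  The
config shrinks the treated arm's organoid radii by a factor 0.7, so the
true mean-area effect is a 51% reduction:

```bash
cat > demo.json <<'EOF'
{
  "cohort": {
    "images_per_arm_per_day": 3,
    "size_effect": 0.7,
    "seed": 11,
    "base_scene": {"height": 512, "width": 512, "n_organoids": 6,
                   "n_debris": 8, "n_bubbles": 0}
  }
}
EOF
organoquant run --config demo.json --out oq_demo
```

`oq_demo/` then contains the images, truth and predicted masks, the
manifest, per-object features, and the statistical results.  From this
run's `results.json` and `match_report.json`:

```
day 3: beta1=-1463.9 px, p=0.0577, n=36
day 7: beta1=-2047.7 px, p=0.0005, n=36
mean recall=1.00, mean precision=1.00
```

Both per-day treatment coefficients are large and negative (treated
organoids are smaller), consistent with the planted effect; with only
36 objects per day the day-3 test just misses the 0.05 line, which is
exactly the sampling noise the calibration checks below quantify.

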