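# wormtrack

Identity-preserving tracking of multiple *Caenorhabditis elegans* on
standard Petri dishes, from low-resolution grayscale image sequences
(nominally 1944×1944 px at 1 Hz).  Most worm trackers discard the data
whenever worms touch, overlap, or crawl over plate debris; `wormtrack`
resolves those situations and keeps each worm's identity through the
aggregation.

It is aimed at labs running behavioral, lifespan, or aggregation assays
who need per-worm pose tracks (ordered midline skeletons) rather than
blob centroids.

## Method

For a 30-frame sequence the pipeline:

1. **Segments** the dish interior (fixed threshold 35 under controlled
   backlight, AND across frames, hole fill, largest component) and the
   dark worm-track components inside it, filtering plate noise by
   minimum area and minimum skeleton length.
2. **Builds per-worm appearance models** at the start frame *k* where
   all worms are separate and unbranched: half-width and gray level
   sampled along the classical thinning skeleton (ordered head-first —
   the tail is the lighter end), plus a running-average length
   *L&#x2097;*.
3. **Skeletonizes with width constraints**: regions of the Euclidean
   distance transform deeper than any single worm's half-width are
   overlap zones; they are re-traversed with ridge-following paths so
   that parallel or crossing worms yield several traversable midlines
   where plain thinning yields one.
4. **Enumerates candidate poses** per worm by recursive traversal of the
   skeleton graph from every endpoint/branch node inside the worm's
   previous body, truncated at the model length.
5. **Optimizes** the assignment per frame: the prediction is
   S = argmin&#x209a; C&#x209a; with C&#x209a; = Σ&#x2c7c; Σᵢ C&#x2c7c;ᵢ over
   the enabled criteria — length (C_L = Σ Δᵢ·W̄ᵢ²), overlap with the
   previous body, completeness of the segmentation, smoothness, plate
   noise, and color (pixels deviating from the model by more than U = 1
   gray level) — scanning the full Cartesian product of candidates.
   Configurations follow the O/L/Cp/N/S/Cl naming (`O`, `OL`, `OCp`,
   `ON`, `OS`, `OCl`, `OCpCl`).
6. **Tracks bidirectionally** from *k* (forward to the end, backward to
   the start) at 3× resolution, then converts results back to the
   original scale.

Evaluation follows the IoU protocol: skeletons are dilated with a
radius-2 disk and scored by Jaccard index against ground truth; track
accuracy is the fraction of poses with non-zero IoU.

A seeded synthetic-fixture module renders dish sequences with known
skeletons (dark undulating tubes on a bright dish, contact events —
end contact, partial overlap, parallel bodies, crossing — scripted into
the middle of the sequence), so the whole pipeline is testable without
laboratory data.

## Worked example

```sh
wormtrack fixtures generate --scenario cross --worms 2 --seed 7 --out seq/
wormtrack run --input seq/ --model OCpCl --out out/
wormtrack eval --result out/track_result.json --truth seq/ground_truth.json
```

The `eval` step prints:

```
{"accuracy": 1.0, "mean_iou": 0.8758, "sd_iou": 0.0546, "track_accuracy": {"0": 1.0, "1": 1.0}}
```

Both worms cross mid-sequence; accuracy 1.0 means every reported pose
overlaps its own worm's ground truth (identity held through the
crossing), and mean IoU ≈ 0.88 is the localization quality of the
radius-2 body reconstructions.

The same pipeline is available as a library:

```python
from wormtrack import ScenarioSpec, render_sequence, track_sequence, score_tracks

seq, truth = render_sequence(ScenarioSpec(n_worms=2, event="cross", seed=7))
result = track_sequence(seq, "OCpCl")
print(score_tracks(result, truth).mean_iou)
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on a seeded two-worm crossing
(render → track under `OCpCl` → IoU scoring) and writes the
machine-readable report to `--out`.  The headline accuracies reported
for this method were measured on an external 70-track laboratory
dataset and are not recomputed here; the package's own guarantees (optimizer exactness,
criterion identities, identity preservation on seeded crossings,
skeleton separation, determinism, time symmetry) are asserted by
`tests/test_acceptance.py`.

See `docs/methods.md` for modelling assumptions, parameter defaults,
and known limitations.
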