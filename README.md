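# invertid

Specimen-level identification of freshwater macroinvertebrates from
multi-view silhouette image sequences.

In backlit-cuvette imaging systems, each specimen sinks through an
ethanol-filled glass cuvette and is photographed at a fixed frame rate by
two perpendicular cameras, yielding tens to hundreds of dark silhouettes per
individual. `invertid` implements the full downstream analysis as a tested,
reusable pipeline:

- **imaging** — blob detection (Otsu or fixed threshold, largest 8-connected
  component, hole filling), geometric features (area, boundary-walk
  perimeter, max Feret diameter), the standard 496-px cuvette crop, and body
  size in mm² via the pixel pitch implied by the 10 mm cuvette width:
  (10/496)² ≈ 4.06×10⁻⁴ mm² per pixel.
- **datasets** — specimen-grouped, leakage-free splits: a fixed test set
  (10 specimens per taxon), *nested* balanced training subsamples for
  learning-curve experiments, a stratified 10 % validation carve-out, and
  stratified grouped k-fold cross-validation. All frames of a specimen stay
  in exactly one partition.
- **classification** — 224×224 resizing, random rotation/flip/shear
  augmentation (shear: x′ = x + λₓy, y′ = λ_y x + y), and a pluggable
  per-image scorer. The reference scorer is a regularized multinomial linear
  model over downsampled pixels plus blob shape features, trained by
  deterministic gradient descent with early stopping on validation
  cross-entropy (weights from the epoch with minimum validation loss).
- **voting** — specimen-level aggregation of per-frame outputs: *majority
  vote* (equal-weight frame votes) and *max scoring sum* (argmax of the
  summed unbounded score vectors).
- **evaluation** — confusion matrices, accuracy, per-taxon precision
  TPₓ/(TPₓ+FPₓ) and recall TPₓ/(TPₓ+FNₓ), macro means with 95 % t-intervals
  across taxa, and body-size-vs-precision tables.
- **experiment** — the two study designs: a balanced sample-size sweep
  (one model per training size, identical test set throughout) and grouped
  k-fold CV, with CSV/JSON reports.
- **synthetic** — a generator that emulates the archive's statistical
  structure (taxon-specific frame counts inversely related to sinking speed,
  body sizes spanning >10×, two orthogonal views, pose-dependent
  foreshortening from tumbling) so the whole pipeline runs end to end with
  no external data.

## Worked example

```python
from invertid.synthetic import make_taxon_specs
from invertid.experiment import SweepConfig, run_sweep, synthesize_features

specs = make_taxon_specs(8, seed=0, speed_range=(0.8, 1.25))
features = synthesize_features(specs, 30, frames_base=20.0, seed=0)
cfg = SweepConfig(sizes=(2, 5, 10, 20), n_test_per_taxon=10, seed=0)
result = run_sweep(None, cfg, features=features)
for size in cfg.sizes:
    accs = {s: round(result.reports[(size, s)].accuracy, 3) for s in result.schemes}
    print(size, accs)
```

which prints (accuracy on the fixed 80-specimen test set; per-image is
frame-level, the other two specimen-level):

```
2 {'per_image': 0.445, 'majority': 0.425, 'score_sum': 0.487}
5 {'per_image': 0.783, 'majority': 0.8, 'score_sum': 0.825}
10 {'per_image': 0.886, 'majority': 0.912, 'score_sum': 0.925}
20 {'per_image': 0.902, 'majority': 0.938, 'score_sum': 0.938}
```

Accuracy rises steeply with the number of training specimens, and from five
training specimens per taxon upward, specimen-level voting beats per-frame
decisions, with the largest advantage at the smaller sizes. At the
degenerate size of two (a single training specimen per taxon after the
validation carve-out) the scorer is near chance for overlapping taxa, and
majority voting cannot amplify per-frame accuracy below one half — so the
voting advantage only emerges once the model is better than a coin flip per
frame.

A command-line interface mirrors the library:

```sh
invertid generate --taxa 16 --specimens 60 --seed 0 --out archive/
invertid features --in archive/ --out feats/
invertid split --manifest archive/manifest.csv --n-test 10 --seed 0 --out splits.json
invertid sweep --images archive/ --seed 0 --out report/
invertid cv --images archive/ --k 10 --seed 0 --out cv.json
```

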