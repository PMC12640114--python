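# plastinet

Desk-scale simulations of two intertwined facts of early visual
development: newborns see the world degraded (blurred, color-reduced), and
neuronal plasticity is highest early and decays with age. Is that decay a
mere constraint, or does it help *preserve* the processing strategies that
degraded early input instills? `plastinet` probes this with small
convolutional classifiers: stimulus fidelity is manipulated by a training
**regimen** (an epoch-indexed sequence of degradations) and plasticity by
the **learning-rate schedule** (constant = sustained plasticity,
decreasing = a time-limited critical period). The package is aimed at
computational-neuroscience and developmental-modeling work where the
full-scale version of such experiments (large networks, natural-image
corpora, GPUs) is out of reach but the qualitative structure is the point.

## What it contains

* `plastinet.imagesets` — a procedural generator of labeled image sets in
  which class identity is carried redundantly by hue, by band-pass texture,
  and by polygon outline, so grayscale conversion and Gaussian blur each
  remove one genuine cue family; PNG + CSV-manifest persistence, and a
  loader for user-supplied directories in the same format.
* `plastinet.degradations` — Gaussian blur with resolution-scaled sigma,
  BT.601 grayscale, HSV hue rotation, and the crop/flip/rescale
  preprocessing pipeline.
* `plastinet.schedules` — regimen presets (F2F, D2D, D2F, F2D, partial and
  gradual variants), LR presets (three constant, three decreasing, gradual
  staircase, reduce-on-plateau), and the matched decreasing-vs-constant
  pairings.
* `plastinet.network` / `plastinet.training` — a compact NumPy conv-net
  (im2col + BLAS) trained with Nesterov SGD, fully seed-reproducible, with
  per-epoch checkpointing.
* `plastinet.evaluation` — deterministic test batteries (blur sweeps, hue
  sweeps), seed aggregation (mean ± SE), matched comparisons, timing sweeps.
* `plastinet.representations` — first-layer receptive-field metrics
  (color-tuning score, spatial-frequency centroid), below-diagonal scatter
  counts, and layer-wise weight-dynamics (change magnitude, adjacent-epoch
  correlation, stabilization epochs).
* `plastinet.experiment` + the `plastinet` CLI — full regimen x schedule x
  seed grids with manifests, config hashing, resumable runs, and
  figure-style CSV tables.
* `plastinet.replication` — the canonical desk-scale grids and their
  summary statistics.

## A worked example

```python
from plastinet import ArchConfig, TrainConfig, generate_dataset, train, evaluate
from plastinet.degradations import DegradationSpec
from plastinet.presets import desk_spec
from plastinet.schedules import make_lr_schedule, make_regimen

train_set, test_set = generate_dataset(desk_spec(seed=1))
runs = {
    name: train(ArchConfig(), train_set, test_set,
                make_regimen("D2F", 10, degraded_kind="grayscale"),
                make_lr_schedule(name, 10),
                TrainConfig(epochs=10, seed=1))
    for name in ("dec1", "const1")
}
for name, run in runs.items():
    acc = evaluate(run.final_checkpoint(), test_set,
                   DegradationSpec("grayscale")).top1_accuracy
    print(name, round(acc, 3))
```

prints (seed 1)

```
dec1 0.59
const1 0.317
```

Both models trained first on grayscale, then on color images; the run
whose learning rate dropped at the switch (`dec1`) retained far more of
its grayscale competence than the run that stayed plastic (`const1`) —
the time-limited-plasticity effect this package exists to measure. The
scripts in `examples/` walk through each capability (dataset generation,
degradations, schedules, a single training run, receptive-field and
dynamics analysis) with printed output and a line on what it means.

Shell users can drive the same machinery via the CLI:

```sh
plastinet generate-data --out data/demo --n-classes 4
plastinet run-experiment --preset paper-desk-color --out results/color
plastinet figure-tables --results results/color --figure deltas --out tables/
```

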