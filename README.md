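# gazebehave

Gaze parsing, stare/move behaviour classification, and multi-level gaze
visualization for screen-based eye tracking.

Eye-tracking analyses almost always begin by collapsing raw gaze samples
into *fixations* (the eye holding still on a region of interest) and
*saccades* (rapid jumps between them), usually with one of a small family
of threshold algorithms — I-VT (velocity threshold), I-DT (dispersion +
duration window growth), density clustering (DBSCAN with an
automatically chosen radius), or I-VDT (velocity then dispersion, which
also separates *smooth pursuit*, the slow ≈10–30 deg/s tracking of a
moving target).  These algorithms are simple but parameter-sensitive:
nearly identical thresholds can produce very different fixation counts
and scanpath shapes, which silently changes every downstream
visualization.

`gazebehave` packages, for researchers and tool builders who work with
screen-based gaze data:

* the four classical detectors with strict, tested contracts (outputs
  always partition the samples; I-DT fixations individually satisfy both
  thresholds; DBSCAN's border tie-breaks are pinned down);
* a *behaviour-based* alternative that sidesteps event thresholds: each
  gaze sample becomes a small grayscale raster of the recent scanpath (a
  32°-wide window, dots fading with age), labelled **stare** (fixation or
  smooth pursuit — the target is being held on the fovea) or **move**
  (saccade-like repositioning), and classified by one of three small
  convolutional networks (a 3-conv net, an AlexNet-style 5-conv net, a
  sigmoid LeNet-style net) trained on those rasters;
* three abstraction levels of visualization: attention heatmap,
  scanpath, and a time-layered "abstract gaze movement" rendering whose
  tapered, colour-graded links encode movement direction between stare
  regions;
* detector-evaluation metrics (FQnS/FQlS fixation scores, pursuit
  position/velocity scores, Range-Coefficient parameter sweeps,
  per-class sample-level F1);
* a seeded oculomotor simulator (tremor, drift, return-biased
  microsaccades, main-sequence saccades, pursuit with catch-up saccades,
  binocular dropouts) that generates every fixture and benchmark in the
  test suite from code — no data downloads.

The scientific background and all modelling choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate the 4-target box task (targets at the corners of a 27.5° × 15°
rectangle, 3 s stays, 0.2 s transitions, 40 Hz), run two detectors, and
score them against the scripted stimulus:

```python
import gazebehave as gb

script = gb.make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
rec, truth = gb.simulate_gaze(script, 40.0, gb.OculomotorParams(seed=1))
stim = gb.script_to_stimulus_signal(script, 40.0)

for name, segs in [
    ("I-VT  v_T=30", gb.ivt(rec, 30.0)),
    ("I-VDT v_T=30 D_T=3", gb.ivdt(rec, 30.0, 3.0)),
]:
    regions = gb.stare_regions(segs, rec)
    print(name, "->", len(regions), "stare regions,",
          f"FQnS {gb.fqns(segs, stim):.1f}%")
```

```
I-VT  v_T=30 -> 4 stare regions, FQnS 100.0%
I-VDT v_T=30 D_T=3 -> 4 stare regions, FQnS 100.0%
```

Both detectors recover exactly the four scripted stare regions, and the
fixation qualitative score (the percentage of stimulus-fixation time
covered by a detected fixation within 1.5° of the target) reaches its
100 % ceiling on this clean task.  The same pipeline is available from
the shell:

```bash
gazebehave simulate --pattern four_target --transitions 0.2,0.2,0.2 \
    --seed 1 --out gaze.csv --truth truth.csv
gazebehave detect --algo ivt --vt 30 --in gaze.csv --out events.csv
gazebehave visualize --mode abstract --in gaze.csv --events events.csv \
    --out abstract.png
gazebehave evaluate --pred events.csv --truth truth.csv \
    --classes fixation,saccade --out scores.json
```

Training the behaviour classifiers on the bundled synthetic corpus
(2000 stare + 2000 move windows in each of train and validation):

```python
from gazebehave.datasets import bundled_dataset
from gazebehave.classify import train

train_set, val_set = bundled_dataset(n_per_class=4000, split=0.5, seed=0)
for arch in ("alexnet_like", "cnn3", "lenet_like"):
    _, report = train(arch, train_set, val_set, epochs=6, seed=0)
    print(arch, f"val accuracy {report.final_val_accuracy:.3f}")
```

```
alexnet_like val accuracy 0.974
cnn3 val accuracy 0.967
lenet_like val accuracy 0.500
```

The AlexNet-style net is the strongest and the sigmoid LeNet-style net
the weakest — the deeper ReLU architectures separate the compact stare
rasters from the gapped move rasters within an epoch or two, while the
sigmoid net is still climbing out of saturation at this training length.

## Layout

```
src/gazebehave/
  core.py       recordings, geometry, CSV I/O, velocity, segments
  detect.py     I-VT, I-DT, DBSCAN-with-IQR, I-VDT, merge utilities
  windows.py    behaviour-window rasterization and dataset building
  nn.py         numpy conv-net layer stack (im2col conv, pooling, Adam)
  classify.py   the three architectures, training, behaviour segmentation
  metrics.py    FQnS/FQlS, pursuit scores, RC sweeps, per-class F1
  simulate.py   stimulus scripts and the oculomotor simulator
  datasets.py   bundled synthetic training corpus
  viz.py        heatmap, scanpath, abstract gaze-movement renderers
  cli.py        `gazebehave` command-line interface
```
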