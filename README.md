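# toposep

Topographic analysis of multichannel sensory evoked potentials (SEPs):
global field power, randomization statistics on scalp maps, automated
component marking, data-driven time windows, and microstate segmentation
— with a synthetic evoked-potential generator that provides ground truth
for every stage.

## The problem

Clinical SEP work traditionally reads a single bipolar trace (e.g. Cz–Fz
for lower-urinary-tract or pudendal SEPs) and marks P1/N1/P2 peaks by
hand. That discards the spatial structure of the scalp field and depends
on a reference choice. Reference-independent topographic analysis treats
each time point as a *map* and asks two separate questions:

* does the **strength** of the field differ between conditions?
  Strength is the **global field power**,
  `GFP(u) = sqrt( (1/K) Σ_k (u_k − ū)² )` — the spatial SD of the
  average-referenced map;
* does the **shape** (topography) differ, independent of strength?
  The **TANOVA** statistic normalizes every map to unit GFP and measures
  the generalized dissimilarity `Σ_levels GFP(mean map of level − grand
  mean map)`, with significance from permuting condition labels within
  subjects (or subjects across groups), `p = (#{null ≥ obs}+1)/(n_perm+1)`.

Supporting tools: the **topographic consistency test** (is there a
common topography across subjects at all?), channel-wise **t-maps**,
component time windows from GFP minima / inflection points or mean ± 2 SD
of individual latencies, and **microstate** segmentation by
atomize-and-agglomerate hierarchical clustering (AAHC) with the class
count chosen by split-half cross-validation over subjects. Because a
scaled map difference can be strength, shape, or timing, the package
keeps these analyses side by side; `docs/methods.md` has the full
formulation.

Intended users: neurophysiology groups analyzing stimulus-locked EEG who
want these statistics scriptable, seeded, and testable rather than bound
to a GUI analyzer.

## Worked example

The bundled demo simulates a small study — 5 subjects × 3 stimulation
frequencies (0.5/1.1/1.6 Hz, map strength decreasing with frequency), 12
trials per average, 20 channels, 125 Hz — then runs the whole workflow:

```bash
toposep run-all --config src/toposep/configs/demo.yaml --out demo_out
# run complete; outputs in demo_out
# responder rate: 100.0%
# microstates: k=4 GEV=0.963
```

or in Python:

```python
from toposep import pipeline
summary = pipeline.run(pipeline.load_config("src/toposep/configs/demo.yaml"),
                       "demo_out")
```

What the numbers mean:

* `responder rate: 100.0%` — every simulated recording had stable
  split-half averages (r ≥ 0.5) with all three components markable; the
  per-recording latencies/amplitudes are in `demo_out/markers.tsv`
  (e.g. subject BD-S00, 0.5 Hz: P1 at 56 ms, 0.88 µV on Cz–AvgRef).
* `demo_out/windows.json` — data-driven component windows from the
  grand-average GFP curve: minima mode brackets N1 at 80–152 ms and P2 at
  176–328 ms; the narrower inflection windows (102–132, 231–281 ms) nest
  inside them; mean ± 2 SD of the individual N1 markers gives 104–128 ms.
* `demo_out/significant_intervals.json` — the GFP test flags a frequency
  effect on map strength around the N1 peak (80–120 ms) and over the late
  P2 range (200–600 ms), while TANOVA stays at chance there: the
  programmed effect is amplitude scaling with unchanged topography, and
  the strength/shape dissociation recovers exactly that. The TCT shows
  consistent topography across subjects from ~88 ms onward (and in the
  pre-stimulus range, where the simulated slow anticipatory negativity
  is shared across subjects).
* `microstates: k=4` — split-half cross-validation over subjects peaks
  at 4 classes (CV curve in `demo_out/microstates_summary.json`), and the
  4-prototype AAHC model explains 96.3% of the GFP-weighted map variance;
  per-class duration / mean GFP / occurrence by condition are in
  `demo_out/microstate_parameters.tsv`.

Everything is seeded: rerunning with the same config produces
byte-identical tables. `toposep simulate` writes epoch fixtures + ground
truth, `toposep plot` renders topographic map series (nose-up
azimuthal-equidistant projection), and BrainVision recordings
(`.vhdr/.vmrk/.eeg`, multiplexed float32/int16) can be fed through the
same pipeline via the `input: brainvision` config block.

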