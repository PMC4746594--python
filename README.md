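# cellpick

In-silico computer-vision-controlled micropipette single-cell isolation.

Fluorescence-activated sorters struggle when the target cells are very rare
or when each cell must end up in its own vessel. An alternative is a
motorized microscope plus a glass micropipette (30 µm inner diameter) that
detects fluorescent cells in a thin (~97 µm) oil-covered layer of suspension
and aspirates them one by one in ~1.4 nl. `cellpick` reimplements the
computational side of that instrument — detection, targeting, scheduling —
together with a stochastic digital twin of the suspension, so the sparse
isolation, microwell-comparison and successive-enrichment experiments can be
run and tested entirely in software. It is aimed at people studying or
extending image-guided single-cell manipulation who need a ground-truthed
sandbox rather than hardware.

## What is modeled

* **Synthetic imaging** (`cellpick.synthetic`) — cell populations with a
  hard-core minimum separation, Gaussian-spot fluorescence rendering with
  known ground truth, and tiled mosaic scans with stage offsets.
* **Detection** (`cellpick.detection`) — the local-variance segmentation:
  threshold the per-pixel window variance at `noise_level² × sensitivity`,
  take 8-connected components with hole filling, filter by equivalent
  diameter *d* and mean brightness. ImageJ "Analyze Particles" CSV tables
  can be imported as an external segmenter.
* **Adaptive targeting** (`cellpick.targeting`) — a single fresh frame
  captured right before each pick corrects the target's stale scan
  coordinates (nearest fresh detection within a 50 µm search radius).
* **Scheduling** (`cellpick.scheduler`) — greedy nearest-neighbor tour over
  the targets, destination assignment (500 µm deposition grid, 24-well
  miniature plate, PCR tubes) and the timed valve protocol
  (−100 Pa × 10 ms pick, 1 s ambient equilibration, +4200 Pa × 1 s deposit,
  5 µm approach height).
* **Suspension digital twin** (`cellpick.suspension`) — persistent random
  walk floating motion (presets 39 ± 12, 5.4 ± 1.1 and 2.3 ± 0.6 µm/min),
  capture-disc pick physics (radius *R* = 34 µm sparse, 63 µm dense
  effective), exact nanoliter volume accounting (1.4 nl per pick, 147 nl
  per deposit), deposition spread, and Bernoulli microwell trapping
  (10,000 wells at 100 µm pitch, fill efficiency 0.25/0.54).
* **Workflows** (`cellpick.workflows`) — the three composed experiments and
  the estimators they report.

The central quantity in the sorting statistics is the expected number of
bystanders co-aspirated with a target in a uniform field of density *d*:
a Poisson count with mean λ = *d*·π·*R*². Successive enrichment thins
bystanders geometrically by the capture-to-spread area ratio
(*R*/*R*_spread)² = (34/127)² ≈ 0.072 per pass, which is what turns a
1,000:1 contaminated inoculum into a pure population in three passes.

## Worked example

Run the dense-culture successive enrichment (50 labeled cells among 50,000
unlabeled in a 5 × 5 mm² square, three passes between arenas):

```bash
$ cellpick --seed 0 enrich
pass 1: 24.62 +- 4.58 bystanders/labeled, purity 0.039
pass 2: 1.78 +- 1.47 bystanders/labeled, purity 0.360
pass 3: 0.04 +- 0.20 bystanders/labeled, purity 0.962
```

Pass 1 works at the dense effective capture radius (63 µm), so each of the
50 labeled cells drags along ~25 unlabeled bystanders
(λ = 0.002 µm⁻² · π · 63² ≈ 25). After redeposition in 127 µm clusters,
re-picking at the sparse 34 µm radius keeps only ~7% of them (1.78 per
labeled cell), and by pass 3 the transferred population is essentially pure
— the geometric thinning described above.

The same library drives the sparse isolation loop (mosaic scan → detect →
route → fresh-frame retarget → pick into tubes):

```bash
$ cellpick --seed 0 simulate
recovery 0.959 over 2000 targets -> isolation_report.json
```

and the floating-speed measurement:

```bash
$ cellpick --seed 3 speed --n-cells 10
4.89 +- 1.42 um/min over 10 cells (thin_layer, 120 s intervals)
```

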