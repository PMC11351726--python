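# ivfc — in vivo flow cytometry from line-scan kymographs

Adapting a scanning (confocal or multi-photon) intravital microscope into an
in vivo flow cytometer: the laser line is parked across a blood vessel and
scanned at 650–850 Hz, so every fluorescent cell that flows past leaves a
streak in the resulting position × time image (kymograph). This package
turns such recordings into quantitative measurements of circulating cells —
counts, sizes, velocities, and blood concentrations — for experiments such
as tracking neutrophil dynamics during inflammation in reporter mice.

For each record the pipeline measures:

* the vessel lumen diameter **D** from the intravascular dye channel;
* per cell, the streak's spatial extent **d** (≈ cell diameter, since a
  free-flowing leukocyte is round), temporal extent **t** (traverse time),
  and velocity **v = d/t**;
* the blood volume sampled by the line over the scanning time **T**,

  **V = π (D/2)² · ave(v) · T**,

  and the circulating concentration **n/V** from the cell count **n**, with
  an exact Poisson confidence interval.

It also supports two-color recordings (a reporter plus an injected
fluorophore-conjugated antibody): percent antibody-positive events against
a background-statistics gate, background-subtracted MFI, and dot-plot /
quadrant tables. A ground-truth simulator generates synthetic kymographs
with known concentration, velocity/diameter distributions, vessel geometry
and noise, so every estimator is validated by parameter recovery without
any external data. Statistical comparisons (Pearson correlation with the
slope F-test, per-timepoint unpaired t-tests for longitudinal group
comparison) are included.

See `docs/methods.md` for the model, algorithmic choices, and limitations.

## Worked example

Simulate a 120 s resting-state record (40 µm vessel, 750 Hz, true
concentration 1.31×10⁵ cells/mL) and analyze it:

```python
from ivfc import SimulationParams, simulate_record, RecordModel

kymo, truth = simulate_record(SimulationParams(seed=1))
results = RecordModel(kymo).fit()
print(results.summary())
```

```
IVFC record summary
=======================================================
record: 90000 lines x 128 px @ 750.0 Hz, 0.6 um/px
scanning time T:            120.00 s
vessel diameter D:           39.60 um
cells counted n:                18
mean velocity ave(v):        954.6 um/s  (SEM 79.9)
sampled volume V:        1.411e-04 mL
concentration n/V:       1.276e+05 cells/mL
  95% Poisson CI:       [7.561e+04, 2.016e+05]
threshold used:             169.81 (background-floor)
```

All 18 simulated cells were found (`truth.n_events == 18`), and the
estimated concentration 1.28×10⁵ cells/mL brackets the generating value
1.31×10⁵ well inside the Poisson interval — at ~20 expected events per
record, counting noise dominates, which is why longitudinal experiments
average several records per animal. `results.events` carries the per-cell
measurements, `results.events_frame()` the tidy table, and
`results.plot()` the kymograph with detection boxes.

The same pipeline is scriptable from the shell:

```sh
ivfc simulate --out run/ --seed 1
ivfc analyze --image run/record.tif --metadata run/record.json --out run/
ivfc timecourse --manifest manifest.csv --out tc/ --treated treated --control control
ivfc gate2c --image rec.tif --metadata rec.json --out gate/
```

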