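# cytobarcode

Combinatorial **k-of-n live-cell barcoding** for mass cytometry (CyTOF):
design barcode key schemes, simulate barcoded single-cell batches with known
ground truth, debarcode pooled events back into per-sample sets, and report
yield/QC statistics.

## The problem

Mass cytometry measures dozens of metal-isotope-tagged antibodies per cell.
To compare many samples without batch effects, samples are *barcoded*: each
well is stained with antibodies against ubiquitous surface antigens (e.g.
CD29, CD98, CD45) conjugated to a unique combination of metal isotopes, then
all wells are pooled and acquired together. With **B** barcode channels and
exactly **k** of them positive per sample (a constant-weight binary code),
**C(B, k)** samples can be pooled — e.g. 10 samples from 5 channels with
k = 3 (112Cd, 113In, 114Cd, 115In, 116Cd), or 20 from 6 channels.

Because every key has the same weight, any two keys differ in ≥ 2 positions.
A cell-cell doublet carries the *union* of two keys (weight ≥ k + 1), so it
matches no key and can be rejected computationally.

## Debarcoding

Two procedures are implemented:

- **Separation-threshold assignment** (automated). Barcode channels are
  arcsinh-transformed (`asinh(x / 5)`), rescaled per channel to [0, 1]
  between the 1st/99th percentiles, and scored against every key:
  `score(e, s) = min(rescaled over key-positive channels) − max(rescaled
  over key-negative channels)`. The best key wins; the winning score —
  the *separation* between the dimmest "on" channel and the brightest
  "off" channel — must reach a threshold (default **0.3**) or the event
  is left unassigned. For a complete scheme this is provably the
  "top-k brightest channels" rule, with separation equal to the gap
  between the k-th and (k+1)-th brightest rescaled values.
- **Hierarchical Boolean gating** (the manual gating strategy, automated).
  A per-channel cutoff — supplied, or estimated by minimising within-class
  variance (Otsu's criterion) — splits each channel into +/−; an event is
  assigned to the unique key whose positive set equals its above-cutoff set.

Preprocessing mirrors a standard CyTOF cleanup: cell events are identified
on DNA (rhodium) intensity and event length, dead cells removed on
palladium uptake.

## Worked example

```bash
cat > demo.yaml <<EOF
simulation: {events_per_sample: 1000, doublet_rate: 0.05, dead_rate: 0.02}
gate: {rh_min: 2.0, length_range: [10, 35], pd_max: 3.4}
outdir: demo
seed: 1
EOF
cytobarcode run --config demo.yaml
```

prints

```
capture rate 99.47% (9809/9861 live cells); artifacts in demo
```

i.e. the simulator pooled 10 samples × 1,000 singlets plus 5% doublets and
2% dead cells (10,526 events total); the Rh/event-length gate kept 10,056
cell events (most doublets fail the length gate), the Pd gate kept 9,861
live cells, and separation-threshold debarcoding at 0.3 assigned 9,809 of
them (99.47%) — with every barcode receiving ≈ 10% of assigned events
(`demo/report.json` holds the per-sample table; singlet calls were 100%
correct against the simulator's ground truth and 96% of surviving doublets
were rejected). `demo/` also contains the pooled batch FCS, one FCS per
assigned sample, the per-event assignment CSV, and a run manifest.

The same stages are available individually:

```bash
cytobarcode scheme --k 3 --out key.csv                 # 10-plex key CSV
cytobarcode simulate --out batch.fcs --truth truth.csv
cytobarcode debarcode --fcs batch.fcs --threshold 0.3 --out-prefix db_
cytobarcode report --assignment db_assignment.csv --truth truth.csv
```

or from Python:

```python
from cytobarcode import (generate_complete_scheme, SimulationConfig,
                         simulate_barcoded_events, debarcode_separation,
                         compute_yield, score_concordance)

scheme = generate_complete_scheme()          # 5-choose-3 -> 10 keys
batch, truth = simulate_barcoded_events(scheme, SimulationConfig(seed=1))
calls = debarcode_separation(batch, scheme)  # threshold 0.3
print(compute_yield(calls, scheme.sample_names).capture_rate)
```

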