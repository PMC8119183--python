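# Methods

## Barcode schemes

A scheme is a binary key matrix **K** (samples × channels) with constant row
weight *k*. `generate_complete_scheme` enumerates all C(B, k) keys in
lexicographic order of their positive-channel index sets; the ordering is a
package convention chosen so repeated generation is byte-identical (any
fixed order works — the assignment problem is permutation-invariant).
Default channels are the five-channel cadmium/indium layout
`112Cd, 113In, 114Cd, 115In, 116Cd` in ascending mass order, giving the
10-plex design at k = 3 and a 20-plex when a sixth channel is added.

Validation asserts row weight, pairwise distinctness, row count ≤ C(B, k),
and pairwise Hamming distance ≥ 2. The distance bound is implied by
distinct constant-weight rows but is asserted independently so corrupted
matrices are caught even when other invariants also fail. Distance ≥ 2 is
what makes doublets detectable; the package deliberately does not attempt
distance > 2 (error-correcting) designs.

Key CSVs are comma-separated UTF-8 with header `sample,<ch1>,...` and 0/1
body cells. Partial schemes (fewer than C(B, k) rows) are read without
error; `validate_scheme` accepts them, since real panels sometimes use a
subset of keys.

## Simulated batches

The simulator emulates one pooled acquisition of a live-cell-barcoded
plate: every well gets a rhodium DNA intercalator, a short palladium pulse
(viability mark — dead cells take up far more Pd), and one barcode; wells
are pooled and acquired.

Signal model: each channel intensity is lognormal,
`LogNormal(ln(median), log_cv)`, i.e. the *median* is specified directly
and `log_cv` is the standard deviation of the natural-log intensity. A
barcode channel uses `pos_median` where the sample's key is 1 and
`neg_median` where it is 0 (`neg_median = 0` yields exact zeros;
`log_cv = 0` is the noiseless limit). Defaults — `pos_median 200`,
`neg_median 2`, `log_cv 0.5`, live/dead Pd medians `10`/`500`, Rh median
`300` — describe a clearly separable but not trivial stain: positive and
negative barcode distributions overlap in their tails at `log_cv 0.5`, so
the separation threshold actually discards a small fraction of events.
These values are package conventions (raw ion counts of realistic
magnitude), not measurements.

Doublets are channelwise **sums** of two independent singlets from
distinct, uniformly chosen samples — ion clouds add; a max-composition was
rejected as unphysical. Their event length is drawn from a longer, wider
Gaussian (mean 40 vs 25, sd 4 vs 2 — nominal pulse-length units), so an
event-length gate can remove part of the doublet load before debarcoding,
as in routine practice. The number of doublets is chosen so that the
doublet fraction of the *total* emitted batch equals `doublet_rate`
(`n_doublets = round(r/(1−r) · n_singlets)`). A doublet's dead flag is the
OR of its components; dead singlets keep their sample label with `is_dead`
set.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; event order is shuffled with the same generator.

What the simulator does **not** model: normalization beads, spillover and
isotopic impurity between channels, acquisition-time drift, cell-free
debris, and per-sample staining variability. Passing tests therefore
demonstrate the correctness of the *algorithms* under a clean lognormal
stain model, not robustness to every artifact of real acquisitions —
channel crosstalk in particular would lower real separation scores.

## Preprocessing

Intensities are arcsinh-transformed, `asinh(x / c)` with cofactor
`c = 5` — the conventional CyTOF choice, configurable. Rh (cell
identification) and Pd (viability) gates compare against transformed
values so thresholds are stable across signal scales; the event-length
gate uses raw pulse length. Gate thresholds are explicit numbers in the
configuration: automatic estimation (the Otsu cutoff below) can be applied
to any single channel, but cleanup gates default to stated values so runs
are auditable. Gating is idempotent and cell/viability gates commute.

Barcode channels are rescaled per channel to [0, 1] between the 1st and
99th percentiles (clamped), a robust alternative to min–max scaling;
percentiles are configurable. A constant column is flagged with a warning
and rescaled to all zeros — nothing can look positive on a dead channel.
One *global* percentile rescale is used, deliberately: no iterative
per-population re-rescaling is performed, which keeps the procedure
deterministic and single-pass at the cost of a slightly shifted effective
threshold compared with debarcoders that re-normalise per assigned
population.

## Separation-threshold debarcoding

For event *e* and key *s*,

```
score(e, s) = min_{j: K[s,j]=1} r[e, j]  −  max_{j: K[s,j]=0} r[e, j]
```

on rescaled intensities `r`. The event is assigned to the arg-max key and
its **separation** is the winning score clamped to [0, 1]. Scoring is
defined key-wise rather than as "take the k brightest channels" so that
partial schemes work; for complete schemes the two are equivalent (the
winning key is the top-k set and the separation equals the gap between the
k-th and (k+1)-th brightest rescaled values), and that equivalence is a
tested property against an independent brute-force oracle. Exact score
ties between distinct keys are unassignable (separation 0) — a
conservative tie-break; ties have probability zero under the continuous
signal model and arise only for degenerate inputs.

`apply_threshold` unassigns events with separation below the threshold
(default **0.3**); the comparison is `≥`, so an event exactly at the
threshold is kept. Capture rate is non-increasing in the threshold by
construction. The Mahalanobis-distance outlier filter found in some
debarcoder implementations is not included; the separation threshold is
the only event filter. Both are noted extension points.

## Hierarchical-gating debarcoding

The manual Boolean strategy, automated: with one cutoff `t_j` per channel,
an event is positive on channel *j* iff its transformed value is `> t_j`.
An event is assigned to key *s* iff its positive set equals the key's
positive set exactly (positive on every key-positive channel, at or below
cutoff on every key-negative one); in a constant-weight scheme at most one
key can match. Cutoffs operate on arcsinh-transformed values.

When not supplied, cutoffs are estimated per channel by minimising the
total within-class sum of squares over all realisable 1-D splits (Otsu's
criterion on the continuous values, computed exactly by prefix sums over
the sorted channel; first minimal split wins, so the estimate is
deterministic). A constant channel is flagged failed and given a +∞
cutoff — nothing is called positive. The separation field of gated
assignments is populated from percentile-rescaled values so both
debarcoders produce comparable QC reports.

## Yield and concordance reporting

The yield report tracks the event funnel — total events, gated cells, live
cells, assigned — and the **capture rate** = assigned / live cells. The
denominator is the live gated cell count: capture is a property of the
debarcoder, so events already discarded as debris or dead are excluded.
Per-sample rows carry both each barcode's share of *assigned* events (the
even-distribution view; ≈ 1/S for an equal-abundance pool) and its share
of live cells (which sums with the unassigned fraction to 1). The
separation histogram uses fixed 0.02-wide bins over [0, 1]. A batch with
zero live cells produces an explicitly flagged empty report rather than a
division by zero.

Against simulator ground truth, the concordance report gives singlet
accuracy (fraction of assigned singlets called correctly), doublet
rejection (fraction of true doublets left unassigned), and an S × (S+1)
confusion table (true sample × called sample + unassigned); either
fraction is NaN when its denominator is empty.

## Pipeline and reproducibility

`cytobarcode run` chains simulate → gate → debarcode → report from one
YAML config. Every stage logs input/output event counts; a run manifest
records package and numpy versions, the seed, and all parameters. Reports
contain no timestamps, so a rerun with the same config and seed is
byte-identical.

## Problem sizes

Tests simulate batches of 10 samples × 100–3,000 events; the acceptance
script uses 2,000 singlets per sample (20,000 events). These sizes give
sampling error well below the tolerances being checked (per-barcode shares
concentrate within ±1 percentage point of 10% at n = 10,000) while keeping
any single run under a minute.

## Known limitations

- No spillover/isotopic-impurity compensation; barcode channels are
  treated as independent.
- The 0.3 default threshold is calibrated to rescaled units after a
  *global* percentile rescale; pipelines that re-rescale per population
  will place the same nominal threshold at a slightly different operating
  point.
- FCS support covers single-dataset FCS 3.0/3.1 list mode ($DATATYPE
  F/D/I); FCS 2.0, multi-dataset files, and spillover keywords are out of
  scope.
- Doublet rescue (assigning a doublet to one of its constituents) is
  deliberately not attempted.
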