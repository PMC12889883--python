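# Methods

## Measurement model

The package analyses metagenomic sequencing (MGS) count tables under a
two-stage measurement model.  First, each taxon *z* in a sample produces an
analytical response proportional to its actual abundance `A_z` (copies/mcL
by convention) times an aggregate bias factor `B_z` that collects every
taxon-specific distortion of the pipeline — DNA extraction efficiency, PCR
amplification, sequencing and read classification.  Under a locked-down
protocol (one fully specified pipeline applied to all samples) `B_z` is
assumed constant across samples; the model does not attempt to decompose it
into per-step factors, because only the aggregate is identifiable from the
final table.  Second, sequencing saturates: a fixed read budget closes the
responses to a constant sum, so the observed relative abundance is

    RA_z = A_z B_z / Σ_t A_t B_t.

This closure is the source of compositionality — the denominator couples
every taxon to every other.

An exogenous internal standard (IS), spiked into every sample at a known
concentration `A_IS`, shares each sample's denominator.  The **Scaled
Abundance**

    SA_z = (RA_z / RA_IS) · A_IS = A_z · (B_z / B_IS)

therefore cancels the closure exactly.  Everything the package computes
follows from this identity:

* `ΔSA_z` between two samples equals `ΔA_z` (bias ratios cancel);
* the bias ratio `B_z / B_IS` is the slope of SA against known actual
  abundance, estimable from spiked replicates;
* `A_z = SA_z / (B_z / B_IS)` back-calculates absolute concentration.

These identities hold exactly only in expectation.  With finite read
depth, counts are modelled as a multinomial draw over the expected relative
abundances, and SA inherits counting noise with relative magnitude roughly
`1/√(reads of taxon z)` + `1/√(reads of IS)` per sample.  The evaluation
procedures quantify how much of the exact behaviour survives that noise.

## Statistical procedures

**Replicate precision** is the coefficient of variation, 100 × sample
standard deviation (ddof = 1) / mean.  A zero mean returns NaN rather than
an error so vectorised summaries can proceed.

**Proportionality fits** regress SA (or RA) on known actual abundance or
dilution fraction by least squares *through the origin* by default — the SA
model has no intercept.  An intercept flag exists for sensitivity checks.
Slope confidence intervals are standard t-intervals (df = n − 1 through the
origin, n − 2 with intercept).

**Regression goodness-of-fit CV** is defined as

    CV = 100 × RSE / mean(observed y),   RSE = sqrt(SS_res / (n − p)),

with p the number of fitted coefficients.  This is a deliberate
interpretation choice: "CV of a regression" is not a uniquely defined
quantity, and the df-corrected residual standard error (what R reports as
the residual standard error) is the standard statistical reading.  Exact
proportional data give CV 0 regardless of slope.

**Bias-ratio estimation** forms per-replicate ratios `r_i = SA_i / A_truth`
and reports their arithmetic mean with a two-sided t-interval (default 95%).
The arithmetic mean of per-replicate ratios was chosen over ratio-of-means
and over log-space aggregation as the simplest defensible estimator; a
`aggregation="geometric"` flag switches to the log-space (geometric-mean)
version for workflows that treat ratios multiplicatively.  At least two
replicates are required — below that no interval is estimable.

**Internal-standard rotation** treats each taxon of a multi-community
design in turn as the IS, computes SA for the remaining taxa using the
candidate's known abundance, fits per-taxon proportionality regressions,
and averages the per-taxon CVs with a t-interval.  Communities lacking the
candidate are omitted for that rotation; taxa with fewer than three usable
points are skipped and listed.  A relative-abundance baseline (RA regressed
on truth, no IS) is reported once for comparison.  On noise-free data every
rotation returns mean CV 0 — the IS choice is immaterial in principle, and
the rotation quantifies how far that holds under noise.

**Limit-of-quantitation profiling** fits SA against dilution fraction
through the origin for every native taxon of a dilution series and pairs
each regression CV with the taxon's relative abundance in the undiluted
sample.  Plotting CV against RA shows the relative abundance below which SA
stops tracking actual abundance within a chosen CV bound.

## Simulator

`simulate_counts` draws counts per sample as multinomial(depth, expected
RA), with expected RA from the closure above; `noise="expectation"` returns
`depth × expected RA` exactly and is used wherever an algebraic identity is
asserted.  Depth is fixed per sample by default, optionally
Poisson-distributed.  Biases default to lognormal draws with log-scale
sigma 1.0 — spanning the regime where biases vary substantially and
unpredictably between taxa — normalised to ensemble **mean 1**: only bias
ratios are identifiable, so the scale is a convention, and mean-1 keeps the
bias-weighted total response on the same scale as total abundance, which
keeps depth and concentration calibrations meaningful.  Explicit bias
vectors are always accepted.  Per-sample bias jitter is deliberately not
modelled: the framework's assumptions make biases constant under a
locked-down protocol, and the simulator exists to test the framework under
its own assumptions.

Three scenario builders bind the validation designs:

* **Mock communities** (default 80) assemble random subsets (≥ 2 members)
  of a 7-strain panel, each member at an abundance drawn from the stock
  dilutions {1/2, 1/3, 1/7}, which double as the known actual abundances.
* **Spike-in backgrounds** (default 5 backgrounds × 3 technical replicates)
  draw native compositions from a flat Dirichlet over 50 taxa, scaled to a
  per-background total microbial load — median 1.2 × 10⁶ copies/mcL with
  lognormal spread sigma 0.7.  The four spike taxa are constant in every
  sample at 4.8 × 10⁴, 9.6 × 10³, 5.4 × 10³ and 6.2 × 10² copies/mcL, and
  the internal standard at 2.16 × 10⁵ copies/mcL.  The load median places
  the rarest spike near relative abundance 5 × 10⁻⁴, and the load spread
  reproduces the large (tens of percent) between-donor variation in spike
  relative abundances observed in real stool panels; both were fixed from
  those observed conditions, not tuned.
* **Dilution series** scales one community (lognormal abundances, sigma
  1.5, scaled to the same total) by fractions 0.2–1.0, adding the IS at
  constant concentration *after* dilution.  An optional extra taxon is
  constructed with unit bias and an abundance solved so its expected
  undiluted relative abundance hits a requested value (default use case:
  3 × 10⁻⁵, the limit-of-quantitation probe).

Every scenario is driven by a single integer seed through one
`numpy.random.Generator` stream, so identical specs give bit-identical
tables.

### What the simulator does and does not emulate

It emulates: taxon-specific multiplicative bias, compositional closure,
multinomial counting noise, replicate structure, background diversity and
dilution designs.  It does not emulate: read-level artefacts (sequencing
error, chimeras), taxonomic misassignment between taxa, protocol drift
(per-sample bias variation), zero-inflation beyond what multinomial
sampling produces, or correlated community structure.  Passing tests
therefore show that the estimators are correct *under the measurement
model's own assumptions* and quantify counting-noise-limited precision;
they do not certify performance against distortions the model excludes —
in real data, protocol drift and misassignment would add variance that
these simulations cannot see.

## Numerical and policy choices

* No pseudocounts by default; `RA = 0` yields `SA = 0`.  An optional
  pseudocount (added to all counts pre-normalisation) exists for log-scale
  workflows.
* A sample whose IS relative abundance is zero is a hard error by default
  (a vanished internal standard invalidates the sample); an explicit
  `on_zero_is="drop"` discards such samples with a logged warning.
* Fold changes are NaN (undefined), never infinite, when either sample's SA
  is zero; the numerator/denominator order is caller-specified and recorded.
* Proportions-vs-counts auto-detection accepts row sums within 1e-6 of 1;
  validation of declared proportions uses the tighter 1e-9.  Ambiguity is
  resolved by an explicit `mode_hint`.
* Tables are written with 17 significant digits so a write/read round trip
  reproduces doubles exactly.
* Regression requires ≥ 3 points and non-degenerate x; taxa failing this
  are skipped and reported, not silently dropped.

## Problem sizes

The stochastic test and acceptance workloads use 5 backgrounds × 3
replicates at depth 10⁵ (spike precision), 5-point dilution series at depth
10⁶–2 × 10⁶ (regression CVs), and 20 seeded replicate simulations wherever
a single simulated CV would itself be a noisy statistic (the 5-sample spike
CV, and the limit-of-quantitation regression CV).  These sizes give
stable averages at a few seconds of runtime; the identities that hold
exactly are tested in expectation mode at tolerance 1e-9 or tighter.

## Known limitations

* The bias-ratio t-interval assumes approximately normal per-replicate
  ratios; at very low counts (≲ 20 reads) the ratio distribution is
  skewed and coverage degrades below nominal.
* Regression CVs compare variability to the *mean* response; for series
  whose mean is dominated by one large point the CV can understate
  relative error at the low end.
* The CLI and library treat taxon ids as opaque strings; there is no
  taxonomy awareness, aggregation across ranks, or handling of ambiguous
  classifications.
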