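# Methods

`clscreen` implements the analysis of a pooled-deletion-collection
chronological lifespan (CLS) screen in *Saccharomyces cerevisiae*, together
with a synthetic-screen generator that lets every stage be exercised and
validated without array data.  This note records the models, the defaults
and why they were chosen, and what the synthetic results do and do not say
about real screens.

## The screen being modeled

A pool of ~4,800 viable haploid deletion mutants, each carrying unique
UPTAG and DNTAG barcodes, is aged in liquid culture under non-restricted
(NR, 2% glucose) or calorie-restricted (CR, 0.5% glucose) medium.  At days
1, 9, 21 and 33 an aliquot is plated, survivors are recovered, and their
barcodes are PCR-amplified, fluorescently labeled and co-hybridized with
the day-1 material on a tag microarray.  The per-mutant **abundance ratio**

    R_d = I_d / I_1

(later-day channel over day-1 channel, per tag) is a proxy for relative
survival.  Probes for essential genes have no corresponding mutant in the
pool, so their signal measures nonspecific hybridization and anchors the
background filter.

## Synthetic screen generator (`clscreen.simulate`)

**Survival law.**  Each mutant dies off with Weibull survival
`S(d) = exp(-(d/τ)^k)`.  The Weibull was chosen because its shape
parameter gives stationary-phase die-off a tunable shoulder; `k = 1.5` by
default (gentle shoulder, sub-exponential early death).  Per-condition
characteristic times: `τ_NR` and `τ_CR = 1.6·τ_NR` for CR-responsive
mutants (CR-unresponsive mutants have `τ_CR = τ_NR`), encoding the
population-wide viability boost under CR.

**Lifespan classes.**  The "normal" class is wild-type-like and therefore
tight by construction: `τ_NR ~ Normal(12 d, 0.3 d)`, truncated at 1 d.
Planted phenotype classes scale τ by an effect-size factor with its own
spread, because deletion phenotypes vary in strength while "normal" means
indistinguishable from WT: short `× Normal(1/3, 0.10)`, long
`× Normal(3, 0.6)` (floored at 0.05 and 1.2).  Default class mix: 5%
short, 5% long, 4% CR-unresponsive, 86% normal; 1,000 essential
probe-only genes accompany the default 4,800-mutant pool.  Class counts
are apportioned by largest remainder, so fractions are honored to within
one mutant.

**Sampling and signal.**  Plating recovers `plating_depth` (default
2×10⁶) cells as one multinomial draw over the pool's expected viable
counts; counting noise is therefore shared between a mutant's two tags,
as it is in reality (both tags ride on the same recovered cells).  Probe
intensity is `count × tag efficiency × ε + b`, with per-gene, per-tag
efficiencies `Uniform(0.4, 1)`, multiplicative log-normal noise ε of unit
mean and CV `noise_cv = 0.05` (the residual per-probe technical
variability beyond counting noise and background), and an additive
log-normal background with mean 10 and CV 0.25 (intensities are on the
scale of recovered-cell counts).  Essential probes receive background
only.  A tag flagged missing (probability 0.005 per tag) is emitted with
empty intensity fields and is dropped — and counted — at ratio
computation, which is what gives dual-tag concordance filtering something
real to remove.

**Adaptive regrowth ("gasping").**  With probability 0.005 per mutant per
timecourse, a mutant's viable count is multiplied by 25 from a uniformly
chosen post-reference day onward — a single multiplicative jump, since the
phenomenon is described only qualitatively.  Regrowth events are recorded
in the truth table; they are the simulator's source of genuinely
irreducible false long-lived calls.

**Determinism.**  The whole simulation is a pure function of (profiles,
config, seed); every stage draws from an independent child stream of one
master seed, so re-running any command with the same config is
byte-identical.

## Ratio processing (`clscreen.arrays`)

Ratios are computed per (gene, tag, condition, day); records with a
missing channel or non-positive reference are dropped, never imputed, and
counted in the processing report.  Log ratios use base 2, the two-channel
microarray convention.  Box-plot summaries use linear-interpolation
quartiles (numpy default, R type 7), matching the convention of the
statistics environments these plots come from.

**Background filter modes.**  Two metrics are implemented behind a
switch.  `"ratio"` averages essential-gene abundance *ratios* per tag and
eliminates non-essential genes whose mean ratio falls below it — the rule
as classically printed for this screen design.  `"ref_intensity"`
averages essential-gene *reference-channel intensities* and keeps genes
whose day-1 signal clears it — a direct signal-presence criterion.  On
synthetic data the two differ sharply: an essential probe's ratio is the
quotient of two background draws and centers near 1, so the ratio rule
would discard most of a genuinely dying pool, including every true
short-lived mutant.  Since the filter's purpose is to keep "genes with
signals from both tags" — an intensity property — the simulated pipeline
and the CLI example use `ref_intensity`; `ratio` remains the default
switch position for processing measured ratio tables where only ratios
are available.

## Candidate calling (`clscreen.calling`)

Ranking uses competition (minimum-rank) semantics — spreadsheet `RANK`
behavior — within each tag's own filtered universe.  Rank cuts are
inclusive ("bottom 200" includes rank 200); ratio cuts are strict
("less than 0.3", "greater than 1.0").  All criteria require both tags and
are therefore evaluated on the dual-tag universe; genes missing a tag are
listed in a side report.

- **Short-lived:** day-9 ascending rank ≤ 200 for both tags AND day-21
  ratio < 0.3 for both tags; day 33 is never consulted (most of the pool
  is dead by then).
- **Long-lived:** day-33 descending rank ≤ 500 for both tags AND day-21
  ratio > 1.0 for both tags.
- **CR-unresponsive:** at every time point the absolute fractional
  difference between mean NR and CR log ratios (difference over their
  average, tags averaged per day) is < 0.1, AND a two-sided Welch t-test
  on the pooled per-condition log ratios (tags × days, 6 values per
  condition at the full design) passes the configured p-rule.  The
  p-rule is exposed because the printed criterion ("p < 0.05, i.e. their
  means are not significantly different") is internally contradictory:
  `p_lt_alpha` follows the printed inequality and is the default;
  `p_ge_alpha` is the conventional not-significantly-different reading.
  The rule used is stamped into the output sidecar.  Genes with a
  vanishing denominator are excluded and reported as undefined.

No multiple-testing correction is applied anywhere, matching the original
analysis.  Every call set carries its per-gene justification columns, and
`verify_call_set` re-derives all of them from the ratio table (the audit
runs inside the `call` CLI command on every invocation).

## Lifespan assays (`clscreen.cls`)

Survival fractions are CFU(d)·dilution(d) relative to the reference day.
Strain-vs-WT classification uses the trapezoid-averaged difference of
log10 survival over shared days rather than a single-day cutoff, because
curve-level judgment is what the per-strain assays actually express; the
margin default of 0.5 log10 units (≈3-fold average survivor difference)
was calibrated so that replicate WT-vs-WT courses with multinomial CFU
noise classify "normal" ≥ 95% of the time (this calibration is a test).
Printed percentages (confirmation rates, overlaps) round half away from
zero to one decimal — `numpy.round`'s half-to-even would turn 13/16 into
81.2 rather than the printed 81.3.

## Recovery experiments (`clscreen.experiments`)

`planted_recovery` simulates a 2,000-mutant pool with 5% planted short
and 5% planted long mutants, runs the full pipeline, and scores the
short/long call sets against the planted labels with rank cuts rescaled
in proportion to pool size (round(200·n/4800), round(500·n/4800)).  Note
that proportional scaling caps short recall at round(200·n/4800)/(0.05·n)
≈ 0.83 by construction — the cut admits at most 83 of 100 planted shorts
— so recall is reported as a mean over seeds and sits at ~0.81 at
default noise.  The 2,000-mutant size keeps a five-seed recovery
experiment under ten seconds while leaving ~100 genes per planted class,
enough for stable precision/recall estimates.

## What the synthetic screens do not capture

- No between-culture variance: the real protocol pools survivors from 20
  parallel cultures per condition; a single culture is simulated with
  `plating_depth` absorbing the aggregation.
- No cell-extrinsic coupling between strains (secreted-metabolite
  effects, medium conditioning), no probe-sequence or cross-hybridization
  structure, no spatial array artifacts — and consequently no need for
  print-tip or loess normalization, which the analysis never had.
- The planted classes are well-separated by design; passing recovery
  tests demonstrates that the pipeline's arithmetic and thresholds behave
  as specified, not that a real screen of this design achieves comparable
  precision — the published retest confirmation rates (81.3% for
  short-lived, 30.8% for long-lived candidates) are the honest estimate
  of real-data performance, and the gap is dominated by biology the
  simulator only sketches (adaptive regrowth, strain competition, medium
  effects).

## Degenerate inputs and tie-breaks

Zero or missing reference channels drop the record; an all-dead pool at
plating raises a "pool extinct" error; tied ratios share the minimum
rank; a CR-unresponsiveness denominator of exactly zero excludes the gene
as undefined; curves crossing with equal log-AUC classify "normal".
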